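# Methods

## Model and assumptions

Both models treat one fully mixed soil compartment (default: 1 m² × 0.35 m
at bulk density 1500 kg/m³, hence 525 kg of soil and a contaminant mass of
525·C mg per mg/kg of concentration) and one removal pathway: harvest of
above-ground tissue. Stems and leaves are the only harvest compartments;
roots enter only through the translocation factor TF = C_stem/C_root used
to repair incomplete harvest records, and fruits are not modelled.

The extraction potential E aggregates all plant-side processes into two
empirical variables per tissue, BAF and BMP, assumed constant within a
model run. The **linear** model holds E constant over the whole
remediation and therefore yields the theoretical minimum time; the
**exponential** model keeps the removal *rate* k = E/m_i constant instead,
so annual removal shrinks with the remaining pool. Reality sits between
and usually beyond both: neither model represents biodegradation,
leaching, aging-driven bioavailability decline, spatial heterogeneity, or
feedback of concentration on plant growth. The probability distributions
on BAF and BMP are the mechanism by which such variability is
acknowledged, not resolved.

Both times are reported for the same reduction; for a 90% reduction at
equal k the exponential/linear ratio is ln(10)/0.9 ≈ 2.558, a closed-form
identity the test suite asserts.

## Uncertain inputs

Each of the four inputs (baf_stem, baf_leaves, bmp_stem, bmp_leaves) is an
independent random variable described by one of:

* **Beta-PERT(min, mode, max)** — shapes α₁ = 1 + 4(b−a)/(c−a),
  α₂ = 1 + 4(c−b)/(c−a); mean (a + 4b + c)/6. Used when a bounded range
  is available or estimable.
* **zero-truncated Normal(mean, sd)** — negative draws are rejected and
  resampled, never clipped: clipping would create a point mass at zero
  that corrupts mode estimates. Specs needing acceptance probability
  below 1% are refused.
* **point(value)** — degenerate; used for per-metabolite BAF means whose
  spreads were never published, and for sweep levers.

Independence between and within tissues is an assumption; no correlation
structure (e.g. plants that grow well also accumulating more) is imposed,
because the source datasets provide none.

### Fitting rules

From raw replicates (n ≥ 3): PERT with a = sample min, c = sample max,
and the mode solved from the mean identity, b = (6·mean − a − c)/4,
clamped into [a, c]. An empirical mode of a handful of replicates would be
ill-defined; this choice preserves the sample mean exactly whenever the
solved b needs no clamping.

From published summaries (mean ± SD): the default family is the truncated
Normal. For variables assigned a PERT family but published only as
mean ± SD with sample size n, the endpoints are placed at the expected
range of a normal n-sample — mean ± d₂(n)/2 · SD, with d₂ the
expected-range constant (d₂(6) = 2.534, d₂(15) = 3.472) — the minimum
floored at zero and the mode again solved from the mean identity. This is
the package's own construction: it reproduces, in expectation, the
min/max a PERT would have been built from had the underlying sample been
available.

### Default family assignment

The packaged datasets record a family per variable: bounded PERT for the
literature dataset's bioaccumulation factors, truncated Normal for its
biomass variables and for the whole site-specific dataset. The assignment
used by the original analysis of these datasets is not recoverable from
the publication (it lived in unpublished supplementary material), so the
package tested the 2×2 family patterns (BAF/BMP × PERT/Normal) against
the published result tables and ships the only pattern that reproduces
the published removal-rate and remediation-time modes within ±30% across
seeds. Every assignment remains overridable per variable in configuration.
Two published results are *not* jointly reproducible with the time
tables under any summary-faithful pattern (see "Known discrepancies").

## Simulation and summaries

10 000 iterations by default (at least 100), vectorized; one seeded
`numpy.random.Generator` drives all draws in a fixed variable order, so a
config plus seed reproduces results bitwise. Remediation times are
computed inside each iteration and summarized as their own distributions:
for right-skewed outputs mode(t) differs systematically from
t(mode(k)), and the per-draw summarization is what produces the wide,
honest uncertainty intervals. Zero-extraction draws yield an infinite
time sentinel; summaries use finite draws only and report the non-finite
fraction, and a run with more than half non-finite time draws is flagged
degenerate (CLI exit code 3).

### Mode estimation

The "most likely value" of a simulated output is the argmax of a Gaussian
KDE with Silverman's rule-of-thumb bandwidth
0.9 · min(sd, IQR/1.349) · n^(−1/5), evaluated on a 512-point grid from
the sample minimum to the 99th percentile. Two choices matter and were
made deliberately:

* **Original scale, not log scale.** A KDE argmax computed on log-draws
  and back-transformed maximizes x·f(x), not f(x); for the heavy
  right-skews these models produce it overestimates modes by 50–100%.
* **Trimmed evaluation grid, robust bandwidth.** Time distributions have
  a sharp density peak near their minimum (the reciprocal transform of E
  concentrates mass there) and tails stretching over orders of magnitude.
  A grid spanning the full range wastes essentially all resolution on the
  tail, and an sd-only bandwidth over-smooths the peak; trimming the
  *grid* (never the sample) at p99 and guarding the bandwidth with the
  IQR keeps the estimator stable across seeds (observed spread ≤ ±6% at
  10 000 iterations).

Constant samples return their value; fewer than 100 finite draws is an
error (or a NaN summary inside a flagged degenerate run).

### Sensitivity

Spearman rank correlation (scipy) of each input draw vector against each
output vector, ranked by |ρ|. Constant inputs carry no rank information
and are reported as ρ = 0 with a flag.

## Scenarios

* **A — efficiency gradient**: nine (C_soil,i, %eff) pairs from (10, 33%)
  to (2, 155%); the factor multiplies E only.
* **B — BAF sweep**: BAF_stem as a point lever (8–18) against the
  empirical probability P(t_linear ≤ horizon), horizon 25 years.
* **C — optimized biomass**: site BAF distributions with literature BMP
  distributions.

All cells of a scenario share one draw table (common random numbers).
Besides reducing noise between cells, this makes the structural
monotonicities — times falling along the gradient, success probability
rising in BAF and falling in concentration — exact properties of every
run, which the engines' tests assert unconditionally.

## Synthetic field studies

`generate_synthetic_study` fabricates per-plot records (soil, stem, leaf
and root concentrations; tissue dry weights) around known true BAF/BMP/TF
values with multiplicative lognormal noise (mean 1, chosen coefficient of
variation) — lognormal because field concentrations and biomasses are
positive and right-skewed. It emulates the *structure* of a small field
trial, not its hard parts: no spatial correlation between plots, no
season effects, no measurement censoring, and noise that is honestly
mean-1 where real bias (washing losses, moisture corrections) would not
be. Passing recovery tests therefore demonstrates that the
fit-then-simulate pipeline is consistent, not that a 6-plot trial pins
down field parameters. The recovery acceptance check uses 50 plots at
cv 0.3 and 4 000 iterations × 20 trials, which runs in seconds.

`adjust_damaged_harvest` imputes missing stem concentrations as
TF_reference · C_root (flagging them), mirroring the repair a real trial
needs when pests destroy an above-ground harvest; plots missing roots too
are dropped with a warning.

## Reporting

All library numbers are unrounded; the report layer renders 3 significant
figures (half away from zero, matching printed tables), rates as
percentages, and years ≥ 1000 with a thin-space thousands separator.
Machine outputs (JSON summaries, CSV draw tables) carry raw floats and a
config echo sufficient to rebuild the run.

## Known discrepancies and limitations

* The published BAF-sweep claim "< 40% probability at BAF_stem 18,
  C_soil,i 10" computes to ≈ 0.42 under the shipped family assignment;
  it reproduces (≈ 0.27) only with a bounded-PERT stem-BMP, which in
  turn breaks the published time modes by +50%. The two published
  results are mutually inconsistent given only the printed summary
  statistics; the package keeps the assignment that reproduces the
  primary rate/time tables.
* The published optimized-biomass removal-rate mode (0.178 %/yr) exceeds
  the mean rate implied by the published input summaries (0.146 %/yr).
  Right-skewed products of summary-faithful distributions place their
  density mode below their mean, so this mode is not reproducible from
  the printed data; both published *time* modes of the same run are
  reproduced, and 0.178 lies inside the simulated [p5; p95].
* The per-metabolite table ships with point BAFs (spreads unpublished)
  and the shared ΣDDX biomass distributions; its published E/k/t values
  are internally inconsistent and are not used as checks.
* Mode estimates of 10 000-draw skewed samples carry irreducible
  estimator variance of a few percent; comparisons against published
  modes use a ±30% band plus containment of the published mode in the
  simulated 90% interval.
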