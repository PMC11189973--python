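dataset,variable,tissue,mean,sd,n,min,mode,max,family,c_soil_i,source
site_specific,baf,stem,0.89,0.46,6,,,,normal,10,Kolleberga field experiment years 1-2 (sum-DDX)
site_specific,baf,leaves,0.134,0.08,6,,,,normal,10,Kolleberga field experiment years 1-2 (headline table prints 0.13 at 2 sf; 0.134 from the per-metabolite breakdown)
site_specific,bmp,stem,0.0783,0.0416,6,,,,normal,10,Kolleberga field experiment years 1-2
site_specific,bmp,leaves,0.190,0.0808,6,,,,normal,10,Kolleberga field experiment years 1-2
literature,baf,stem,5.74,3.35,15,,,,pert,10,Cucurbita pepo cv. Howden field studies (literature review)
literature,baf,leaves,0.435,0.203,15,,,,pert,10,Cucurbita pepo cv. Howden field studies (literature review)
literature,bmp,stem,0.799,0.690,15,,,,normal,10,Cucurbita pepo cv. Howden field studies; 4 plants per m2
literature,bmp,leaves,0.410,0.312,15,,,,normal,10,Cucurbita pepo cv. Howden field studies; 4 plants per m2
pp_ddt,baf,stem,0.718,,6,,,,point,7.9,"Kolleberga, p,p'-DDT (per-metabolite mean; spread unpublished)"
pp_ddt,baf,leaves,0.114,,6,,,,point,7.9,"Kolleberga, p,p'-DDT"
pp_ddt,bmp,stem,0.0783,0.0416,6,,,,normal,7.9,shared sum-DDX site biomass distribution
pp_ddt,bmp,leaves,0.190,0.0808,6,,,,normal,7.9,shared sum-DDX site biomass distribution
op_ddt,baf,stem,2.67,,6,,,,point,1.0,"Kolleberga, o,p'-DDT"
op_ddt,baf,leaves,0.286,,6,,,,point,1.0,"Kolleberga, o,p'-DDT"
op_ddt,bmp,stem,0.0783,0.0416,6,,,,normal,1.0,shared sum-DDX site biomass distribution
op_ddt,bmp,leaves,0.190,0.0808,6,,,,normal,1.0,shared sum-DDX site biomass distribution
pp_ddd,baf,stem,1.63,,6,,,,point,0.48,"Kolleberga, p,p'-DDD"
pp_ddd,baf,leaves,0.114,,6,,,,point,0.48,"Kolleberga, p,p'-DDD"
pp_ddd,bmp,stem,0.0783,0.0416,6,,,,normal,0.48,shared sum-DDX site biomass distribution
pp_ddd,bmp,leaves,0.190,0.0808,6,,,,normal,0.48,shared sum-DDX site biomass distribution
pp_dde,baf,stem,1.08,,6,,,,point,0.76,"Kolleberga, p,p'-DDE"
pp_dde,baf,leaves,0.199,,6,,,,point,0.76,"Kolleberga, p,p'-DDE"
pp_dde,bmp,stem,0.0783,0.0416,6,,,,normal,0.76,shared sum-DDX site biomass distribution
pp_dde,bmp,leaves,0.190,0.0808,6,,,,normal,0.76,shared sum-DDX site biomass distribution
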