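chrom	start	end	length	n_windows	mean_fst	score	n_snps	duality_class	het_mean_HWS55	het_mean_LWS55	het_median_HWS55	het_median_LWS55
chr1	21501	996500	975000	181	0.9994185508973704	180.89475771242405	3165	fixed_high	0.01416060013595497	0.16536865838984607	0.0	0.05401234567901234
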