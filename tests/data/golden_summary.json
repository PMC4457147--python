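{
 "defense_regions": 0,
 "loci_disiRNA": 2,
 "loci_milRNA": 2,
 "loci_total": 4,
 "mc_context_CHG": 0.003902439024390244,
 "mc_context_CHH": 0.006829268292682927,
 "mc_context_CpG": 0.9892682926829268,
 "mc_sites": 1025,
 "mean_level_TE": 85.35353535353535,
 "mean_level_gene": 2.6666666666666665,
 "methylation_rate": 0.009222021287124259,
 "rip_fraction_CG_to_TA": 0.5719298245614035,
 "rip_sites": 163,
 "silencing_fraction_classI_rip_mc": 0.3333333333333333,
 "sim_planted_loci": 4,
 "sim_planted_rip_sites": 49,
 "te_expressed": 5,
 "te_records": 11
}
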