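# SYNTHETIC stand-in for SEER stage-specific survival over the 3-year
# analysis horizon.  These life expectancies are free parameters of the
# scenario, calibrated once (closed-form 2x2 solve) so that the default
# pipeline's life-years-gained totals match the reference analysis
# (47.8 and 103.8 LYG).  Substitute real SEER-derived values for any
# application beyond the packaged scenario.
stratum,life_expectancy_years
metastatic,1.20316
non_metastatic,2.61696
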