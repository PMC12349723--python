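# Published LC-MS/MS intracellular-accumulation summary panel for the P-gp
# substrate daunorubicin (DAU) and nine experimental inhibitor candidates.
# Values are mean ± SD of normalized ratios ((analyte/IS)/lysate mg/mL) over
# triplicate samples, measured in P-gp-overexpressing DU145-TXR cells with
# (plus) or without (minus) 500 nM tariquidar; printed_p is the p-value as
# published alongside the panel. Trials with analyte below quantification in
# both conditions are marked indeterminate (no printed p).
compound_id,trial,mean_minus,sd_minus,mean_plus,sd_plus,n,indeterminate,printed_p
DAU,1,0.014,0.001,0.216,0.002,3,0,<1e-06
DAU,2,0.017,0.001,0.232,0.016,3,0,2e-05
70,1,0.93,0.15,0.93,0.07,3,0,>1
70,2,0.56,0.11,0.55,0.15,3,0,0.9
78,1,0.001,0.000,0.001,0.000,3,1,
78,2,0.001,0.000,0.001,0.000,3,1,
96,1,0.087,0.009,0.092,0.036,3,0,0.8
96,2,0.121,0.005,0.163,0.032,3,0,0.09
97,1,0.07,0.02,0.08,0.03,3,0,0.7
97,2,0.10,0.02,0.10,0.02,3,0,>1
101,1,11.86,1.16,12.03,2.45,3,0,0.9
101,2,21.17,3.59,22.88,2.92,3,0,0.6
103,1,5.13,0.6,5.61,1.34,3,0,0.6
103,2,2.63,0.52,3.75,0.34,3,0,0.04
103,3,3.21,0.23,3.73,0.15,3,0,0.03
111,1,0.012,0.002,0.013,0.004,3,0,0.7
111,2,0.011,0.002,0.013,0.001,3,0,0.2
122,1,0.049,0.005,0.146,0.018,3,0,0.0008
122,2,0.058,0.018,0.209,0.014,3,0,0.0003
124,1,0.006,0.001,0.061,0.011,3,0,0.001
124,2,0.007,0.002,0.055,0.009,3,0,0.0008
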