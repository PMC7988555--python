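muscle,ff_mean_A,ff_sd_A,csa_A,ccsa_A,n_A,ff_mean_B,ff_sd_B,csa_B,ccsa_B,n_B
adductor_longus,24.49,14.39,75.87,53.33,17,24.87,14.88,69.84,47.38,17
adductor_magnus,40.20,19.34,203.15,145.42,17,42.97,28.92,189.43,132.98,17
biceps_femoris_long,39.05,19.34,113.99,78.94,18,40.23,20.77,111.53,76.27,18
biceps_femoris_short,30.73,25.47,78.01,59.29,16,28.19,25.64,78.71,59.71,15
gracilis,32.33,20.05,63.72,44.20,19,33.89,22.59,55.62,38.44,18
rectus_femoris,38.01,20.37,58.84,40.32,17,37.65,19.87,58.03,39.84,17
sartorius,41.46,18.77,45.61,27.68,16,41.92,18.61,44.87,26.73,16
semimembranosus,41.09,19.17,118.58,76.87,20,42.69,20.98,110.72,71.01,20
semitendinosus,38.22,17.42,79.72,49.22,20,41.25,20.44,77.54,47.32,20
vastus_intermedius,37.51,24.84,71.75,56.41,6,35.16,23.74,65.72,51.97,6
vastus_lateralis,47.94,23.09,225.27,127.24,16,49.31,24.32,212.81,119.41,16
vastus_medialis,47.82,21.42,109.58,66.93,20,49.20,22.31,107.48,63.29,20
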