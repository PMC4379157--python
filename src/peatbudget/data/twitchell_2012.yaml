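# Published site-level summary inputs (mean +/- SE) for the two flooded-rice
# fields on Twitchell Island, CA (2012 season): every quantity the annual
# N-budget -> C-loss chain consumes, at the precision given in the source
# tables.  Values are inputs to the model, not outputs.
description: >
  Site-level budget inputs for two rice fields on Rindge mucky silt loam,
  Sacramento-San Joaquin Delta.  N quantities kg N ha-1, C quantities
  kg C ha-1, concentrations mg N L-1.
constants:
  n_deposition: 6.0     # kg N ha-1 yr-1, wet + dry atmospheric deposition
  n_fixation: 25.0      # kg N ha-1 yr-1, free-living cyanobacteria
  nue: 0.50             # assumed N uptake efficiency
et:
  cumulative_et_m: 0.634     # flooded period 21 Jun - 21 Sep 2012
  crop_coefficient: 1.06
residue_application:       # labelled/unlabelled residue mixture, spring 2012
  mass_labeled: 1310.0     # kg dry matter ha-1
  mass_unlabeled: 3700.0
  n_labeled: 12.0          # kg N ha-1
  n_unlabeled: 35.0
  cn_labeled: 41.0
  cn_unlabeled: 35.0
  atom_pct_labeled: 9.0693
  atom_pct_unlabeled: 0.3673
som_pct_c: 0.58            # g C per g SOM
f_min: 0.67                # fraction of subsidence from SOM oxidation
sites:
  "1":
    uptake_0n: {value: 185.0, se: 10.0}
    ndr: {value: 1.9, se: 0.2}
    ndsw: {value: 2.9, se: 1.3}
    ndgw: {value: 61.7, se: 9.0}
    residue_min_fallow: {value: 16.9, se: 1.3}
    soil_no3_at_flooding: {value: 20.3, se: 0.7}
    residue_c_input: {value: 1872.0, se: 137.0}
    cn_ratio: 14.4
    bulk_density_g_cm3: 0.555
    grain_yield_mg_ha: 7.9
  "2":
    uptake_0n: {value: 167.0, se: 7.7}
    ndr: {value: 3.8, se: 1.1}
    ndsw: {value: 3.0, se: 1.3}
    ndgw: {value: 39.6, se: 6.7}
    residue_min_fallow: {value: 21.0, se: 2.1}
    soil_no3_at_flooding: {value: 42.1, se: 0.5}
    residue_c_input: {value: 1894.0, se: 189.0}
    cn_ratio: 14.8
    bulk_density_g_cm3: 0.782
    grain_yield_mg_ha: 10.7
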