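# Gallium-68 decay data (standard nuclear decay tables; positron branch 88.9%,
# mean beta+ energy 0.836 MeV, annihilation photon yield 2 x 0.889, plus the
# 1.077 MeV gamma at 3.22%). delta_np bundles all electron/positron energy.
name: Ga-68
half_life_min: 67.71
delta_np_mev: 0.740
photon_emissions:
  - [0.511, 1.778]
  - [1.077, 0.0322]
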