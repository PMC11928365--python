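# Full two-group study configuration for the `tsce` CLI.
# Usage: tsce --config examples/config.yaml --seed 1 --out out/ report
generator:
  groups:
    - {race: NHB, n: 8000, female_fraction: 0.638, entry_mean: 61.8,
       entry_sd: 9.08, p_never: 0.391, p_former: 0.381, p_current: 0.228}
    - {race: NHW, n: 8000, female_fraction: 0.539, entry_mean: 59.5,
       entry_sd: 9.08, p_never: 0.393, p_former: 0.439, p_current: 0.168}
  censor_window: 10.0
  seed: 1

model:
  # each free parameter may be shared, by_race, by_gender or by_race_gender
  sharing: {mu0: by_race_gender, g: by_race_gender,
            g_c: by_race_gender, mu1_c: by_race_gender}
  name: group_specific

candidates:
  - sharing: {mu0: shared, g: shared, g_c: shared, mu1_c: shared}
    name: shared
  - sharing: {mu0: by_race, g: by_race, g_c: by_race, mu1_c: by_race}
    name: by_race
  - sharing: {mu0: by_race_gender, g: by_race_gender,
              g_c: by_race_gender, mu1_c: by_race_gender}
    name: group_specific

sampler:
  n_starts: 3
  mcmc_steps: 3000
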