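# gppval

Validation pipeline for daily gross primary production (GPP) models against
eddy-covariance observations. The package bundles:

- **`photosynthesis`** — leaf-level C3 (Farquhar-type, minimum of light-,
  Rubisco- and triose-phosphate-limited rates) and C4 (minimum of three
  fixation capacities) gross photosynthesis with Q10 kinetics, plus
  big-leaf canopy scaling (Beer's-law light absorption, daylength
  integration) to daily GPP.
- **`eclue`** — a light-use-efficiency comparison model:
  GPP = ε_max · fPAR(NDVI) · PAR · min(T-stress, moisture-stress), with the
  moisture scalar LE/(LE+H) from the Bowen-ratio components.
- **`partitioning`** — "observed" GPP from NEE: a Lloyd–Taylor respiration
  law fitted to nighttime NEE, extrapolated to daytime temperature, minus
  daytime NEE.
- **`inversion`** — Metropolis–Hastings MCMC of the maximum carboxylation
  rate (Vcmax) against observed daily GPP (uniform prior, Gaussian
  likelihood), posterior-mode point estimates (highest-frequency bin), and
  per-PFT pooling with one-way ANOVA.
- **`metrics`** — R², RMSE, relative predictive error (RPE), per-biome
  aggregation, RPE threshold censuses, paired t-tests, and a toy
  area-weighted global upscaling.
- **`site_io`** / **`synth`** — tabular site-file IO with quality-flag
  gap filling of 8-day NDVI/LAI; synthetic sites with known truth
  (seasonal weather, flagged satellite series, NEE manufactured from a
  chosen true Vcmax); a packaged 62-site × 2-model performance fixture and
  the nine-entry PFT parameter catalogue.

## CLI

All stages are exposed through one entry point:

```sh
gppval simulate --site-id SYN-1 --latitude 35 --years 2 \
    --true-vcmax 40e-6 --seed 3 site.tsv      # site file + NDVI/LAI sidecars
gppval partition site.tsv site_obs.tsv        # NEE -> observed GPP
gppval forward site_obs.tsv site_fwd.tsv      # process-model GPP column
gppval eclue site_obs.tsv site_lue.tsv        # LUE-model GPP column
gppval validate site_fwd.tsv metrics.tsv      # R2 / RMSE / RPE vs gpp_obs
gppval invert site_obs.tsv chain.txt          # MCMC Vcmax inversion
gppval pool optima.tsv pooled.tsv             # per-PFT means + ANOVA
gppval report site_metrics.tsv summary.tsv    # per-biome aggregation
```

Site files are tab-separated UTF-8 with ISO dates and `# key: value`
metadata headers (site id, PFT, latitude); 8-day NDVI/LAI live in
`<stem>.ndvi.tsv` / `<stem>.lai.tsv` sidecars with a `reliable` flag
column.

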