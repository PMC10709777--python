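# Complete annotated pipeline configuration.
#
# Exactly one of `synthetic` or `inputs` must be present: `synthetic`
# generates a seeded vital-statistics panel; `inputs` points at existing
# delimited files (panel.csv with header
# county_id,age_group,year,births,preterm,early_preterm; an undirected
# adjacency edge list; an SVI table; optionally a county membership table).

output_dir: runs/demo        # all stage outputs + manifest.json land here
seed: 1                      # master seed: generator, MCMC, bootstrap
outcome: preterm             # preterm (<37 wk) or early_preterm (<34 wk)
reference_year: 2007         # age-standardization reference (default: first year)

synthetic:                   # see SyntheticConfig for every field
  n_rows: 8                  # lattice height  (counties = n_rows * n_cols)
  n_cols: 8
  years: [2007, 2008, 2009, 2010, 2011, 2012, 2013,
          2014, 2015, 2016, 2017, 2018, 2019]
  baseline_rate_per100: 12.6 # national preterm rate scale
  births_range: [50, 500]    # expected annual births per county-age cell
  spatial_sd: 0.15           # structured (ICAR) county effect scale
  heterogeneity_sd: 0.08     # unstructured county effect scale
  trend_sd: 0.008            # per-year sd of county log-linear slopes
  svi_correlation: 0.68      # corr(county log rate, overall SVI latent)

# inputs:                    # alternative to `synthetic`
#   panel: data/panel.csv
#   adjacency: data/adjacency.csv
#   svi: data/svi.csv
#   membership: data/membership.csv

mcmc:
  iterations: 5000
  burn_in: 2500
  thin: 5

bootstrap_B: 1000            # county-resampling replicates for gap/ratio CIs

filters:
  min_births: 100            # reliability rule: births per county-year
  min_births_per_age: 0      # >0 restricts to counties with >min births
                             # in every age group (age-specific analyses)
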