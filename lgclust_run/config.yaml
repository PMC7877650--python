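points_csv: null
domain_geojson: null
synthetic: null
r_min: 300.0
r_max: 10000.0
n_radii: 25
spacing: geometric
transform: log1p+zscore
method: clara
k: vote
k_range:
- 2
- 3
- 4
- 5
- 6
- 7
redundancy: false
redundancy_threshold: 0.05
morisita_m: 2
profile_radius: 4000.0
som_rows: 20
som_cols: 15
som_epochs: 30
hier_subsample: 5000
seed: 0
outdir: lgclust_run
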