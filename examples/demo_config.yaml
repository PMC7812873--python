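# Demo pipeline configuration: sgpartition run --config examples/demo_config.yaml
seed: 7
outdir: scratch/demo_run
model: power
n_grid: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
ks: [0, 5, 7, 25]
cells_per_construct: 200
spots_mean: 1000
cell_noise_concentration: 2000
predict_at: [27, 26, 3, 2]
invert_at: [50, 20]
sgseq_transcripts: 200
sgseq_depth: 500000
sgseq_replicates: 3
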