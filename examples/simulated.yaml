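# Full-scale simulated run: 4 cell types x 2 hemispheres x 6 replicates,
# ~10k background genes plus planted categories. Override outdir/seed on
# the command line: nvustroke run --config examples/simulated.yaml
outdir: out
seed: 1
simulation:
  n_background: 10000
  n_epam: 10
  n_induced: 5
  n_shutdown: 5
  n_up: 5
  n_down: 5
  n_opposite: 3
  n_markers: 20
  seed: 1
thresholds:
  min_reads: 10
  min_abs_log2fc: 0.585
  max_padj: 0.05
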