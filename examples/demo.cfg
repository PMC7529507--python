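# End-to-end demo: simulate a low-pass tumor-normal pair and call
# purity/ploidy.  Run from the repository root with:
#   puriploid run --config examples/demo.cfg --out-dir demo_out
seed: 7
out_dir: demo_out
sample: demo
purity: 0.65
n_chroms: 8
event_rate: 3.0
wgd: false
coverage: 0.5
bin_size: 100000
snps_per_mb: 150
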