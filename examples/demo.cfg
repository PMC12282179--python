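# Demo: simulate a small strain panel plus a mixed-community read sample,
# then run every stage end to end.  Run from the repository root:
#   crisprcomp run-all examples/demo.cfg
simulate = true
n_strains = 4
seed = 7
outdir = demo_output
min_identity = 0.80
pad = 32
power = 13,18,lnorm(2.7365304,0.6243374),exp(0.0323741),0.05; 31,9,exp(0.03865337),lnorm(1.5345364,0.6981095),0.05
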