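# Desk-scale design: small enough to run in minutes on one CPU.
communities:
  - Alaspungo
  - Yanacocha
n_replicates: 25
alpha_levels: [0.0, 1.0, 2.0, 3.0]
c_levels: [0.0, 1.0, 2.0, 3.0]
modes: [flattened, empirical]
variant: none
master_seed: 0
phenology_breadth: [1.5, 3.0]
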