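# Study-scale design: 11 communities x 250 replicates x 7 alpha x 7 c x 2
# modes = 269,500 simulations.  Long-running; use --resume for checkpointing.
communities:
  - Alaspungo
  - LasGralarias
  - Maquipucuna
  - MashpiCapuchin
  - MashpiLaguna
  - Sachatamia
  - SantaLuciaLower
  - SantaLuciaUpper
  - UnPocoDelChoco
  - Verdecocha
  - Yanacocha
n_replicates: 250
alpha_levels: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
c_levels: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
modes: [flattened, empirical]
variant: none
master_seed: 0
phenology_breadth: [1.5, 3.0]
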