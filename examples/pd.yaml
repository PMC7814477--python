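# Perceptual discrimination, 50-unit network, short training run.
task:
  name: perceptual_discrimination
  coherences: [0.3]
network:
  n_rec: 50
training:
  n_iterations: 300
  batch_size: 64
master_seed: 7
output_dir: runs/pd
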