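# Desk-scale end-to-end demo: renalscint run-all --config examples/demo.yaml
# Roughly 10 minutes on one CPU; outputs under ./demo_run.
out_dir: demo_run
seed: 7
n_cases: 20
image_shape: [64, 64]
n_frames: 10
kidney_mean_counts_per_frame: 21.0
background_mean_counts_per_frame: 2.0
uptake_range: [0.14, 0.28]
motion_max_px: 2.0
motion_max_deg: 1.0
register: true
registration_iterations: 100
split_fractions: [0.7, 0.15, 0.15]
pairs_per_case: 8
architectures: [DnCNN, Win5RB, ResUnet]
arch_overrides:
  DnCNN: {n_filters: 6, dncnn_units: 15}
  Win5RB: {n_filters: 4}
  ResUnet: {resunet_level_filters: [6, 12, 24], resunet_bridge_filters: 48}
train_config: {learning_rate: 0.001, max_epochs: 8, batch_size: 8}
attenuation_k: 1.0
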