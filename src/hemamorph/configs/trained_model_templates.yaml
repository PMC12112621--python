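# Reference hyperparameter templates for externally trained models.
#
# These models are NOT trained or bundled here; the templates record the
# training protocols so an externally trained detector/backbone/geometry
# model can be reproduced and then plugged in behind the package's
# contracts (detector plug-in, 2048-d deep-feature contract, rule engine).

detector_yolo:
  learning_rate: 0.001
  batch_size: 16
  optimizer: Adam
  epochs: 200
  momentum: 0.9
  weight_decay: 0.0005

cnn_mono_poly:
  learning_rate: 0.001
  batch_size: 32
  epochs: 50
  optimizer: Adam
  loss: binary_cross_entropy
  activation: relu_hidden_sigmoid_output
  dropout: 0.5
  conv_layers: 3
  kernel: [3, 3]
  pooling: max_2x2
  early_stopping_patience: 5

resnet50_finetune:
  pretrained: imagenet
  learning_rate: 0.0001
  batch_size: 32
  epochs: 200
  optimizer: Adam
  loss: categorical_cross_entropy
  dropout: 0.5
  trainable_fraction: 0.5
  early_stopping_patience: 10

zero_shot:
  learning_rate: 0.001
  batch_size: 16
  epochs: 100
  optimizer: Adam
  loss: cross_entropy
  embedding_dimension: 300
  dropout: 0.3
  l2_lambda: 0.01
  early_stopping_patience: 5

spherical_scattering_geometry:
  # rotation-equivariant spherical scattering learner; the in-package
  # geometric rule engine realizes the stated shape criteria instead
  learning_rate: 0.0005
  batch_size: 32
  epochs: 150
  optimizer: Adam
  loss: mean_squared_error
  scattering_layers: 3
  wavelet_filters: 8
  dropout: 0.4
  l2_lambda: 0.01
  early_stopping_patience: 8
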