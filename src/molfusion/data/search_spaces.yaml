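# Per-family randomized-search distributions.
# Encoding: {loguniform: [lo, hi]}, {uniform: [lo, hi]}, {randint: [lo, hi)},
# or a plain list of categorical choices.
SVC:
  C: {loguniform: [0.01, 1000.0]}
  kernel: [rbf, linear]
  gamma: [scale, auto]
RF:
  n_estimators: {randint: [100, 1000]}
  max_depth: {randint: [2, 30]}
  max_features: [sqrt, log2]
KNN:
  n_neighbors: {randint: [3, 16]}
  weights: [uniform, distance]
DT:
  max_depth: {randint: [2, 30]}
  min_samples_split: {randint: [2, 20]}
  criterion: [gini, entropy]
GBDT:
  n_estimators: {randint: [50, 500]}
  learning_rate: {loguniform: [0.01, 1.0]}
  max_depth: {randint: [2, 8]}
ABDT:
  n_estimators: {randint: [50, 500]}
  learning_rate: {loguniform: [0.01, 1.0]}
GNB:
  var_smoothing: {loguniform: [1.0e-11, 1.0e-7]}
SGD:
  alpha: {loguniform: [1.0e-6, 0.01]}
  loss: [hinge, log_loss]
  penalty: [l2, l1]
LR:
  C: {loguniform: [0.01, 1000.0]}
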