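# Default hyperparameter grids for grid_search, one table per learner.
# Every grid is user-overridable via `train --grid my_grids.toml`.

[lightgbm]
learning_rate = [0.01, 0.05, 0.1]
num_leaves = [15, 31, 63]
n_estimators = [100, 300, 500]
min_child_samples = [5, 20]

[rf]
n_estimators = [100, 300, 500]
max_features = ["sqrt", 0.5]
min_samples_leaf = [1, 3]

[knn]
n_neighbors = [3, 5, 7, 11]
weights = ["uniform", "distance"]

[mlr]
# ordinary least squares has no tunable hyperparameters

[svm]
C = [0.1, 1.0, 10.0]
epsilon = [0.05, 0.1, 0.2]
gamma = ["scale", "auto"]

[adaboost]
n_estimators = [50, 100, 300]
learning_rate = [0.05, 0.1, 1.0]

[xgboost]
learning_rate = [0.01, 0.05, 0.1]
max_depth = [3, 5, 7]
n_estimators = [100, 300, 500]

[ann]
alpha = [0.0001, 0.001, 0.01]
learning_rate_init = [0.001, 0.01]
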