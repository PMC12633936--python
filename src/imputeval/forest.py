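"""A thin bagged-trees random forest over scikit-learn decision trees.

The imputation engines fit tens of thousands of small forests per benchmark
run; this wrapper exposes exactly what they need -- bootstrap bagging,
per-split feature subsampling, out-of-the-box ``apply``/leaf access for
donor draws -- while skipping the per-fit validation overhead of the
high-level ensemble estimators (which dominates runtime at these problem
sizes). Feature matrices are float32 C-order, which is what the tree code
consumes natively.
"""

from __future__ import annotations

import numpy as np
from sklearn import config_context
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

__all__ = ["RandomForest"]


class RandomForest:
    """Bootstrap-bagged CART forest (regression or classification).

    Parameters
    ----------
    ntree : number of trees.
    max_features : features considered per split (mtry).
    min_leaf : minimum samples per leaf.
    rng : numpy Generator; drives bootstrap draws and tree seeds.
    classify : fit classification trees (majority-vote predict).
    """

    def __init__(
        self,
        ntree: int,
        max_features: int,
        min_leaf: int,
        rng: np.random.Generator,
        classify: bool = False,
    ) -> None:
        self.ntree = ntree
        self.max_features = max_features
        self.min_leaf = min_leaf
        self.rng = rng
        self.classify = classify
        self.trees: list = []

    @staticmethod
    def as_features(X: np.ndarray) -> np.ndarray:
        return np.ascontiguousarray(X, dtype=np.float32)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RandomForest":
        n = X.shape[0]
        cls = DecisionTreeClassifier if self.classify else DecisionTreeRegressor
        # one legacy RandomState drives every tree's split randomness; its
        # seed comes from the forest rng, so fits stay fully deterministic
        split_rs = np.random.RandomState(int(self.rng.integers(0, 2**31 - 1)))
        self.trees = []
        # parameter validation dominates the cost of these very small fits
        with config_context(skip_parameter_validation=True, assume_finite=True):
            for _ in range(self.ntree):
                idx = self.rng.integers(0, n, size=n)  # bootstrap with replacement
                tree = cls(
                    max_features=self.max_features,
                    min_samples_leaf=self.min_leaf,
                    random_state=split_rs,
                )
                tree.fit(X[idx], y[idx], check_input=False)
                self.trees.append(tree)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.classify:
            votes = np.stack([t.predict(X, check_input=False) for t in self.trees])
            # majority vote; ties broken by smallest encoded label
            out = []
            for col in votes.T:
                vals, counts = np.unique(col, return_counts=True)
                out.append(vals[np.argmax(counts)])
            return np.asarray(out)
        preds = np.zeros(X.shape[0])
        for t in self.trees:
            preds += t.predict(X, check_input=False)
        return preds / self.ntree

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index of each row in each tree, shape (n, ntree)."""
        return np.column_stack([t.tree_.apply(X) for t in self.trees])

    def node_donors(self, tree_index: int, x_row: np.ndarray, X_obs: np.ndarray) -> np.ndarray:
        """Indices of observed rows sharing the deepest non-empty node with
        ``x_row`` in one tree (ancestor fallback for empty leaves)."""
        tree = self.trees[tree_index]
        path_row = tree.decision_path(x_row.reshape(1, -1)).toarray().ravel().astype(bool)
        path_obs = tree.decision_path(X_obs).toarray().astype(bool)
        nodes = np.nonzero(path_row)[0][::-1]  # leaf upward to the root
        for node in nodes:
            members = np.nonzero(path_obs[:, node])[0]
            if members.size:
                return members
        return np.arange(X_obs.shape[0])
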