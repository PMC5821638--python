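"""Rule-based model tree: piecewise multivariate-linear regression with
smoothed predictions.

An M5-style learner in the spirit of Cubist: recursive binary splitting on
an SD-reduction criterion, a multivariate least-squares model at every node,
error-based pruning, and Quinlan smoothing at prediction time (a leaf
prediction is blended with its ancestors' linear models on the way back up,
weighted by subtree size against a smoothing constant). Predictions are
finally clamped to the training response range extended by a small
extrapolation cap, guarding against runaway linear extrapolation.

Committee support (boosting-style response adjustment, predictions averaged)
is available but defaults to a single member.

The learner is deterministic: split ties are broken by lowest predictor
index, then lowest threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class TrainConfig:
    """Model-tree hyperparameters.

    min_leaf_size should be at least 2*(n_predictors + 1) so leaf linear
    models stay overdetermined; smoothing_k is Quinlan's blending constant;
    extrapolation_cap extends the response clamp by that fraction of the
    training range on each side; sd_stop_frac stops splitting once a node's
    response SD falls below that fraction of the root SD.
    """

    min_leaf_size: int = 20
    max_depth: int = 12
    smoothing: bool = True
    smoothing_k: float = 15.0
    n_committees: int = 1
    extrapolation_cap: float = 0.1
    sd_stop_frac: float = 0.05
    seed: int | None = None

    def __post_init__(self):
        if self.min_leaf_size < 2:
            raise ValueError("min_leaf_size must be >= 2")
        if self.n_committees < 1:
            raise ValueError("n_committees must be >= 1")
        if self.extrapolation_cap < 0:
            raise ValueError("extrapolation_cap must be >= 0")


def _fit_linear(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares coefficients [intercept, slopes...]; rank-deficient
    designs resolved by the minimum-norm solution."""
    a = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    return coef


def _linear_predict(coef: np.ndarray, x: np.ndarray) -> np.ndarray:
    return coef[0] + x @ coef[1:]


class _Node:
    __slots__ = ("coef", "n", "feature", "threshold", "left", "right")

    def __init__(self, coef, n, feature=None, threshold=None, left=None, right=None):
        self.coef = coef
        self.n = n
        self.feature = feature
        self.threshold = threshold
        self.left = left
        self.right = right

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def to_dict(self) -> dict:
        d = {"coef": [float(c) for c in self.coef], "n": int(self.n)}
        if not self.is_leaf:
            d["feature"] = int(self.feature)
            d["threshold"] = float(self.threshold)
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "_Node":
        node = cls(np.asarray(d["coef"], dtype=float), d["n"])
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive SD-reduction (SSE) split search with prefix sums.

    Returns (feature, threshold, sse) of the best admissible split, or None.
    Ties: lowest feature index, then lowest threshold.
    """
    n, p = x.shape
    if n < 2 * min_leaf:
        return None
    best = None
    for j in range(p):
        order = np.argsort(x[:, j], kind="stable")
        xs = x[order, j]
        ys = y[order]
        cum = np.cumsum(ys)
        cum2 = np.cumsum(ys * ys)
        tot, tot2 = cum[-1], cum2[-1]
        i = np.arange(min_leaf, n - min_leaf + 1)       # left sizes
        valid = xs[i - 1] < xs[i]
        if not valid.any():
            continue
        i = i[valid]
        left_sse = cum2[i - 1] - cum[i - 1] ** 2 / i
        right_n = n - i
        right_sum = tot - cum[i - 1]
        right_sse = (tot2 - cum2[i - 1]) - right_sum**2 / right_n
        sse = left_sse + right_sse
        k = int(np.argmin(sse))
        cand = (float(sse[k]), j, float((xs[i[k] - 1] + xs[i[k]]) / 2.0))
        if best is None or cand[0] < best[0] - 1e-12 * max(1.0, abs(best[0])):
            best = cand
    if best is None:
        return None
    sse, j, thr = best
    return j, thr, sse


class ModelTree:
    """Fitted rule-based piecewise-linear regressor.

    Use :meth:`fit` to train; :meth:`predict` applies smoothing and response
    clamping. :meth:`rules` exports the rule list (path conditions plus leaf
    coefficients) for audit.
    """

    def __init__(self, config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self._roots: list[_Node] = []
        self.y_min: float | None = None
        self.y_max: float | None = None
        self.n_features: int | None = None

    # ------------------------------------------------------------------ fit
    def fit(self, x: np.ndarray, y: np.ndarray) -> "ModelTree":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y must have matching rows")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValueError("X and y must be finite")
        if x.shape[0] < self.config.min_leaf_size:
            raise ValueError("fewer rows than min_leaf_size")
        self.n_features = x.shape[1]
        self.y_min = float(y.min())
        self.y_max = float(y.max())
        self._roots = []
        target = y.copy()
        for _ in range(self.config.n_committees):
            root = self._build(x, target, depth=0, root_sd=float(target.std()))
            self._prune(root, x, target)
            self._roots.append(root)
            if len(self._roots) < self.config.n_committees:
                pred = self._predict_tree(root, x)
                target = 2.0 * y - pred     # boost: next member corrects residual
        return self

    def _build(self, x: np.ndarray, y: np.ndarray, depth: int, root_sd: float) -> _Node:
        coef = _fit_linear(x, y)
        node = _Node(coef, len(y))
        if (depth >= self.config.max_depth
                or len(y) < 2 * self.config.min_leaf_size
                or y.std() <= self.config.sd_stop_frac * root_sd):
            return node
        split = _best_split(x, y, self.config.min_leaf_size)
        if split is None:
            return node
        j, thr, sse = split
        parent_sse = float(((y - y.mean()) ** 2).sum())
        if parent_sse - sse <= 1e-12 * max(1.0, parent_sse):
            return node
        mask = x[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.left = self._build(x[mask], y[mask], depth + 1, root_sd)
        node.right = self._build(x[~mask], y[~mask], depth + 1, root_sd)
        return node

    def _prune(self, node: _Node, x: np.ndarray, y: np.ndarray) -> float:
        """Bottom-up error-based pruning; returns the subtree's adjusted
        training error (MAE with an (n+v)/(n-v) optimism penalty)."""
        n, p = x.shape
        v = p + 1
        penalty = (n + v) / (n - v) if n > v else 10.0
        node_err = float(np.abs(y - _linear_predict(node.coef, x)).mean()) * penalty
        if node.is_leaf:
            return node_err
        mask = x[:, node.feature] <= node.threshold
        left_err = self._prune(node.left, x[mask], y[mask])
        right_err = self._prune(node.right, x[~mask], y[~mask])
        subtree_err = (mask.sum() * left_err + (~mask).sum() * right_err) / n
        if node_err <= subtree_err:
            node.left = node.right = None
            node.feature = node.threshold = None
            return node_err
        return subtree_err

    # -------------------------------------------------------------- predict
    def predict(self, x: np.ndarray) -> np.ndarray:
        if self.y_min is None:
            raise ValueError("model is not fitted")
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} predictor columns, got {x.shape[1]}")
        preds = np.mean([self._predict_tree(root, x) for root in self._roots], axis=0)
        span = self.y_max - self.y_min
        cap = self.config.extrapolation_cap * span
        return np.clip(preds, self.y_min - cap, self.y_max + cap)

    def _predict_tree(self, root: _Node, x: np.ndarray) -> np.ndarray:
        out = np.empty(x.shape[0])
        self._predict_node(root, x, np.arange(x.shape[0]), out)
        return out

    def _predict_node(self, node: _Node, x: np.ndarray, idx: np.ndarray,
                      out: np.ndarray) -> None:
        if node.is_leaf:
            out[idx] = _linear_predict(node.coef, x[idx])
            return
        mask = x[idx, node.feature] <= node.threshold
        left_idx, right_idx = idx[mask], idx[~mask]
        child_n = np.where(mask, node.left.n, node.right.n).astype(float)
        if left_idx.size:
            self._predict_node(node.left, x, left_idx, out)
        if right_idx.size:
            self._predict_node(node.right, x, right_idx, out)
        if self.config.smoothing:
            k = self.config.smoothing_k
            node_pred = _linear_predict(node.coef, x[idx])
            out[idx] = (child_n * out[idx] + k * node_pred) / (child_n + k)

    # ----------------------------------------------------------- inspection
    def rules(self) -> list[dict]:
        """Flat rule list: one entry per leaf with its path conditions and
        linear-model coefficients."""
        out: list[dict] = []

        def walk(node: _Node, conditions: list[tuple[int, str, float]]):
            if node.is_leaf:
                out.append({
                    "conditions": [
                        {"feature": f, "op": op, "threshold": t}
                        for f, op, t in conditions
                    ],
                    "coef": [float(c) for c in node.coef],
                    "n": int(node.n),
                })
                return
            walk(node.left, conditions + [(node.feature, "<=", node.threshold)])
            walk(node.right, conditions + [(node.feature, ">", node.threshold)])

        for root in self._roots:
            walk(root, [])
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "config": asdict(self.config),
            "y_min": self.y_min, "y_max": self.y_max,
            "n_features": self.n_features,
            "trees": [root.to_dict() for root in self._roots],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ModelTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        model = cls(TrainConfig(**doc["config"]))
        model.y_min = doc["y_min"]
        model.y_max = doc["y_max"]
        model.n_features = doc["n_features"]
        model._roots = [_Node.from_dict(t) for t in doc["trees"]]
        return model


class PassthroughModel:
    """Identity learner: predicts its single predictor column unchanged.

    The reference oracle for Monte-Carlo propagation tests — with predictor
    equal to response, ensemble spread reflects the injected field error
    alone, so per-pixel relative uncertainty converges to 196 * eps_field/100
    percent.
    """

    def fit(self, x: np.ndarray, y: np.ndarray) -> "PassthroughModel":
        return self

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("PassthroughModel expects a single predictor column")
            x = x[:, 0]
        return x.copy()
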