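"""Classifier training: repeated stratified CV, grid refinement, refit.

Three classifier families are supported over the binary n-gram features:
a linear support vector machine (tuned over its cost/regularization
parameter), a random forest (maximum depth, number of trees, maximum
features per split), and a multilayer perceptron (hidden layer sizes and
alpha/L2 regularization).

Hyperparameters are tuned by 3-times-repeated, stratified 10-fold
cross-validation scored by F (harmonic mean of PPV and sensitivity;
accuracy would be dominated by the ~97% non-overdose class).  Tuning is
an iterative grid search: evaluate an initial grid, then re-grid around
the best point — geometric neighbors for continuous hyperparameters,
integer steps for discrete ones, extending outward when the best value
sits on a grid edge — until the improvement falls below a tolerance with
the best point interior, or a round cap is reached.  The final model is
refit on all training rows at the selected values.

Ties between grid points are broken toward the least complex model
(lowest cost, shallowest/smallest forest, smallest hidden layer, largest
alpha) so tuning is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import joblib
import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import ParameterGrid, RepeatedStratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from .certificates import FieldSet
from .errors import ConfigurationError, ValidationError
from .features import Vocabulary

__all__ = [
    "CVConfig",
    "DEFAULT_GRIDS",
    "ModelSpec",
    "TrainedModel",
    "cross_validate",
    "refine_grid",
    "train_final",
    "tune",
]

FAMILIES = ("linear_svm", "random_forest", "mlp")

_ALLOWED_KEYS = {
    "linear_svm": {"cost"},
    "random_forest": {"max_depth", "n_trees", "max_features"},
    "mlp": {"hidden_layer_sizes", "alpha"},
}

#: Starting grids; every value is overridable via configuration.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "linear_svm": {"cost": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {
        "n_trees": [100, 300],
        "max_depth": [8, 16, None],
        "max_features": ["sqrt", 0.1],
    },
    "mlp": {"hidden_layer_sizes": [(32,), (64,)], "alpha": [1e-4, 1e-2]},
}

# Hyperparameters refined on a multiplicative scale.
_GEOMETRIC = {"cost", "alpha"}
# Hyperparameters refined by integer steps.
_INTEGER = {"n_trees", "max_depth"}


@dataclass(frozen=True)
class ModelSpec:
    """A classifier family plus its hyperparameter search grid."""

    family: str
    grid: Mapping[str, Sequence[Any]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        extra = set(self.grid) - _ALLOWED_KEYS[self.family]
        if extra:
            raise ValidationError(
                f"grid keys {sorted(extra)} not tunable for {self.family}; "
                f"allowed: {sorted(_ALLOWED_KEYS[self.family])}"
            )
        object.__setattr__(
            self, "grid", {k: list(v) for k, v in self.grid.items()}
        )

    @classmethod
    def with_default_grid(cls, family: str) -> "ModelSpec":
        return cls(family, DEFAULT_GRIDS[family])


@dataclass(frozen=True)
class CVConfig:
    """Stratified repeated k-fold settings; scoring is always the F-score."""

    k: int = 10
    repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.repeats < 1:
            raise ValidationError("need k >= 2 and repeats >= 1")


def _as_key(params: Mapping[str, Any]) -> tuple:
    return tuple(sorted((k, tuple(v) if isinstance(v, (list, tuple)) else v) for k, v in params.items()))


def _from_key(key: tuple) -> dict:
    return {k: v for k, v in key}


def build_estimator(family: str, params: Mapping[str, Any], seed: int):
    """Instantiate the scikit-learn estimator for one grid point."""
    if family == "linear_svm":
        return LinearSVC(C=params.get("cost", 1.0), random_state=seed, max_iter=10000)
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_trees", 100),
            max_depth=params.get("max_depth"),
            max_features=params.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
    if family == "mlp":
        hidden = params.get("hidden_layer_sizes", (32,))
        return MLPClassifier(
            hidden_layer_sizes=tuple(hidden),
            alpha=params.get("alpha", 1e-4),
            random_state=seed,
            max_iter=200,
        )
    raise ValidationError(f"unknown family {family!r}")


def _check_labels(y: np.ndarray, k: int) -> None:
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ConfigurationError("training labels must contain both classes")
    if min(n_pos, n_neg) < k:
        raise ConfigurationError(
            f"minority class has {min(n_pos, n_neg)} records, fewer than k={k} folds; "
            "use a smaller k"
        )


def cross_validate(
    X: sp.spmatrix | np.ndarray,
    y: Sequence[bool],
    spec: ModelSpec,
    cv: CVConfig = CVConfig(),
) -> dict[tuple, float]:
    """Mean held-out F-score for every grid point.

    Returns a mapping from a hashable grid-point key (sorted
    ``(name, value)`` pairs) to the mean F over ``k x repeats`` folds.
    Deterministic given ``cv.seed``: the fold assignment, the estimator
    seeds, and therefore the scores are all reproducible.
    """
    y = np.asarray(y, dtype=bool)
    if X.shape[0] != len(y):
        raise ValidationError(f"X has {X.shape[0]} rows but y has {len(y)} labels")
    _check_labels(y, cv.k)
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.k, n_repeats=cv.repeats, random_state=cv.seed
    )
    splits = list(splitter.split(np.zeros(len(y)), y))
    results: dict[tuple, float] = {}
    grid = spec.grid or {}
    for params in ParameterGrid({k: list(v) for k, v in grid.items()}) if grid else [{}]:
        est_proto = build_estimator(spec.family, params, cv.seed)
        scores = []
        for train_idx, test_idx in splits:
            est = clone_estimator(est_proto)
            est.fit(X[train_idx], y[train_idx])
            pred = est.predict(X[test_idx])
            scores.append(f1_score(y[test_idx], pred, zero_division=0))
        results[_as_key(params)] = float(np.mean(scores))
    return results


def clone_estimator(est):
    from sklearn.base import clone

    return clone(est)


def _complexity(family: str, params: Mapping[str, Any]) -> tuple:
    """Sort key: smaller means simpler; used to break score ties."""
    if family == "linear_svm":
        return (params.get("cost", 1.0),)
    if family == "random_forest":
        depth = params.get("max_depth")
        return (
            math.inf if depth is None else depth,
            params.get("n_trees", 0),
            str(params.get("max_features", "")),
        )
    hidden = params.get("hidden_layer_sizes", (0,))
    return (sum(hidden), -params.get("alpha", 0.0))


def best_point(results: Mapping[tuple, float], spec: ModelSpec) -> tuple[dict, float]:
    """Highest-scoring grid point; ties go to the least complex model."""
    if not results:
        raise ValidationError("no cross-validation results to choose from")
    best_score = max(results.values())
    tied = [k for k, v in results.items() if abs(v - best_score) < 1e-12]
    tied.sort(key=lambda k: (_complexity(spec.family, _from_key(k)), repr(k)))
    return _from_key(tied[0]), best_score


def _refine_geometric(values: list[float], best: float) -> list[float]:
    values = sorted(values)
    i = values.index(best)
    if len(values) == 1:
        ratio = 10.0
    elif i == 0:
        ratio = values[1] / values[0]
    else:
        ratio = values[i] / values[i - 1]
    step = math.sqrt(ratio)
    if step <= 1.05:  # converged to resolution
        return [best]
    out = [best / step, best, best * step]
    if i == 0 and len(values) > 1:
        out.insert(0, best / ratio)
    if i == len(values) - 1 and len(values) > 1:
        out.append(best * ratio)
    if len(values) == 1:
        out = [best / step, best, best * step]
    return [round(v, 12) for v in out]


def _refine_integer(values: list, best) -> list:
    numeric = sorted(v for v in values if v is not None)
    if best is None:
        return [None]
    i = numeric.index(best)
    if len(numeric) == 1:
        gap = max(1, best // 2)
    elif i == 0:
        gap = numeric[1] - numeric[0]
    else:
        gap = numeric[i] - numeric[i - 1]
    half = gap // 2
    if half == 0 and len(numeric) > 1:
        return [best]
    out = {best}
    if half:
        out.update({best - half, best + half})
    if len(numeric) > 1:
        if i == 0:
            out.add(best - gap)
        if i == len(numeric) - 1:
            out.add(best + gap)
    return sorted(v for v in out if v >= 1)


def refine_grid(
    results: Mapping[tuple, float],
    spec: ModelSpec,
    prev_best_score: Optional[float] = None,
    tol: float = 1e-3,
) -> ModelSpec:
    """Next search grid, bracketing the best point of ``results``.

    Continuous hyperparameters get geometric neighbors (half a decade by
    default), integer ones get half-gap steps; a best value on a grid
    edge extends the grid outward so the optimum can become interior.
    Categorical values (e.g. ``max_features`` choices, ``None`` depth)
    are fixed at the best value.  If ``prev_best_score`` is supplied and
    the best point is interior with improvement below ``tol``, the spec
    is returned unchanged, signalling termination.
    """
    params, score = best_point(results, spec)
    if not spec.grid:
        return spec
    interior = _all_interior(spec, params)
    if prev_best_score is not None and interior and score - prev_best_score < tol:
        return spec
    new_grid: dict[str, list] = {}
    for name, values in spec.grid.items():
        best = params[name]
        if name in _GEOMETRIC and all(isinstance(v, (int, float)) for v in values):
            new_grid[name] = _refine_geometric([float(v) for v in values], float(best))
        elif name in _INTEGER:
            new_grid[name] = _refine_integer(list(values), best)
        elif name == "hidden_layer_sizes" and all(
            isinstance(v, (tuple, list)) and len(v) == 1 for v in values
        ):
            widths = _refine_integer([v[0] for v in values], best[0])
            new_grid[name] = [(w,) for w in widths]
        else:
            new_grid[name] = [best]
    return ModelSpec(spec.family, new_grid)


def _all_interior(spec: ModelSpec, params: Mapping[str, Any]) -> bool:
    for name, values in spec.grid.items():
        numeric = sorted(v for v in values if isinstance(v, (int, float)))
        best = params[name]
        if name == "hidden_layer_sizes" and all(
            isinstance(v, (tuple, list)) and len(v) == 1 for v in values
        ):
            numeric = sorted(v[0] for v in values)
            best = best[0]
        if not isinstance(best, (int, float)) or len(numeric) <= 1:
            continue
        if best in (numeric[0], numeric[-1]):
            return False
    return True


def tune(
    X,
    y,
    spec: ModelSpec,
    cv: CVConfig = CVConfig(),
    max_rounds: int = 5,
    tol: float = 1e-3,
) -> tuple[dict, float, list[dict]]:
    """Iterative grid search; returns (best params, best F, round history)."""
    history: list[dict] = []
    prev_best: Optional[float] = None
    best_params, best_score = {}, -1.0
    current = spec
    for round_no in range(max_rounds):
        results = cross_validate(X, y, current, cv)
        params, score = best_point(results, current)
        history.append({"round": round_no, "grid": current.grid, "best": params, "f": score})
        if score > best_score:
            best_params, best_score = params, score
        refined = refine_grid(results, current, prev_best_score=prev_best, tol=tol)
        if refined.grid == current.grid:
            break
        prev_best = score
        current = refined
    return best_params, best_score, history


@dataclass
class TrainedModel:
    """A refit classifier plus everything needed to apply it coherently."""

    family: str
    params: dict
    estimator: Any
    vocabulary: Optional[Vocabulary] = None
    field_set: Optional[FieldSet] = None
    config_hash: str = ""

    def predict(self, X) -> np.ndarray:
        self._check_width(X)
        if X.shape[0] == 0:
            return np.zeros(0, dtype=bool)
        return np.asarray(self.estimator.predict(X), dtype=bool)

    def decision_scores(self, X) -> Optional[np.ndarray]:
        """Margin / positive-class probability where the family has one."""
        self._check_width(X)
        if X.shape[0] == 0:
            return np.zeros(0)
        if hasattr(self.estimator, "decision_function"):
            return np.asarray(self.estimator.decision_function(X))
        if hasattr(self.estimator, "predict_proba"):
            return np.asarray(self.estimator.predict_proba(X))[:, 1]
        return None

    def _check_width(self, X) -> None:
        if self.vocabulary is not None and X.shape[1] != self.vocabulary.size:
            raise ValidationError(
                f"feature matrix has {X.shape[1]} columns but the model's "
                f"vocabulary has {self.vocabulary.size}"
            )

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "family": self.family,
                "params": self.params,
                "estimator": self.estimator,
                "vocabulary": self.vocabulary,
                "field_set": self.field_set.value if self.field_set else None,
                "config_hash": self.config_hash,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = joblib.load(path)
        return cls(
            family=d["family"],
            params=d["params"],
            estimator=d["estimator"],
            vocabulary=d["vocabulary"],
            field_set=FieldSet(d["field_set"]) if d["field_set"] else None,
            config_hash=d.get("config_hash", ""),
        )


def config_hash(payload: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]


def train_final(
    X,
    y,
    family: str,
    params: Mapping[str, Any],
    seed: int = 0,
    vocabulary: Optional[Vocabulary] = None,
    field_set: Optional[FieldSet] = None,
    cfg_hash: str = "",
) -> TrainedModel:
    """Refit on all training rows at the chosen hyperparameter values."""
    y = np.asarray(y, dtype=bool)
    if int(y.sum()) in (0, len(y)):
        raise ConfigurationError("training labels must contain both classes")
    est = build_estimator(family, params, seed)
    est.fit(X, y)
    return TrainedModel(family, dict(params), est, vocabulary, field_set, cfg_hash)
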