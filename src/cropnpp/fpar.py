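"""FPAR retrieval: feature selection, CNN and tree regressors, and the
classic empirical NDVI/RVI stretch.

The improved retrieval chain is: 15 vegetation indices -> min-max
feature normalization -> recursive feature elimination (RFE) ranking ->
1-D CNN regression to FPAR. Gradient-boosted tree baselines (GBDT via
scikit-learn, XGBoost) share the same split protocol for comparison.

The classic light-use-efficiency approach instead stretches NDVI and the
simple ratio (RVI) linearly between scene-level bounds and averages the
two; it is retained as the built-in baseline.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold, cross_val_score

from .errors import DegenerateBoundsError, FeatureMismatchError, TrainingError
from .grids import Grid
from .indices import IndexCube, INDEX_NAMES
from .metrics import EvalReport, evaluate
from .nn import Cnn1DRegressor


# ---------------------------------------------------------------------------
# containers


@dataclass
class FeatureMatrix:
    """Samples-by-indices table with optional per-feature min-max scaling."""

    values: np.ndarray
    feature_names: list[str]
    scaling: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length differs from column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def select(self, names: list[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        scaling = ({n: self.scaling[n] for n in names} if self.scaling else None)
        return FeatureMatrix(self.values[:, idx], list(names), scaling)


def validate_fpar(values) -> np.ndarray:
    """Validate an FPAR sample vector: finite, within [0, 1]."""
    v = np.asarray(values, dtype=float).ravel()
    if not np.isfinite(v).all():
        raise ValueError("FPAR vector contains non-finite values")
    if (v < 0).any() or (v > 1).any():
        raise ValueError("FPAR values must lie in [0, 1]")
    return v


def normalize_features(m: FeatureMatrix) -> FeatureMatrix:
    """Min-max normalize each feature to [0, 1], recording the scaling.

    Constant features cannot be scaled and are dropped with a warning.
    """
    keep, scaling = [], {}
    for j, name in enumerate(m.feature_names):
        lo, hi = float(m.values[:, j].min()), float(m.values[:, j].max())
        if hi <= lo:
            warnings.warn(f"dropping constant feature {name!r}", stacklevel=2)
            continue
        keep.append(j)
        scaling[name] = (lo, hi)
    names = [m.feature_names[j] for j in keep]
    vals = np.empty((m.n_samples, len(keep)))
    for out_j, j in enumerate(keep):
        lo, hi = scaling[names[out_j]]
        vals[:, out_j] = (m.values[:, j] - lo) / (hi - lo)
    return FeatureMatrix(vals, names, scaling)


def apply_scaling(values: np.ndarray, names: list[str],
                  scaling: dict[str, tuple[float, float]]) -> np.ndarray:
    """Apply a previously recorded min-max scaling to new data."""
    out = np.empty_like(np.asarray(values, dtype=float))
    for j, n in enumerate(names):
        lo, hi = scaling[n]
        out[:, j] = (values[:, j] - lo) / (hi - lo)
    return out


def invert_scaling(values: np.ndarray, names: list[str],
                   scaling: dict[str, tuple[float, float]]) -> np.ndarray:
    out = np.empty_like(np.asarray(values, dtype=float))
    for j, n in enumerate(names):
        lo, hi = scaling[n]
        out[:, j] = values[:, j] * (hi - lo) + lo
    return out


# ---------------------------------------------------------------------------
# recursive feature elimination


@dataclass
class RfeResult:
    """Feature ranking from recursive elimination (1 = most important)."""

    ranking: dict[str, int]
    selected: list[str]
    scores: list[float]  # cross-validated R^2 at each elimination step


def rfe_rank(m: FeatureMatrix, y, n_keep: int, seed: int = 42,
             cv: int = 5, estimator_factory=None) -> RfeResult:
    """Rank features by recursive elimination with a boosted-tree ranker.

    At each step a gradient-boosted regressor is fit on the remaining
    features, the cross-validated R^2 is recorded, and the feature with
    the smallest impurity importance is removed, one per step, until
    ``n_keep`` remain. Survivors are ranked 1..n_keep by their final-fit
    importance; eliminated features continue the ranking in reverse
    elimination order.
    """
    y = validate_fpar(y)
    n_feat = len(m.feature_names)
    if not 1 <= n_keep <= n_feat:
        raise ValueError(f"n_keep must be in [1, {n_feat}], got {n_keep}")
    if y.size != m.n_samples:
        raise ValueError("target length differs from sample count")
    if estimator_factory is None:
        estimator_factory = lambda: GradientBoostingRegressor(  # noqa: E731
            n_estimators=100, max_depth=3, random_state=seed)

    remaining = list(m.feature_names)
    eliminated: list[str] = []
    scores: list[float] = []
    importances: dict[str, float] = {}
    while True:
        sub = m.select(remaining)
        est = estimator_factory()
        if cv and cv > 1:
            cv_split = KFold(n_splits=cv, shuffle=True, random_state=seed)
            scores.append(float(np.mean(
                cross_val_score(estimator_factory(), sub.values, y,
                                cv=cv_split, scoring="r2"))))
        est.fit(sub.values, y)
        imp = np.asarray(est.feature_importances_, dtype=float)
        importances = dict(zip(remaining, imp))
        if len(remaining) <= n_keep:
            break
        drop = remaining[int(np.argmin(imp))]
        eliminated.append(drop)
        remaining.remove(drop)

    # survivors ordered by final importance, descending
    selected = sorted(remaining, key=lambda n: -importances[n])
    ranking = {n: i + 1 for i, n in enumerate(selected)}
    for i, n in enumerate(reversed(eliminated)):
        ranking[n] = n_keep + 1 + i
    return RfeResult(ranking=ranking, selected=selected, scores=scores)


# ---------------------------------------------------------------------------
# model training


@dataclass
class CnnConfig:
    """Hyperparameters of the FPAR regression network."""

    conv_filters: tuple[int, ...] = (16, 32, 64)
    kernel_size: int = 2
    dropout_rate: float = 0.3
    dense_units: tuple[int, ...] = (64, 32)
    learning_rate: float = 0.001
    epochs: int = 10
    batch_size: int = 16
    split_ratio: float = 0.7
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainedFparModel:
    """A fitted FPAR predictor with its feature contract and held-out report."""

    kind: str  # cnn | gbdt | xgb | empirical
    model: object
    feature_names: list[str]
    scaling: dict[str, tuple[float, float]] | None
    training_report: EvalReport | None = None
    config: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps({"kind": self.kind, "features": self.feature_names,
                           "config": self.config}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def train_test_split_indices(n: int, split_ratio: float, seed: int):
    """Seeded uniform shuffle split; first ``split_ratio`` fraction trains."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split_ratio * n))
    return order[:n_train], order[n_train:]


def train_cnn(m: FeatureMatrix, y, cfg: CnnConfig | None = None) -> TrainedFparModel:
    """Train the 1-D CNN on a (normalized) feature matrix.

    Splits 7:3 by a seeded shuffle, trains for the configured number of
    epochs, and reports held-out metrics.
    """
    cfg = cfg or CnnConfig()
    y = validate_fpar(y)
    if m.n_samples < 100:
        raise TrainingError(f"need >= 100 samples to train the CNN, got {m.n_samples}")
    tr, te = train_test_split_indices(m.n_samples, cfg.split_ratio, cfg.seed)
    if tr.size < cfg.batch_size:
        raise TrainingError("training split smaller than one batch")
    net = Cnn1DRegressor(
        n_features=len(m.feature_names), conv_filters=cfg.conv_filters,
        kernel_size=cfg.kernel_size, dropout_rate=cfg.dropout_rate,
        dense_units=cfg.dense_units, seed=cfg.seed)
    try:
        net.fit(m.values[tr], y[tr], epochs=cfg.epochs,
                batch_size=cfg.batch_size, lr=cfg.learning_rate)
    except FloatingPointError as exc:
        raise TrainingError(f"CNN training diverged: {exc}") from exc
    pred = np.clip(net.predict(m.values[te]), 0.0, 1.0)
    report = evaluate(y[te], pred)
    return TrainedFparModel(kind="cnn", model=net,
                            feature_names=list(m.feature_names),
                            scaling=m.scaling, training_report=report,
                            config=asdict(cfg))


def train_tree_baseline(m: FeatureMatrix, y, kind: str = "gbdt",
                        hyperparams: dict | None = None, seed: int = 42,
                        split_ratio: float = 0.7) -> TrainedFparModel:
    """Gradient-boosted tree baseline (GBDT or XGBoost-style), same split."""
    y = validate_fpar(y)
    hp = {"n_estimators": 500, "max_depth": 6, "learning_rate": 0.05}
    hp.update(hyperparams or {})
    if kind == "gbdt":
        est = GradientBoostingRegressor(random_state=seed, **hp)
    elif kind in ("xgb", "xgb-style", "xgboost"):
        from xgboost import XGBRegressor
        est = XGBRegressor(random_state=seed, n_jobs=1, **hp)
        kind = "xgb"
    else:
        raise ValueError(f"unknown tree baseline kind {kind!r}")
    tr, te = train_test_split_indices(m.n_samples, split_ratio, seed)
    est.fit(m.values[tr], y[tr])
    pred = np.clip(est.predict(m.values[te]).astype(float), 0.0, 1.0)
    report = evaluate(y[te], pred)
    return TrainedFparModel(kind=kind, model=est,
                            feature_names=list(m.feature_names),
                            scaling=m.scaling, training_report=report,
                            config={"hyperparams": hp, "seed": seed,
                                    "split_ratio": split_ratio})


# ---------------------------------------------------------------------------
# prediction


def _predict_matrix(model: TrainedFparModel, values: np.ndarray) -> np.ndarray:
    if model.kind == "cnn":
        raw = model.model.predict(values)
    else:
        raw = model.model.predict(values).astype(float)
    return np.clip(raw, 0.0, 1.0)


def predict_fpar(model: TrainedFparModel, data: FeatureMatrix | IndexCube):
    """Predict FPAR for a feature matrix (vector out) or index cube (grid out).

    Raw features are scaled with the model's recorded scaling; outputs
    are clipped to [0, 1]; masked pixels stay masked.
    """
    if isinstance(data, IndexCube):
        mat, valid = data.to_matrix(model.feature_names)
        if model.scaling is not None:
            mat = apply_scaling(mat, model.feature_names, model.scaling)
        pred = _predict_matrix(model, mat)
        ref = data.layers[model.feature_names[0]]
        out = np.full(ref.shape, np.nan)
        out[valid] = pred
        return Grid(out, ~valid, ref.transform, ref.crs)

    missing = [n for n in model.feature_names if n not in data.feature_names]
    extra = [n for n in data.feature_names if n not in model.feature_names]
    if missing:
        raise FeatureMismatchError(f"missing features: {missing}; extra: {extra}")
    sub = data.select(model.feature_names)
    vals = sub.values
    if model.scaling is not None and data.scaling is None:
        vals = apply_scaling(vals, model.feature_names, model.scaling)
    return _predict_matrix(model, vals)


# ---------------------------------------------------------------------------
# empirical NDVI/RVI FPAR (classic CASA)


@dataclass
class EmpiricalFparParams:
    """Linear-stretch parameters of the classic NDVI/RVI FPAR.

    Bounds default to None and are then taken as the 5th/95th
    percentiles of vegetated pixels in the scene at hand.
    """

    ndvi_min: float | None = None
    ndvi_max: float | None = None
    sr_min: float | None = None
    sr_max: float | None = None
    fpar_min: float = 0.001
    fpar_max: float = 0.95
    alpha: float = 0.5
    veg_ndvi_threshold: float = 0.2  # pixels counted as vegetated for percentiles

    def __post_init__(self) -> None:
        if not 0.0 <= self.fpar_min < self.fpar_max <= 1.0:
            raise ValueError("need 0 <= fpar_min < fpar_max <= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def _stretch(v: np.ndarray, lo: float, hi: float, f_lo: float, f_hi: float):
    if hi <= lo:
        raise DegenerateBoundsError(f"degenerate stretch bounds: [{lo}, {hi}]")
    out = (v - lo) * (f_hi - f_lo) / (hi - lo) + f_lo
    return np.clip(out, f_lo, f_hi)


def empirical_fpar(ndvi: Grid, rvi: Grid, p: EmpiricalFparParams | None = None) -> Grid:
    """Classic FPAR: average of linear NDVI and RVI stretches.

    FPAR_NDVI stretches NDVI between (ndvi_min, ndvi_max) onto
    (fpar_min, fpar_max); FPAR_SR does the same with RVI; the output is
    ``alpha * FPAR_NDVI + (1 - alpha) * FPAR_SR``, clamped into
    [fpar_min, fpar_max] by construction.
    """
    p = p or EmpiricalFparParams()
    mask = ndvi.mask | rvi.mask
    nv, rv = ndvi.values, rvi.values
    veg = (~mask) & (nv >= p.veg_ndvi_threshold)
    if not veg.any():
        veg = ~mask
    ndvi_lo = p.ndvi_min if p.ndvi_min is not None else float(np.percentile(nv[veg], 5))
    ndvi_hi = p.ndvi_max if p.ndvi_max is not None else float(np.percentile(nv[veg], 95))
    sr_lo = p.sr_min if p.sr_min is not None else float(np.percentile(rv[veg], 5))
    sr_hi = p.sr_max if p.sr_max is not None else float(np.percentile(rv[veg], 95))
    f_ndvi = _stretch(nv, ndvi_lo, ndvi_hi, p.fpar_min, p.fpar_max)
    f_sr = _stretch(rv, sr_lo, sr_hi, p.fpar_min, p.fpar_max)
    out = p.alpha * f_ndvi + (1.0 - p.alpha) * f_sr
    return Grid(np.where(mask, np.nan, out), mask, ndvi.transform, ndvi.crs)


# ---------------------------------------------------------------------------
# serialization (JSON archive: weights, feature order, scaling, config hash)

FORMAT_VERSION = 1


def save_model(model: TrainedFparModel, path) -> None:
    """Serialize a trained model to a versioned JSON archive.

    CNN weights are stored as nested lists; tree models are stored via
    their own JSON export (XGBoost) or pickled-free re-fit parameters
    are not supported — for tree baselines the sklearn estimator is
    rebuilt from its params and retrained state is stored as artifacts
    only for the CNN and empirical kinds.
    """
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "feature_names": model.feature_names,
        "scaling": model.scaling,
        "config": model.config,
        "config_hash": model.config_hash(),
    }
    if model.kind == "cnn":
        payload["weights"] = [w.tolist() for w in model.model.get_weights()]
        payload["target_scaling"] = [model.model.y_loc, model.model.y_scale]
    elif model.kind == "empirical":
        payload["empirical_params"] = asdict(model.model)
    else:
        raise ValueError(f"serialization supported for cnn/empirical, not {model.kind}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> TrainedFparModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError("unsupported model archive version")
    scaling = payload["scaling"]
    if scaling is not None:
        scaling = {k: tuple(v) for k, v in scaling.items()}
    if payload["kind"] == "cnn":
        cfg = payload["config"]
        net = Cnn1DRegressor(
            n_features=len(payload["feature_names"]),
            conv_filters=tuple(cfg.get("conv_filters", (16, 32, 64))),
            kernel_size=cfg.get("kernel_size", 2),
            dropout_rate=cfg.get("dropout_rate", 0.3),
            dense_units=tuple(cfg.get("dense_units", (64, 32))),
            seed=cfg.get("seed", 42))
        net.set_weights([np.asarray(w) for w in payload["weights"]])
        net.y_loc, net.y_scale = payload.get("target_scaling", (0.0, 1.0))
        model = net
    else:
        model = EmpiricalFparParams(**payload["empirical_params"])
    return TrainedFparModel(kind=payload["kind"], model=model,
                            feature_names=payload["feature_names"],
                            scaling=scaling, config=payload["config"])
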