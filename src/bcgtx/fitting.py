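"""Three-step fitting of the personalized BCG treatment model.

Only two tumor-burden observations per patient exist (treatment start and
end), so the rate constants are estimated by matching simulated end-of-course
burden to the observed one.  The procedure, per cross-validation fold:

1. *Per-group gradient descent.*  Within the fold's training split, patients
   are grouped by socio-demographic profile and each group's free rate
   constants are fitted by gradient descent on the relative mean absolute
   error (RMAE) of the predicted end burden.  Parameters are optimized in
   log10 space with projection to bounds; gradients use the five-point
   stencil, which is exact for polynomials up to degree four.

2. *Gated synthetic augmentation.*  The training split is augmented with
   synthetic samples whose features are drawn uniformly between the training
   minima and maxima; a candidate is accepted only if the current model
   predicts its (model-labelled) outcome better than an optimized
   k-nearest-neighbour regressor would.  After refitting, a paired one-sided
   t-test on the held-out test split decides whether the augmented fit is a
   statistically significant improvement; if not the augmentation round is
   repeated (bounded number of rounds).

3. *Pipeline search.*  A fixed candidate set of multi-output regression
   pipelines (constant, linear, nearest-neighbour, tree-ensemble; optionally
   feature-scaled) is trained to map socio-demographic features (plus the
   log presentation burden) to the fitted log-parameters, and the candidate
   with the best validation RMAE is kept as the fold's extrapolator for
   profiles without a directly fitted group.

The fold-level results are averaged at prediction time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cohort import PatientRecord, decode_features, encode_features, estimate_Hm, group_of
from .dynamics import simulate_final
from .params import DoseSchedule, ModelParameters, default_parameters

__all__ = [
    "FitConfig",
    "FoldResult",
    "FittedModel",
    "rmae",
    "predict_outcome",
    "stencil_gradient",
    "gd_fit",
    "augment_train",
    "significance_gate",
    "pipeline_search",
    "default_pipeline_candidates",
    "fit",
    "predict",
]

logger = logging.getLogger(__name__)

#: rate constants that may be fitted; protocol constants (b, N, tau, mu_B, H_m)
#: are observed and stay fixed
DEFAULT_FREE = (
    "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9",
    "mu_E", "alpha", "lambda_", "e0",
)


@dataclass
class FitConfig:
    """Hyper-parameters of the three-step fitting procedure.

    ``free`` lists the parameter names optimized by gradient descent; bounds
    default to three decades either side of the initial value.  ``fractions``
    are the train/test/validate shares within each fold.  ``sim_rtol`` is the
    (deliberately loose) integration tolerance used inside the fitting loop;
    final reported predictions use the same path so train and evaluation are
    consistent.
    """

    k: int = 5
    n_augment: int = 20
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    free: tuple[str, ...] = DEFAULT_FREE
    bounds: dict[str, tuple[float, float]] | None = None
    bound_decades: float = 3.0
    gd_step: float = 0.25
    gd_max_iter: int = 500
    gd_refit_iter: int = 50
    gd_tol: float = 1e-6
    stencil_h: float = 1e-3
    restarts: int = 3
    alpha_gate: float = 0.05
    max_aug_rounds: int = 3
    aug_attempt_factor: int = 50
    knn_grid: tuple[int, ...] = (1, 3, 5, 7)
    seed: int = 0
    sim_rtol: float = 1e-6
    init: ModelParameters | None = None
    pooled_Hm: float = 1.84e9

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        if self.n_augment < 0:
            raise ValueError("n_augment must be non-negative")
        for name in self.free:
            if name not in DEFAULT_FREE:
                raise ValueError(f"{name!r} is not a fittable parameter")
        if self.bounds:
            for name, (lo, hi) in self.bounds.items():
                if not (0 <= lo <= hi):
                    raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")


@dataclass
class FoldResult:
    """Per-fold artifacts: fitted group parameters, the selected pipeline, errors."""

    params_by_group: dict[int | None, ModelParameters]
    pipeline: object | None
    pipeline_name: str | None
    rmae_train: float
    rmae_test: float
    rmae_val: float
    n_augmented: int = 0
    gate_pvalues: list[float] = field(default_factory=list)
    augmentation_accepted: bool = False


@dataclass
class FittedModel:
    """The fitted personalized (or pooled) model: one :class:`FoldResult` per fold.

    Predictions are the mean over folds; within a fold, a record's group
    parameters are used when that group was fitted, otherwise the fold's
    pipeline extrapolates them from the record's features.
    """

    folds: list[FoldResult]
    config: FitConfig
    pooled: bool = False

    def __post_init__(self) -> None:
        if len(self.folds) != self.config.k:
            raise ValueError("FittedModel must carry exactly k folds")


# ---------------------------------------------------------------------------
# loss and primitives


def rmae(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Relative mean absolute error: mean over patients of |pred - obs| / obs."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty arrays")
    if np.any(obs <= 0):
        raise ValueError("observed burdens must be positive")
    return float(np.mean(np.abs(pred - obs) / obs))


def predict_outcome(
    params: ModelParameters, record: PatientRecord, rtol: float = 1e-6
) -> float:
    """Simulated end-of-treatment tumor burden for one patient.

    Integrates from the pre-treatment state with the record's presentation
    burden and schedule and returns ``T_i(t_f) + T_u(t_f)``.
    """
    p = params.replace(T0=float(record.T_start))
    y = simulate_final(p, record.schedule, record.t_f, rtol=rtol)
    return float(y[2] + y[3])


def stencil_gradient(loss: Callable[[np.ndarray], float], theta: np.ndarray, h: float) -> np.ndarray:
    """Five-point-stencil gradient of ``loss`` at ``theta`` (step ``h`` per coordinate).

    The fourth-order formula ``(-f(x+2h) + 8 f(x+h) - 8 f(x-h) + f(x-2h)) / 12h``
    is exact for polynomials of degree <= 4.
    """
    theta = np.asarray(theta, dtype=float)
    grad = np.empty_like(theta)
    for i in range(theta.size):
        e = np.zeros_like(theta)
        e[i] = h
        f_p2, f_p1 = loss(theta + 2 * e), loss(theta + e)
        f_m1, f_m2 = loss(theta - e), loss(theta - 2 * e)
        vals = (f_p2, f_p1, f_m1, f_m2)
        if not all(np.isfinite(v) for v in vals):
            raise FloatingPointError(f"non-finite loss near theta[{i}]")
        grad[i] = (-f_p2 + 8 * f_p1 - 8 * f_m1 + f_m2) / (12 * h)
    return grad


# ---------------------------------------------------------------------------
# gradient-descent group fitting


def _free_bounds(config: FitConfig, init: ModelParameters) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for name in config.free:
        if config.bounds and name in config.bounds:
            low, high = config.bounds[name]
        else:
            v = max(getattr(init, name), 1e-16)
            low, high = v * 10 ** (-config.bound_decades), v * 10 ** (config.bound_decades)
        low = max(low, 1e-30)
        lo.append(low)
        hi.append(max(high, low))
    return np.log10(np.array(lo)), np.log10(np.array(hi))


def _theta_to_params(theta: np.ndarray, base: ModelParameters, config: FitConfig) -> ModelParameters:
    return base.replace(**{name: float(10.0 ** t) for name, t in zip(config.free, theta)})


def gd_fit(
    train: Sequence[PatientRecord],
    init: ModelParameters,
    config: FitConfig,
    rng: np.random.Generator | None = None,
    outcome_fn: Callable | None = None,
) -> tuple[ModelParameters, list[float]]:
    """Fit the free parameters to a training set by projected gradient descent.

    Optimizes the RMAE of predicted versus observed end burdens in log10
    parameter space, with five-point-stencil gradients, a fixed step with
    backtracking halving, projection to bounds, and seeded random restarts.
    Returns the best-seen parameters and the accepted-step loss trace (which
    is non-increasing).  Raises ``RuntimeError`` when every simulation fails.
    """
    train = list(train)
    if not train:
        raise ValueError("empty training set")
    if outcome_fn is None:
        outcome_fn = predict_outcome
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    observed = np.array([r.T_end for r in train], dtype=float)
    if np.any(~np.isfinite(observed)) or np.any(observed <= 0):
        raise ValueError("training records must carry positive observed end burdens")

    lo, hi = _free_bounds(config, init)
    cache: dict[tuple, float] = {}

    def loss(theta: np.ndarray) -> float:
        key = tuple(np.round(theta, 12))
        if key in cache:
            return cache[key]
        params = _theta_to_params(theta, init, config)
        preds = np.empty(len(train))
        for i, rec in enumerate(train):
            try:
                preds[i] = outcome_fn(params, rec, rtol=config.sim_rtol)
            except (RuntimeError, ValueError, FloatingPointError):
                preds[i] = np.nan
        if np.any(~np.isfinite(preds)):
            value = np.inf
        else:
            value = rmae(preds, observed)
        cache[key] = value
        return value

    theta_init = np.clip(
        np.log10(np.array([max(getattr(init, n), 1e-30) for n in config.free])), lo, hi
    )
    starts = [theta_init]
    for _ in range(max(config.restarts - 1, 0)):
        starts.append(np.clip(theta_init + rng.normal(0.0, 0.3, theta_init.size), lo, hi))

    best_theta, best_loss, best_trace = None, np.inf, []
    for theta in starts:
        current = loss(theta)
        trace = [current]
        if not np.isfinite(current):
            continue
        for _ in range(config.gd_max_iter):
            try:
                grad = stencil_gradient(loss, theta, config.stencil_h)
            except FloatingPointError:
                break
            gmax = np.max(np.abs(grad))
            if gmax == 0.0:
                break
            direction = -grad / gmax
            step = config.gd_step
            accepted = False
            for _ in range(8):
                cand = np.clip(theta + step * direction, lo, hi)
                cand_loss = loss(cand)
                if cand_loss < current:
                    theta, previous, current = cand, current, cand_loss
                    trace.append(current)
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            if previous > 0 and (previous - current) / previous < config.gd_tol:
                break
        if current < best_loss:
            best_theta, best_loss, best_trace = theta, current, trace
    if best_theta is None:
        raise RuntimeError("all simulations failed during gradient-descent fitting")
    return _theta_to_params(best_theta, init, config), best_trace


# ---------------------------------------------------------------------------
# augmentation with KNN gate


def _features(record: PatientRecord, pooled: bool) -> np.ndarray:
    x = [np.log10(record.T_start)]
    if not pooled:
        x = list(encode_features(record.profile)) + x
    return np.array(x)


def fit_outcome_knn(
    train: Sequence[PatientRecord], config: FitConfig, pooled: bool = False
) -> KNeighborsRegressor:
    """KNN regressor of log10 end burden, neighbour count chosen by leave-one-out error."""
    X = np.array([_features(r, pooled) for r in train])
    y = np.log10(np.array([r.T_end for r in train], dtype=float))
    n = len(train)
    best_k, best_err = None, np.inf
    for k in config.knn_grid:
        if k >= n:
            continue
        errs = []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = KNeighborsRegressor(n_neighbors=k).fit(X[mask], y[mask])
            errs.append((model.predict(X[i: i + 1])[0] - y[i]) ** 2)
        err = float(np.mean(errs))
        if err < best_err:
            best_k, best_err = k, err
    if best_k is None:
        best_k = 1
    return KNeighborsRegressor(n_neighbors=best_k).fit(X, y)


def augment_train(
    train: Sequence[PatientRecord],
    config: FitConfig,
    knn_model: KNeighborsRegressor,
    label_fn: Callable[[PatientRecord], float | None],
    rng: np.random.Generator,
    pooled: bool = False,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Add up to ``n_augment`` accepted synthetic records to the training set.

    Candidate features are drawn uniformly per column between the training
    minima and maxima (one-hot coordinates are rounded to the nearest valid
    profile); the outcome label is the current model's simulated prediction
    (``label_fn``).  A candidate is accepted iff the model's error on that
    label is strictly smaller than the optimized KNN regressor's error.
    Returns ``(augmented_train, accepted)``; never removes original records.
    Stops with a warning at ``aug_attempt_factor * n_augment`` attempts.
    """
    train = list(train)
    if config.n_augment == 0:
        return train, []
    feats = np.array([_features(r, pooled) for r in train])
    col_lo, col_hi = feats.min(axis=0), feats.max(axis=0)
    schedule: DoseSchedule = train[0].schedule
    t_f = train[0].t_f
    profiles = [r.profile for r in train]

    accepted: list[PatientRecord] = []
    attempts, cap = 0, config.aug_attempt_factor * config.n_augment
    while len(accepted) < config.n_augment and attempts < cap:
        attempts += 1
        draw = rng.uniform(col_lo, col_hi)
        if pooled:
            profile = profiles[rng.integers(len(profiles))]
            log_T0 = draw[0]
        else:
            profile = decode_features(draw[:13])
            log_T0 = draw[13]
        candidate = PatientRecord(
            profile=profile,
            T_start=float(10.0 ** log_T0),
            T_end=None,
            schedule=schedule,
            t_f=t_f,
            patient_id=f"AUG{attempts:05d}",
        )
        label = label_fn(candidate)
        if label is None or not np.isfinite(label) or label <= 0:
            continue
        candidate.T_end = float(label)
        model_err = 0.0  # the label is the model's own prediction
        knn_pred = float(10.0 ** knn_model.predict(_features(candidate, pooled)[None, :])[0])
        knn_err = abs(knn_pred - label) / label
        if model_err < knn_err:
            accepted.append(candidate)
    if len(accepted) < config.n_augment:
        warnings.warn(
            f"augmentation cap reached: accepted {len(accepted)} of {config.n_augment}",
            stacklevel=2,
        )
    return train + accepted, accepted


def significance_gate(
    test: Sequence[PatientRecord],
    model_before: Callable[[PatientRecord], float | None],
    model_after: Callable[[PatientRecord], float | None],
    alpha: float = 0.05,
) -> tuple[bool, float]:
    """Paired one-sided test: does the refitted model beat the previous one?

    Computes per-patient absolute relative errors on the test split under both
    models and applies a paired one-sided t-test (after < before) at level
    ``alpha``.  Degenerate inputs (one patient, all-equal differences, or no
    usable predictions) reject with a warning.
    """
    before, after = [], []
    for rec in test:
        pb, pa = model_before(rec), model_after(rec)
        if pb is None or pa is None or rec.T_end is None or rec.T_end <= 0:
            continue
        before.append(abs(pb - rec.T_end) / rec.T_end)
        after.append(abs(pa - rec.T_end) / rec.T_end)
    if len(before) < 2:
        warnings.warn("significance gate: fewer than two comparable test patients", stacklevel=2)
        return False, 1.0
    before_arr, after_arr = np.array(before), np.array(after)
    diff = after_arr - before_arr
    if np.allclose(diff, 0.0):
        warnings.warn("significance gate: identical predictions before and after", stacklevel=2)
        return False, 1.0
    result = stats.ttest_rel(after_arr, before_arr, alternative="less")
    p = float(result.pvalue)
    return p < alpha, p


# ---------------------------------------------------------------------------
# pipeline search


def default_pipeline_candidates(seed: int, n_train: int) -> list[tuple[str, object]]:
    """The fixed multi-output candidate set searched in step three."""
    knn_k = max(1, min(5, n_train - 1))
    return [
        ("constant-mean", DummyRegressor(strategy="mean")),
        ("scaled-linear", Pipeline([("scale", StandardScaler()), ("reg", LinearRegression())])),
        ("nearest-neighbor", KNeighborsRegressor(n_neighbors=1)),
        ("scaled-knn", Pipeline([
            ("scale", StandardScaler()),
            ("reg", KNeighborsRegressor(n_neighbors=knn_k)),
        ])),
        ("random-forest", RandomForestRegressor(n_estimators=60, random_state=seed)),
    ]


def pipeline_search(
    train_X: np.ndarray,
    train_Y: np.ndarray,
    validation: Sequence[PatientRecord],
    candidates: Sequence[tuple[str, object]],
    config: FitConfig,
    build_params: Callable[[np.ndarray, PatientRecord], ModelParameters],
    pooled: bool = False,
) -> tuple[object, str, float, dict[str, float]]:
    """Select the best feature->parameters pipeline by validation-set RMAE.

    Each candidate is trained on ``(train_X, train_Y)`` (features to log10
    free parameters); its metric is the RMAE of the simulated end burden using
    the predicted parameters on the validation records.  The argmin candidate
    is returned (ties break toward the earlier candidate).
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate pipelines")
    if len(validation) == 0:
        raise ValueError("empty validation set")
    scores: dict[str, float] = {}
    fitted: dict[str, object] = {}
    for name, est in candidates:
        try:
            model = clone(est).fit(train_X, train_Y)
            preds, obs = [], []
            for rec in validation:
                yhat = np.atleast_2d(model.predict(_features(rec, pooled)[None, :]))[0]
                params = build_params(np.asarray(yhat, dtype=float).ravel(), rec)
                preds.append(predict_outcome(params, rec, rtol=config.sim_rtol))
                obs.append(rec.T_end)
            scores[name] = rmae(preds, obs)
            fitted[name] = model
        except Exception as exc:
            logger.warning("pipeline candidate %s failed: %s", name, exc)
            scores[name] = np.inf
    best_name = min(scores, key=lambda nm: (scores[nm], list(scores).index(nm)))
    if not np.isfinite(scores[best_name]):
        raise RuntimeError("all pipeline candidates failed")
    return fitted[best_name], best_name, scores[best_name], scores


# ---------------------------------------------------------------------------
# the full three-step procedure


def _init_for(profile, config: FitConfig, pooled: bool) -> ModelParameters:
    base = config.init if config.init is not None else default_parameters()
    Hm = config.pooled_Hm if pooled else estimate_Hm(profile)
    return base.replace(H_m=Hm)


def _group_key(record: PatientRecord, pooled: bool) -> int | None:
    return None if pooled else group_of(record.profile).index


def _make_group_predictor(
    params_by_group: dict[int | None, ModelParameters],
    config: FitConfig,
    pooled: bool,
) -> Callable[[PatientRecord], float | None]:
    def predictor(record: PatientRecord) -> float | None:
        params = params_by_group.get(_group_key(record, pooled))
        if params is None:
            return None
        try:
            return predict_outcome(params, record, rtol=config.sim_rtol)
        except (RuntimeError, ValueError):
            return None
    return predictor


def _split_fold(fold_records: list, fractions, rng) -> tuple[list, list, list]:
    n = len(fold_records)
    order = rng.permutation(n)
    n_train = max(int(round(fractions[0] * n)), 1)
    n_test = max(int(round(fractions[1] * n)), 1)
    n_train = min(n_train, n - 2) if n >= 3 else max(n - 2, 1)
    idx_train = order[:n_train]
    idx_test = order[n_train: n_train + n_test]
    idx_val = order[n_train + n_test:]
    train = [fold_records[i] for i in idx_train]
    test = [fold_records[i] for i in idx_test]
    val = [fold_records[i] for i in idx_val]
    if not val:
        val = test
    if not test:
        test = val
    return train, test, val


def _build_params_factory(config: FitConfig, pooled: bool):
    def build(theta_pred: np.ndarray, record: PatientRecord) -> ModelParameters:
        init = _init_for(record.profile, config, pooled)
        lo, hi = _free_bounds(config, init)
        theta = np.clip(theta_pred, lo, hi)
        return _theta_to_params(theta, init, config)
    return build


def _fold_rmae(records, predictor) -> float:
    preds, obs = [], []
    for rec in records:
        p = predictor(rec)
        if p is None or rec.T_end is None:
            continue
        preds.append(p)
        obs.append(rec.T_end)
    if not preds:
        return np.nan
    return rmae(preds, obs)


def fit(cohort: Sequence[PatientRecord], config: FitConfig, pooled: bool = False) -> FittedModel:
    """Run the full three-step procedure over ``k`` folds and assemble the model.

    ``pooled=True`` collapses all patients into a single group and drops the
    socio-demographic features from the KNN and pipeline inputs (the
    non-personalized variant used as a comparison baseline).
    """
    records = list(cohort)
    if len(records) < config.k:
        raise ValueError(f"cohort of {len(records)} patients cannot fill k={config.k} folds")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(records))
    fold_indices = np.array_split(order, config.k)

    folds: list[FoldResult] = []
    for fi, idx in enumerate(fold_indices):
        fold_rng = np.random.default_rng(config.seed + 7919 * (fi + 1))
        fold_records = [records[i] for i in idx]
        train, test, val = _split_fold(fold_records, config.fractions, fold_rng)

        # step 1: per-group GD on the original training split
        by_group: dict[int | None, list[PatientRecord]] = {}
        for rec in train:
            by_group.setdefault(_group_key(rec, pooled), []).append(rec)
        params_by_group: dict[int | None, ModelParameters] = {}
        for gkey, group_records in sorted(by_group.items(), key=lambda kv: (kv[0] is None, kv[0])):
            init = _init_for(group_records[0].profile, config, pooled)
            params_by_group[gkey], _ = gd_fit(group_records, init, config, fold_rng)

        predict_before = _make_group_predictor(params_by_group, config, pooled)

        # step 2: gated augmentation rounds
        gate_pvalues: list[float] = []
        n_augmented, aug_accepted_flag = 0, False
        current_train = train
        if config.n_augment > 0 and config.max_aug_rounds > 0:
            for _ in range(config.max_aug_rounds):
                knn = fit_outcome_knn(current_train, config, pooled)
                aug_train, accepted = augment_train(
                    current_train, config, knn, predict_before, fold_rng, pooled
                )
                refit_config = replace(config, gd_max_iter=config.gd_refit_iter, restarts=1)
                refit_params: dict[int | None, ModelParameters] = {}
                aug_by_group: dict[int | None, list[PatientRecord]] = {}
                for rec in aug_train:
                    aug_by_group.setdefault(_group_key(rec, pooled), []).append(rec)
                for gkey, group_records in aug_by_group.items():
                    warm = params_by_group.get(gkey, _init_for(group_records[0].profile, config, pooled))
                    refit_params[gkey], _ = gd_fit(group_records, warm, refit_config, fold_rng)
                predict_after = _make_group_predictor(refit_params, config, pooled)
                ok, p = significance_gate(test, predict_before, predict_after, config.alpha_gate)
                gate_pvalues.append(p)
                if ok:
                    params_by_group = refit_params
                    predict_before = predict_after
                    current_train = aug_train
                    n_augmented = len(accepted)
                    aug_accepted_flag = True
                    break

        # step 3: pipeline search on features -> fitted log-parameters
        pipe_records = [
            r for r in current_train + test
            if _group_key(r, pooled) in params_by_group
        ]
        pipeline = pipeline_name = None
        rmae_val = np.nan
        if pipe_records and val:
            X = np.array([_features(r, pooled) for r in pipe_records])
            Y = np.array([
                [np.log10(max(getattr(params_by_group[_group_key(r, pooled)], nm), 1e-30))
                 for nm in config.free]
                for r in pipe_records
            ])
            candidates = default_pipeline_candidates(config.seed + fi, len(pipe_records))
            build = _build_params_factory(config, pooled)
            try:
                pipeline, pipeline_name, rmae_val, _ = pipeline_search(
                    X, Y, val, candidates, config, build, pooled
                )
            except RuntimeError as exc:
                logger.warning("fold %d pipeline search failed: %s", fi, exc)

        fold_predictor = _fold_predictor_factory(params_by_group, pipeline, config, pooled)
        folds.append(FoldResult(
            params_by_group=params_by_group,
            pipeline=pipeline,
            pipeline_name=pipeline_name,
            rmae_train=_fold_rmae(train, fold_predictor),
            rmae_test=_fold_rmae(test, fold_predictor),
            rmae_val=_fold_rmae(val, fold_predictor),
            n_augmented=n_augmented,
            gate_pvalues=gate_pvalues,
            augmentation_accepted=aug_accepted_flag,
        ))
    return FittedModel(folds=folds, config=config, pooled=pooled)


def _fold_predictor_factory(params_by_group, pipeline, config: FitConfig, pooled: bool):
    build = _build_params_factory(config, pooled)

    def predictor(record: PatientRecord) -> float | None:
        params = params_by_group.get(_group_key(record, pooled))
        if params is None and pipeline is not None:
            yhat = np.atleast_2d(pipeline.predict(_features(record, pooled)[None, :]))[0]
            params = build(np.asarray(yhat, dtype=float).ravel(), record)
        if params is None:
            return None
        try:
            return predict_outcome(params, record, rtol=config.sim_rtol)
        except (RuntimeError, ValueError):
            return None
    return predictor


def predict(model: FittedModel, record: PatientRecord) -> float:
    """Fold-averaged end-burden prediction for one patient.

    Each fold contributes its direct group fit when available, otherwise its
    pipeline extrapolation; the prediction is the mean of the per-fold values.
    """
    values = []
    for fold in model.folds:
        pred = _fold_predictor_factory(fold.params_by_group, fold.pipeline, model.config, model.pooled)(record)
        if pred is not None:
            values.append(pred)
    if not values:
        raise RuntimeError("no fold could produce a prediction for this record")
    return float(np.mean(values))
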