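"""Recurrence-free survival prediction with repeated nested cross-validation.

Per-patient fused feature vectors enter a Cox proportional-hazards
pipeline: standard scaling, greedy elimination of highly correlated
features, ICA dimensionality reduction, then a (optionally ridge-penalized)
Cox partial-likelihood fit. Generalization is estimated with nested k-fold
cross-validation repeated with different shuffles: the inner folds
grid-search hyperparameters on outer-training data only, every fitted
object is learned on outer-training data and applied once to the outer
test fold, and performance is reported as Harrell's concordance index per
outer split.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Any

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "SurvivalRecord",
    "CohortFeatures",
    "CVConfig",
    "CVResult",
    "scale_standard",
    "drop_correlated",
    "reduce_ica",
    "fit_cox",
    "concordance_index",
    "nested_cv",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's right-censored endpoint (event=True means observed)."""

    patient_id: str
    time: float
    event: bool

    def __post_init__(self):
        if not (self.time > 0):
            raise ValueError(f"time must be positive, got {self.time}")


@dataclass
class CohortFeatures:
    """N x D feature matrix aligned with patient ids."""

    matrix: np.ndarray
    feature_names: list[str]
    patient_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError(f"feature matrix must be 2D, got {self.matrix.shape}")
        n, d = self.matrix.shape
        if len(self.feature_names) != d:
            raise ValueError("feature_names length must match matrix columns")
        if len(self.patient_ids) != n:
            raise ValueError("patient_ids length must match matrix rows")
        if len(set(self.patient_ids)) != n:
            raise ValueError("duplicate patient ids")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite values")


def _records_arrays(records) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray([r.time for r in records], dtype=np.float64)
    event = np.asarray([r.event for r in records], dtype=bool)
    return time, event


# ---------------------------------------------------------------------------
# Preprocessing stages
# ---------------------------------------------------------------------------

@dataclass
class StandardScaler1D:
    mean: np.ndarray
    scale: np.ndarray

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.scale


def fit_scaler(train: np.ndarray) -> StandardScaler1D:
    """Per-feature mean removal / unit variance; constant features map to 0."""
    x = np.asarray(train, dtype=np.float64)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    return StandardScaler1D(mean, np.where(std > 0, std, 1.0))


def scale_standard(train: CohortFeatures, apply_to: CohortFeatures) -> CohortFeatures:
    """Standardize ``apply_to`` using statistics estimated on ``train``."""
    if train.matrix.shape[0] == 0:
        raise ValueError("empty training cohort")
    scaler = fit_scaler(train.matrix)
    return CohortFeatures(
        scaler.apply(apply_to.matrix), list(apply_to.feature_names), list(apply_to.patient_ids)
    )


def drop_correlated(train, threshold: float = 0.95) -> np.ndarray:
    """Greedy correlated-feature elimination on training data.

    Scanning features in order, feature j is dropped if its absolute
    Pearson correlation with any earlier *kept* feature reaches the
    threshold. Zero-variance features (undefined correlation, no signal)
    are dropped as well. Returns the kept column indices, to be applied
    identically to held-out data.
    """
    x = train.matrix if isinstance(train, CohortFeatures) else np.asarray(train, dtype=np.float64)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    std = x.std(axis=0)
    kept: list[int] = []
    xc = x - x.mean(axis=0)
    norms = np.sqrt((xc**2).sum(axis=0))
    for j in range(x.shape[1]):
        if std[j] == 0:
            continue
        ok = True
        for k in kept:
            r = (xc[:, j] @ xc[:, k]) / (norms[j] * norms[k])
            if abs(r) >= threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.asarray(kept, dtype=int)


@dataclass
class IcaTransform:
    ica: FastICA
    n_components: int
    seed_used: int

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.ica.transform(np.asarray(x, dtype=np.float64))

    def inverse(self, s: np.ndarray) -> np.ndarray:
        return self.ica.inverse_transform(np.asarray(s, dtype=np.float64))


def reduce_ica(
    train,
    n_components: int,
    seed: int,
    max_retries: int = 5,
    max_iter: int = 1000,
    tol: float = 1e-3,
) -> IcaTransform:
    """Fit FastICA on training data with seeded retries on non-convergence.

    The convergence tolerance is deliberately modest: the transform is a
    dimensionality-reduction step feeding a Cox model, not a source
    separation whose components are interpreted individually.
    """
    x = train.matrix if isinstance(train, CohortFeatures) else np.asarray(train, dtype=np.float64)
    n, d = x.shape
    if n_components > min(n - 1, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(N-1, D)={min(n - 1, d)}"
        )
    last_exc: Exception | None = None
    for attempt in range(max_retries):
        seed_used = int(seed) + attempt
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica = FastICA(
                n_components=n_components,
                random_state=seed_used,
                max_iter=max_iter,
                tol=tol,
                whiten="unit-variance",
            )
            try:
                ica.fit(x)
            except Exception as exc:  # numerical failure; retry with a new seed
                last_exc = exc
                continue
            if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
                return IcaTransform(ica, n_components, seed_used)
            last_exc = RuntimeError(f"FastICA did not converge (seed {seed_used})")
    raise RuntimeError(
        f"ICA reduction failed after {max_retries} seeded attempts: {last_exc}"
    )


# ---------------------------------------------------------------------------
# Cox model and concordance
# ---------------------------------------------------------------------------

@dataclass
class CoxModel:
    model: CoxPHSurvivalAnalysis
    penalty: float

    @property
    def coef(self) -> np.ndarray:
        return self.model.coef_

    def risk(self, x: np.ndarray) -> np.ndarray:
        """Linear risk scores; higher = higher hazard."""
        return self.model.predict(np.asarray(x, dtype=np.float64))


def fit_cox(
    train_features: np.ndarray,
    train_records,
    penalty: float = 0.0,
    on_error: str = "raise",
    max_penalty: float = 100.0,
) -> CoxModel:
    """Ridge-penalized Cox partial-likelihood fit.

    ``on_error="boost_penalty"`` retries with a tenfold-increased ridge
    penalty on separation / non-convergence, up to ``max_penalty``.
    """
    x = np.asarray(train_features, dtype=np.float64)
    time, event = _records_arrays(train_records)
    if not event.any():
        raise ValueError("training fold contains no events; Cox fit impossible")
    y = Surv.from_arrays(event=event, time=time)
    alpha = float(penalty)
    while True:
        try:
            est = CoxPHSurvivalAnalysis(alpha=alpha, n_iter=200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(x, y)
            if not np.all(np.isfinite(est.coef_)):
                raise ArithmeticError("non-finite Cox coefficients")
            return CoxModel(est, alpha)
        except Exception as exc:
            if on_error == "boost_penalty":
                alpha = max(alpha * 10.0, 0.1)
                if alpha <= max_penalty:
                    continue
            raise RuntimeError(f"Cox fit failed (penalty {alpha}): {exc}") from exc


def concordance_index(records, risks) -> float:
    """Harrell's concordance index.

    A pair (i, j) is comparable when the smaller time carries an event
    (tied times with both events are not comparable; a tie between an
    event and a censored time is comparable with the event assumed
    first). Concordant pairs score 1, risk ties 0.5, discordant 0;
    returns the score divided by the number of comparable pairs.
    """
    time, event = _records_arrays(records)
    risk = np.asarray(risks, dtype=np.float64)
    if risk.shape[0] != time.shape[0]:
        raise ValueError("records and risks length mismatch")
    t_i, t_j = time[:, None], time[None, :]
    e_i = event[:, None]
    e_j = event[None, :]
    comparable = ((t_i < t_j) & e_i) | ((t_i == t_j) & e_i & ~e_j)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs (all censored or fully tied)")
    r_i, r_j = risk[:, None], risk[None, :]
    score = np.where(r_i > r_j, 1.0, np.where(r_i == r_j, 0.5, 0.0))
    return float((score * comparable).sum() / n_comp)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Nested CV layout and hyperparameter grid.

    Outer loop: ``n_outer`` folds (80/20 at the default 5), repeated
    ``n_repeats`` times with different shuffles. Inner loop: ``n_inner``
    folds grid-searching ICA component count, Cox ridge penalty and the
    correlation-elimination threshold. Component counts are clamped to
    the feasible maximum of each training split.
    """

    n_outer: int = 5
    n_repeats: int = 20
    n_inner: int = 5
    n_components_grid: tuple[int, ...] = (10, 20, 50)
    penalty_grid: tuple[float, ...] = (0.0, 0.1, 1.0)
    corr_threshold_grid: tuple[float, ...] = (0.95,)
    seed: int = 0
    cox_on_error: str = "boost_penalty"


@dataclass
class CVResult:
    """Per-split c-indices plus summaries and the producing configuration."""

    per_split_cindex: list[float]
    mean: float
    std: float
    per_repetition: list[dict[str, float]]
    config: dict[str, Any]
    seed: int
    splits: list[dict[str, Any]] = field(default_factory=list)
    failures: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "per_split_cindex": self.per_split_cindex,
            "mean": self.mean,
            "std": self.std,
            "per_repetition": self.per_repetition,
            "config": self.config,
            "seed": self.seed,
            "failures": self.failures,
        }


@dataclass
class FittedPipeline:
    """All objects learned on one training split, applied as-is to test data."""

    scaler: StandardScaler1D
    kept: np.ndarray
    ica: IcaTransform
    cox: CoxModel

    def risk(self, x: np.ndarray) -> np.ndarray:
        z = self.scaler.apply(x)[:, self.kept]
        return self.cox.risk(self.ica.apply(z))

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for arr in (
            self.scaler.mean,
            self.scaler.scale,
            self.kept.astype(np.float64),
            self.ica.ica.components_,
            self.ica.ica.mean_,
            self.cox.coef,
        ):
            h.update(np.ascontiguousarray(arr, dtype=np.float64).tobytes())
        return h.hexdigest()


def fit_preprocess(
    x_train: np.ndarray, corr_threshold: float, n_components: int, seed: int
) -> tuple[StandardScaler1D, np.ndarray, IcaTransform, np.ndarray]:
    """Fit scaler -> correlation filter -> ICA on one training split.

    Returns the fitted objects plus the reduced training matrix. The
    component count is clamped to the feasible maximum of the split.
    """
    scaler = fit_scaler(x_train)
    z = scaler.apply(x_train)
    kept = drop_correlated(z, corr_threshold)
    if kept.size == 0:
        raise ValueError("correlation filter removed all features")
    z = z[:, kept]
    k = min(n_components, z.shape[0] - 1, z.shape[1])
    ica = reduce_ica(z, k, seed)
    return scaler, kept, ica, ica.apply(z)


def fit_pipeline(
    x_train: np.ndarray,
    records_train,
    corr_threshold: float,
    n_components: int,
    penalty: float,
    seed: int,
    cox_on_error: str = "boost_penalty",
) -> FittedPipeline:
    """Fit scaler -> correlation filter -> ICA -> Cox on one training split."""
    scaler, kept, ica, z = fit_preprocess(x_train, corr_threshold, n_components, seed)
    cox = fit_cox(z, records_train, penalty, on_error=cox_on_error)
    return FittedPipeline(scaler, kept, ica, cox)


def _grid(config: CVConfig):
    return list(
        product(config.corr_threshold_grid, config.n_components_grid, config.penalty_grid)
    )


def nested_cv(features: CohortFeatures, records, config: CVConfig | None = None) -> CVResult:
    """Repeated nested cross-validation of the Cox pipeline.

    Returns every outer-split c-index (``n_outer * n_repeats`` values),
    their overall mean/std, and a per-repetition summary over that
    repetition's outer folds (both views are reported because a "mean
    over five test folds" is ambiguous under repetition). Failed splits
    are recorded in ``failures`` and excluded from the summaries rather
    than silently dropped.
    """
    config = config or CVConfig()
    records = list(records)
    n = features.matrix.shape[0]
    if len(records) != n:
        raise ValueError("records and features are misaligned")
    if n < 25:
        raise ValueError(f"nested CV needs at least 25 patients, got {n}")
    x = features.matrix
    ss = np.random.SeedSequence(config.seed)
    rep_states = ss.generate_state(2 * config.n_repeats) % (2**31 - 1)
    per_split: list[float] = []
    per_rep: list[dict[str, float]] = []
    splits_meta: list[dict[str, Any]] = []
    failures: list[dict[str, Any]] = []
    for rep in range(config.n_repeats):
        outer = KFold(config.n_outer, shuffle=True, random_state=int(rep_states[2 * rep]))
        rep_scores = []
        for fold, (tr, te) in enumerate(outer.split(x)):
            try:
                ranked = _select_hyperparams(x[tr], [records[i] for i in tr], config, rep, fold)
                pipe, best, refit_err = None, None, None
                for params in ranked:  # fall back through the ranked grid
                    try:
                        pipe = fit_pipeline(
                            x[tr], [records[i] for i in tr], *params,
                            seed=config.seed, cox_on_error=config.cox_on_error,
                        )
                        best = params
                        break
                    except Exception as exc:
                        refit_err = exc
                if pipe is None:
                    raise RuntimeError(f"every grid point failed on refit: {refit_err}")
                c = concordance_index([records[i] for i in te], pipe.risk(x[te]))
            except Exception as exc:
                failures.append({"repeat": rep, "fold": fold, "error": str(exc)})
                continue
            per_split.append(c)
            rep_scores.append(c)
            splits_meta.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "train_idx": tr.tolist(),
                    "test_idx": te.tolist(),
                    "hyperparams": {
                        "corr_threshold": best[0],
                        "n_components": best[1],
                        "penalty": best[2],
                    },
                    "cindex": c,
                    "pipeline_fingerprint": pipe.fingerprint(),
                }
            )
        if rep_scores:
            per_rep.append(
                {
                    "repeat": rep,
                    "mean": float(np.mean(rep_scores)),
                    "std": float(np.std(rep_scores)),
                }
            )
    if not per_split:
        raise RuntimeError(f"all CV splits failed: {failures}")
    return CVResult(
        per_split_cindex=[float(c) for c in per_split],
        mean=float(np.mean(per_split)),
        std=float(np.std(per_split)),
        per_repetition=per_rep,
        config={
            "n_outer": config.n_outer,
            "n_repeats": config.n_repeats,
            "n_inner": config.n_inner,
            "n_components_grid": list(config.n_components_grid),
            "penalty_grid": list(config.penalty_grid),
            "corr_threshold_grid": list(config.corr_threshold_grid),
        },
        seed=config.seed,
        splits=splits_meta,
        failures=failures,
    )


def _select_hyperparams(x_tr, records_tr, config: CVConfig, rep: int, fold: int):
    """Inner-fold grid search on outer-training data only.

    Returns the grid ranked by mean inner-validation c-index (ties keep
    grid order); grid points that fail on every inner fold rank last.
    """
    inner_state = int(
        (np.random.SeedSequence([config.seed, rep, fold]).generate_state(1)[0]) % (2**31 - 1)
    )
    inner = KFold(config.n_inner, shuffle=True, random_state=inner_state)
    grid = _grid(config)
    fold_scores: dict[tuple, list[float]] = {params: [] for params in grid}
    for itr, ite in inner.split(x_tr):
        rec_itr = [records_tr[i] for i in itr]
        rec_ite = [records_tr[i] for i in ite]
        # the preprocessing stack is shared by every penalty value
        for thr, k in product(config.corr_threshold_grid, config.n_components_grid):
            try:
                scaler, kept, ica, z = fit_preprocess(x_tr[itr], thr, k, config.seed)
            except Exception:
                continue
            for pen in config.penalty_grid:
                try:
                    cox = fit_cox(z, rec_itr, pen, on_error=config.cox_on_error)
                    pipe = FittedPipeline(scaler, kept, ica, cox)
                    fold_scores[(thr, k, pen)].append(
                        concordance_index(rec_ite, pipe.risk(x_tr[ite]))
                    )
                except Exception:
                    continue
    scored = []
    for gi, params in enumerate(grid):
        scores = fold_scores[params]
        mean_score = float(np.mean(scores)) if scores else -np.inf
        scored.append((-mean_score, gi, params))
    scored.sort(key=lambda t: (t[0], t[1]))
    return [params for _, _, params in scored]
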