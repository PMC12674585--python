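"""Model calibration: partitioning, engines, repeated CV, residual trimming.

The harness is engine-agnostic: fold assignments and partition splits are
functions of the protocol seed only, so swapping engines changes predictions
but never the partitioning. The three engines are

* ``pls``  — PLS1 regression fitted by NIPALS (implemented here), with the
  number of latent components chosen by a one-standard-error rule on
  repeated-CV RMSE;
* ``svm``  — epsilon-SVR with an RBF kernel at C = 1 (scikit-learn);
* ``xgb``  — gradient-boosted trees at the fixed configuration
  nrounds=200, max_depth=5, eta=0.3, gamma=5, subsample=0.7,
  colsample_bytree=0.7, min_child_weight=1 (xgboost).

Calibration follows a two-stage protocol: repeated 5x5 cross-validation on
the calibration partition, removal of the 20% of samples with the largest
cross-validated residuals, and a refit of the trimmed set. Holdout samples
never influence trimming, component selection, MSC references or fitting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ConfigurationError, DegenerateInputError, SizingError
from .metrics import MetricSet, compute_metrics
from .preprocess import TREATMENT_NAMES, TreatmentSpec

XGB_DEFAULTS = dict(
    nrounds=200, max_depth=5, eta=0.3, gamma=5.0,
    subsample=0.7, colsample_bytree=0.7, min_child_weight=1,
)
SVM_DEFAULTS = dict(kernel="rbf", C=1.0, epsilon=0.1, gamma_rule="scale")

ENGINES = ("pls", "svm", "xgb")


@dataclass(frozen=True)
class EngineSpec:
    engine: str
    pls_max_components: int = 20
    svm_params: dict = field(default_factory=lambda: dict(SVM_DEFAULTS))
    xgb_params: dict = field(default_factory=lambda: dict(XGB_DEFAULTS))

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ConfigurationError(f"unknown engine {self.engine!r}")


@dataclass(frozen=True)
class CVProtocol:
    n_folds: int = 5
    n_repeats: int = 5
    trim_fraction: float = 0.20
    split_fraction: float = 0.80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be >= 2")
        if not 0 <= self.trim_fraction < 1:
            raise ConfigurationError("trim_fraction must be in [0, 1)")
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split_fraction must be in (0, 1)")


# ---------------------------------------------------------------------------
# Partitioning

def split_dataset(X, y, plot_ids, protocol: CVProtocol):
    """Seeded simple random split at the plot level.

    Rows of ``X``/``y`` are plots, so grouping by plot is implicit: each plot
    lands wholly in one partition. Returns ``(calibration, holdout)`` as
    ``(X, y, ids)`` triples; the calibration side gets
    ``floor(split_fraction * n)`` plots.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    plot_ids = np.asarray(plot_ids)
    n = len(plot_ids)
    if n < 10:
        raise SizingError(f"need >= 10 plots to split, got {n}")
    rng = np.random.default_rng(np.random.SeedSequence([int(protocol.seed), 83911]))
    perm = rng.permutation(n)
    n_cal = int(math.floor(protocol.split_fraction * n))
    cal, hold = np.sort(perm[:n_cal]), np.sort(perm[n_cal:])
    return (X[cal], y[cal], plot_ids[cal]), (X[hold], y[hold], plot_ids[hold])


def aggregate_readings(ds) -> tuple[np.ndarray, np.ndarray]:
    """Per-plot mean spectrum. Returns (plot_ids, matrix), one row per plot,
    in order of first appearance."""
    plots = pd.unique(ds.meta["plot_id"])
    index = {p: i for i, p in enumerate(plots)}
    sums = np.zeros((len(plots), ds.n_channels))
    counts = np.zeros(len(plots))
    rows = ds.meta["plot_id"].map(index).to_numpy()
    np.add.at(sums, rows, ds.absorbance)
    np.add.at(counts, rows, 1.0)
    return np.asarray(plots), sums / counts[:, None]


def trait_vector(traits: pd.DataFrame, plot_ids, trait: str) -> np.ndarray:
    """Trait values aligned to a plot-id order."""
    lookup = traits.set_index("plot_id")[trait]
    return lookup.loc[np.asarray(plot_ids)].to_numpy(dtype=float)


def fold_assignments(n: int, protocol: CVProtocol) -> np.ndarray:
    """(n_repeats, n) fold labels in 0..n_folds-1, derived from the protocol
    seed only — identical for every engine."""
    if n < protocol.n_folds * 2:
        raise SizingError("too few samples for the fold count")
    out = np.empty((protocol.n_repeats, n), dtype=int)
    for rep in range(protocol.n_repeats):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(protocol.seed), 59359, rep])
        )
        perm = rng.permutation(n)
        labels = np.empty(n, dtype=int)
        for f, chunk in enumerate(np.array_split(perm, protocol.n_folds)):
            labels[chunk] = f
        out[rep] = labels
    return out


def _engine_seed(protocol: CVProtocol, *stream) -> int:
    ss = np.random.SeedSequence([int(protocol.seed), 7211] + [int(s) for s in stream])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# PLS1 by NIPALS

class NIPALSPLS:
    """PLS1 regression fitted by the classical NIPALS iteration.

    X and y are column-centred; each component's weight vector is the
    (normalised) covariance X'y of the deflated matrices, maximising the
    score-response covariance; X is deflated by the score/loading outer
    product and y by its fitted part. Regression coefficients are returned
    in original units via the centring parameters.
    """

    def __init__(self, n_components: int):
        self.n_components = int(n_components)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NIPALSPLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if np.allclose(y, y[0]):
            raise DegenerateInputError("zero-variance response")
        a_max = min(self.n_components, n - 1, p)
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        W, P, Q = [], [], []
        for _ in range(a_max):
            w = Xc.T @ yc
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                break
            w /= norm
            t = Xc @ w
            tt = float(t @ t)
            if tt < 1e-12:
                break
            p_load = Xc.T @ t / tt
            q = float(yc @ t) / tt
            Xc = Xc - np.outer(t, p_load)
            yc = yc - q * t
            W.append(w)
            P.append(p_load)
            Q.append(q)
        if not W:
            raise DegenerateInputError("no extractable PLS component")
        self.W_ = np.column_stack(W)
        self.P_ = np.column_stack(P)
        self.q_ = np.asarray(Q)
        self.n_components_ = self.W_.shape[1]
        # coefficients for every truncation 1..A (reused by component selection)
        self.coef_path_ = np.empty((self.n_components_, X.shape[1]))
        for a in range(1, self.n_components_ + 1):
            R = self.W_[:, :a] @ np.linalg.inv(self.P_[:, :a].T @ self.W_[:, :a])
            self.coef_path_[a - 1] = R @ self.q_[:a]
        self.coef_ = self.coef_path_[-1]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_

    def predict_components(self, X: np.ndarray) -> np.ndarray:
        """(n, A) predictions using 1..A components."""
        X = np.asarray(X, dtype=float)
        return self.y_mean_ + (X - self.x_mean_) @ self.coef_path_.T


def fit_pls(X, y, n_components: int) -> NIPALSPLS:
    """Fit a NIPALS PLS1 model; errors on a zero-variance response."""
    return NIPALSPLS(n_components).fit(np.asarray(X, float), np.asarray(y, float))


# ---------------------------------------------------------------------------
# Engine dispatch

class _ConstantModel:
    def __init__(self, value: float):
        self.value = float(value)

    def predict(self, X) -> np.ndarray:
        return np.full(np.atleast_2d(X).shape[0], self.value)


class FittedEngine:
    """Uniform predict contract plus a parameter echo for reporting."""

    def __init__(self, model, spec: EngineSpec, params: dict, n_components=None):
        self.model = model
        self.spec = spec
        self.params = dict(params)
        self.n_components = n_components

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.model.predict(np.asarray(X, dtype=float)), dtype=float)


def fit_engine(
    X, y, spec: EngineSpec, seed: int | None = None, n_components: int | None = None
) -> FittedEngine:
    """Fit the configured engine. Stochastic engines take ``seed``; PLS takes
    ``n_components`` (defaults to the spec cap). A constant response yields a
    constant predictor for every engine."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if spec.engine == "pls":
        if np.allclose(y, y[0]):
            return FittedEngine(_ConstantModel(y[0]), spec, {"engine": "pls"}, 0)
        a = spec.pls_max_components if n_components is None else n_components
        model = fit_pls(X, y, a)
        params = {"engine": "pls", "n_components": model.n_components_}
        return FittedEngine(model, spec, params, model.n_components_)
    if spec.engine == "svm":
        from sklearn.svm import SVR

        p = dict(SVM_DEFAULTS, **spec.svm_params)
        gamma = "scale" if p.get("gamma_rule", "scale") == "scale" else p["gamma_rule"]
        model = SVR(kernel=p["kernel"], C=p["C"], epsilon=p["epsilon"], gamma=gamma)
        model.fit(X, y)
        params = {"engine": "svm", "kernel": p["kernel"], "C": p["C"],
                  "epsilon": p["epsilon"]}
        return FittedEngine(model, spec, params)
    if spec.engine == "xgb":
        from xgboost import XGBRegressor

        p = dict(XGB_DEFAULTS, **spec.xgb_params)
        model = XGBRegressor(
            n_estimators=int(p["nrounds"]),
            max_depth=int(p["max_depth"]),
            learning_rate=float(p["eta"]),
            gamma=float(p["gamma"]),
            subsample=float(p["subsample"]),
            colsample_bytree=float(p["colsample_bytree"]),
            min_child_weight=float(p["min_child_weight"]),
            random_state=0 if seed is None else int(seed),
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
        model.fit(X, y)
        params = {"engine": "xgb", **{k: p[k] for k in XGB_DEFAULTS}}
        return FittedEngine(model, spec, params)
    raise ConfigurationError(f"unknown engine {spec.engine!r}")


# ---------------------------------------------------------------------------
# Repeated cross-validation

@dataclass
class CVResult:
    oof_predictions: np.ndarray  # (n_repeats, n)
    per_repeat_metrics: list
    metrics: MetricSet  # field-wise mean over repetitions


def _mean_metrics(metric_sets: list[MetricSet]) -> MetricSet:
    fields = ("r", "r2", "rmse", "bias_additive", "slope", "rpd", "rpiq")
    means = {f: float(np.mean([getattr(m, f) for m in metric_sets])) for f in fields}
    return MetricSet(n=metric_sets[0].n, **means)


def repeated_cv(
    X,
    y,
    spec: EngineSpec,
    protocol: CVProtocol,
    n_components: int | None = None,
) -> CVResult:
    """Repeated k-fold CV: per repetition, out-of-fold predictions are pooled
    over folds and scored; reported metrics are the mean over repetitions."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = fold_assignments(n, protocol)
    oof = np.empty((protocol.n_repeats, n))
    per_repeat = []
    for rep in range(protocol.n_repeats):
        for f in range(protocol.n_folds):
            test = folds[rep] == f
            if test.sum() < 2 or (~test).sum() < 2:
                raise SizingError("fold with fewer than 2 samples")
            model = fit_engine(
                X[~test], y[~test], spec,
                seed=_engine_seed(protocol, rep, f),
                n_components=n_components,
            )
            oof[rep, test] = model.predict(X[test])
        per_repeat.append(compute_metrics(y, oof[rep]))
    return CVResult(oof, per_repeat, _mean_metrics(per_repeat))


def select_pls_components(
    X, y, protocol: CVProtocol, max_components: int = 20
) -> int:
    """Smallest component count whose repeated-CV RMSE is within one standard
    error (over repetitions) of the global minimum."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    folds = fold_assignments(n, protocol)
    train_cap = n - math.ceil(n / protocol.n_folds)
    a_max = max(1, min(max_components, train_cap - 1, X.shape[1]))
    rmse = np.full((protocol.n_repeats, a_max), np.nan)
    for rep in range(protocol.n_repeats):
        preds = np.empty((n, a_max))
        for f in range(protocol.n_folds):
            test = folds[rep] == f
            model = fit_pls(X[~test], y[~test], a_max)
            pk = model.predict_components(X[test])  # (n_test, fitted A)
            # pad with the last column if rank ran out early
            if pk.shape[1] < a_max:
                pk = np.column_stack(
                    [pk] + [pk[:, -1]] * (a_max - pk.shape[1])
                )
            preds[test] = pk
        rmse[rep] = np.sqrt(((preds - y[:, None]) ** 2).mean(axis=0))
    mean = rmse.mean(axis=0)
    se = rmse.std(axis=0, ddof=1) / math.sqrt(protocol.n_repeats) if protocol.n_repeats > 1 else np.zeros(a_max)
    best = int(np.argmin(mean))
    threshold = mean[best] + se[best]
    return int(np.nonzero(mean <= threshold)[0][0]) + 1


# ---------------------------------------------------------------------------
# Trim-and-refit calibration runs

@dataclass
class CalibrationRun:
    """One (trait x sample-type x treatment x engine) calibration."""

    trait: str
    sample_type: str
    treatment: TreatmentSpec
    engine: EngineSpec
    calibration_ids: list
    trimmed_ids: list
    holdout_ids: list
    cv_predictions: np.ndarray  # post-trim pooled OOF, (n_repeats, n_retained)
    holdout_predictions: np.ndarray
    metrics_cv: MetricSet
    metrics_val: MetricSet | None
    chosen_pls_components: int | None
    retained_ids: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(
            trait=self.trait,
            sample_type=self.sample_type,
            treatment=dict(name=self.treatment.name, params=self.treatment.resolved_params()),
            engine=self.engine.engine,
            calibration_ids=[str(i) for i in self.calibration_ids],
            trimmed_ids=[str(i) for i in self.trimmed_ids],
            holdout_ids=[str(i) for i in self.holdout_ids],
            retained_ids=[str(i) for i in self.retained_ids],
            cv_predictions=np.asarray(self.cv_predictions).tolist(),
            holdout_predictions=np.asarray(self.holdout_predictions).tolist(),
            metrics_cv=self.metrics_cv.to_dict(),
            metrics_val=None if self.metrics_val is None else self.metrics_val.to_dict(),
            chosen_pls_components=self.chosen_pls_components,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def residual_trim_refit(
    X,
    y,
    ids,
    spec: EngineSpec,
    protocol: CVProtocol,
    holdout: tuple | None = None,
    trait: str = "",
    sample_type: str = "",
    treatment: TreatmentSpec | None = None,
) -> CalibrationRun:
    """Two-stage calibration with residual trimming.

    Stage 1 runs repeated CV on the full calibration set; each sample's
    residual is |observed - out-of-fold prediction| averaged over the
    repetitions (cross-validated residuals, so the trim is not optimistic).
    The ``floor(trim_fraction * n)`` largest-residual samples are removed
    exactly once. Stage 2 repeats CV on the retained set (the reported
    calibration metrics) and refits the final model on the retained set,
    which predicts the holdout for the validation metrics.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.asarray(ids)
    n = len(y)
    n_trim = int(math.floor(protocol.trim_fraction * n))
    if n - n_trim < 2 * protocol.n_folds:
        raise SizingError("trimming would leave too few samples for CV")

    n_comp = None
    if spec.engine == "pls":
        n_comp = select_pls_components(X, y, protocol, spec.pls_max_components)

    stage1 = repeated_cv(X, y, spec, protocol, n_components=n_comp)
    if n_trim > 0:
        resid = np.abs(y - stage1.oof_predictions.mean(axis=0))
        order = np.argsort(-resid, kind="stable")
        trim_idx = np.sort(order[:n_trim])
        keep = np.setdiff1d(np.arange(n), trim_idx)
    else:
        trim_idx = np.array([], dtype=int)
        keep = np.arange(n)

    if n_trim > 0:
        stage2 = repeated_cv(X[keep], y[keep], spec, protocol, n_components=n_comp)
    else:
        stage2 = stage1

    final = fit_engine(
        X[keep], y[keep], spec,
        seed=_engine_seed(protocol, 999), n_components=n_comp,
    )
    if holdout is not None:
        Xv, yv, idv = holdout
        holdout_pred = final.predict(Xv)
        metrics_val = compute_metrics(np.asarray(yv, float), holdout_pred)
        holdout_ids = list(np.asarray(idv))
    else:
        holdout_pred = np.array([])
        metrics_val = None
        holdout_ids = []

    run = CalibrationRun(
        trait=trait,
        sample_type=sample_type,
        treatment=treatment if treatment is not None else TreatmentSpec("raw"),
        engine=spec,
        calibration_ids=list(ids),
        trimmed_ids=list(ids[trim_idx]),
        holdout_ids=holdout_ids,
        cv_predictions=stage2.oof_predictions,
        holdout_predictions=holdout_pred,
        metrics_cv=stage2.metrics,
        metrics_val=metrics_val,
        chosen_pls_components=n_comp,
        retained_ids=list(ids[keep]),
    )
    run.final_model = final  # used by the pipeline to predict all plots
    return run


# ---------------------------------------------------------------------------
# Treatment selection (PLS screening stage)

def select_treatment(runs: list[CalibrationRun]) -> TreatmentSpec:
    """Pick the pre-treatment that best combines high calibration-CV Pearson R
    and low RMSE across both sample types.

    Only PLS runs enter the screening (one PLS fit per treatment and sample
    type). Within each sample type, treatments are ranked on R (descending)
    and RMSE (ascending); the winner minimises the mean rank. Exact ties are
    broken by the fixed treatment-name order.
    """
    pls_runs = [r for r in runs if r.engine.engine == "pls"]
    if not pls_runs:
        raise ConfigurationError("no PLS runs to select a treatment from")
    frame = pd.DataFrame(
        dict(
            treatment=[r.treatment.name for r in pls_runs],
            sample_type=[r.sample_type for r in pls_runs],
            r=[r.metrics_cv.r for r in pls_runs],
            rmse=[r.metrics_cv.rmse for r in pls_runs],
        )
    )
    ranks = []
    for _, grp in frame.groupby("sample_type"):
        ranks.append(
            pd.DataFrame(
                dict(
                    treatment=grp["treatment"].to_numpy(),
                    rank_r=rankdata(-grp["r"].to_numpy()),
                    rank_rmse=rankdata(grp["rmse"].to_numpy()),
                )
            )
        )
    mean_rank = (
        pd.concat(ranks)
        .melt(id_vars="treatment", value_name="rank")
        .groupby("treatment")["rank"]
        .mean()
    )
    order = {name: i for i, name in enumerate(TREATMENT_NAMES)}
    winner = min(mean_rank.index, key=lambda t: (mean_rank[t], order.get(t, 99)))
    for r in pls_runs:
        if r.treatment.name == winner:
            return r.treatment
    raise ConfigurationError("winner not found among runs")  # pragma: no cover
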