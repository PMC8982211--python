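"""Unfolded-PLS (UPLS) calibration of EEM spectra against reference viability.

The calibration chain is the classical second-order soft-sensor recipe:
unfold every sample's masked EEM to a fixed-order vector, stack the vectors
into a samples × variables matrix, split it at random into train and test
sets, autoscale each variable on the training rows, and regress the
reference viability on the scaled spectra with NIPALS PLS1.  The number of
latent variables is chosen by venetian-blinds cross-validation, minimizing
the root-mean-square error of cross-validation (RMSECV); scaling and
response centering are refit inside every fold so no held-out information
leaks into the model.

The reference response is, by default, the dose-level mean of the MTT
replicate viabilities: each EEM sample inherits the mean viability of its
UV dose.  Pairing individual MTT wells with individual EEM wells is offered
as an option but is not physically grounded (the wells differ).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .eem import (
    AcquisitionGeometry,
    ExcitationEmissionMatrix,
    GeometryError,
    build_mask,
    unfold,
)

_ZERO_VAR_TOL = 1e-12


@dataclass
class DataMatrix:
    """Samples × variables matrix of unfolded EEMs with row/column metadata."""

    values: np.ndarray
    meta: pd.DataFrame  # columns: sample_id, dose_min, replicate
    columns: np.ndarray  # (n_variables, 2): (λex, λem) per column, canonical order
    geometry: AcquisitionGeometry

    @property
    def n_samples(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_variables(self) -> int:
        return int(self.values.shape[1])

    def take(self, rows: np.ndarray) -> "DataMatrix":
        return DataMatrix(
            values=self.values[rows],
            meta=self.meta.iloc[rows].reset_index(drop=True),
            columns=self.columns,
            geometry=self.geometry,
        )


def assemble_matrix(eems: list[ExcitationEmissionMatrix]) -> DataMatrix:
    """Stack unfolded EEMs row-wise; all samples must share one geometry."""
    if not eems:
        raise ValueError("cannot assemble a data matrix from an empty EEM list")
    geometry = eems[0].geometry
    if any(e.geometry != geometry for e in eems):
        raise GeometryError("EEMs with mixed acquisition geometries")
    mask = build_mask(geometry)
    values = np.vstack([unfold(e, mask).values for e in eems])
    meta = pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in eems],
            "dose_min": [e.dose_min for e in eems],
            "replicate": [e.replicate for e in eems],
        }
    )
    ex = geometry.ex_wavelengths[mask.index_map[:, 0]]
    em = geometry.em_wavelengths[mask.index_map[:, 1]]
    return DataMatrix(values=values, meta=meta, columns=np.column_stack([ex, em]),
                      geometry=geometry)


@dataclass(frozen=True)
class SplitSpec:
    """Random train/test partition specification."""

    train_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass
class TrainTestSplit:
    train: DataMatrix
    test: DataMatrix
    train_indices: np.ndarray
    test_indices: np.ndarray


def split_train_test(matrix: DataMatrix, spec: SplitSpec) -> TrainTestSplit:
    """Uniformly random disjoint partition; |train| = round(fraction · n)."""
    n = matrix.n_samples
    n_train = int(np.floor(spec.train_fraction * n + 0.5))
    if n_train < 1 or n_train >= n:
        raise ValueError(
            f"train_fraction {spec.train_fraction} leaves an empty train or test "
            f"set for n={n}"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return TrainTestSplit(
        train=matrix.take(train_idx),
        test=matrix.take(test_idx),
        train_indices=train_idx,
        test_indices=test_idx,
    )


@dataclass
class ScalingParams:
    """Per-variable autoscaling parameters fitted on training rows."""

    mean: np.ndarray
    sd: np.ndarray  # sample SD (n−1 denominator)
    zero_variance: np.ndarray  # bool flags for columns with SD below tolerance


def autoscale_fit(values: np.ndarray, tol: float = _ZERO_VAR_TOL) -> ScalingParams:
    """Fit per-column mean and sample SD; flag (near-)constant columns."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("autoscaling needs at least 2 training rows")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    return ScalingParams(mean=mean, sd=sd, zero_variance=sd <= tol)


def autoscale_apply(values: np.ndarray, params: ScalingParams) -> np.ndarray:
    """(x − mean)/SD per column; zero-variance columns map to 0 with a warning."""
    values = np.asarray(values, dtype=float)
    if values.shape[1] != params.mean.shape[0]:
        raise ValueError(
            f"column count {values.shape[1]} does not match scaling parameters "
            f"({params.mean.shape[0]} columns)"
        )
    safe_sd = np.where(params.zero_variance, 1.0, params.sd)
    scaled = (values - params.mean) / safe_sd
    if params.zero_variance.any():
        warnings.warn(
            f"{int(params.zero_variance.sum())} zero-variance column(s) scaled to 0",
            stacklevel=2,
        )
        scaled[:, params.zero_variance] = 0.0
    return scaled


@dataclass
class PLSCore:
    """NIPALS PLS1 factors and the assembled regression vector (scaled space)."""

    weights: np.ndarray  # W, (n_variables, n_lv), unit-norm columns
    x_loadings: np.ndarray  # P, (n_variables, n_lv)
    y_loadings: np.ndarray  # q, (n_lv,)
    scores: np.ndarray  # T, (n_train, n_lv)
    coef: np.ndarray  # regression vector b, (n_variables,)
    n_lv: int


def fit_pls(
    X: np.ndarray, y: np.ndarray, n_lv: int, tol: float = 1e-12
) -> PLSCore:
    """NIPALS PLS1 on scaled predictors and a centered response.

    Per component: ``w ∝ Xᵀy`` (unit norm), ``t = Xw``, ``p = Xᵀt/(tᵀt)``,
    ``q = yᵀt/(tᵀt)``, then deflation ``X ← X − t pᵀ``, ``y ← y − t q``.
    The regression vector is ``W (PᵀW)⁻¹ q``.  Stops early with a warning
    if the residual covariance vanishes, returning fewer components.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y row counts differ")
    if not (1 <= n_lv <= min(n - 1, p)):
        raise ValueError(
            f"n_lv={n_lv} outside the valid range [1, {min(n - 1, p)}]"
        )
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    a = 0
    for _ in range(n_lv):
        cov = X.T @ y
        norm = np.linalg.norm(cov)
        if norm <= tol:
            warnings.warn(
                f"covariance vanished after {a} component(s); stopping early",
                stacklevel=2,
            )
            break
        w = cov / norm
        t = X @ w
        tt = float(t @ t)
        if tt <= tol:
            warnings.warn(
                f"degenerate score vector after {a} component(s); stopping early",
                stacklevel=2,
            )
            break
        p_vec = X.T @ t / tt
        q_a = float(y @ t) / tt
        X = X - np.outer(t, p_vec)
        y = y - t * q_a
        W[:, a], P[:, a], q[a], T[:, a] = w, p_vec, q_a, t
        a += 1
    W, P, q, T = W[:, :a], P[:, :a], q[:a], T[:, :a]
    if a == 0:
        coef = np.zeros(p)
    else:
        coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSCore(weights=W, x_loadings=P, y_loadings=q, scores=T, coef=coef, n_lv=a)


@dataclass
class CVResult:
    """RMSECV (% viability) per candidate LV count and the chosen count.

    ``lv_counts[0] == 0`` is the mean-only model; the chosen count is the
    argmin of the RMSECV curve, smallest count on ties.
    """

    lv_counts: np.ndarray
    rmsecv: np.ndarray
    n_lv: int
    n_splits: int


def venetian_blind_folds(n: int, n_splits: int) -> list[np.ndarray]:
    """Fold assignment: row ``i`` (current order) belongs to fold ``i % n_splits``."""
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    if n < n_splits:
        raise ValueError(f"fewer rows ({n}) than folds ({n_splits})")
    return [np.arange(n)[np.arange(n) % n_splits == k] for k in range(n_splits)]


def cross_validate(
    X: np.ndarray, y: np.ndarray, max_lv: int, n_splits: int = 10
) -> CVResult:
    """Venetian-blinds RMSECV over LV counts 0..max_lv on *unscaled* data.

    Autoscaling and response centering are refit on each fold's retained
    rows; held-out predictions at every candidate LV count are pooled into
    one RMSECV per count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    folds = venetian_blind_folds(n, n_splits)
    sq_err = np.zeros(max_lv + 1)  # index = LV count
    for held in folds:
        keep = np.setdiff1d(np.arange(n), held)
        scaling = autoscale_fit(X[keep])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xtr = autoscale_apply(X[keep], scaling)
            Xte = autoscale_apply(X[held], scaling)
        y_mean = y[keep].mean()
        a_max = min(max_lv, len(keep) - 1, X.shape[1])
        core = fit_pls(Xtr, y[keep] - y_mean, a_max)
        sq_err[0] += float(np.sum((y[held] - y_mean) ** 2))
        for a in range(1, max_lv + 1):
            a_eff = min(a, core.n_lv)
            if a_eff == 0:
                pred = np.full(len(held), y_mean)
            else:
                Wa = core.weights[:, :a_eff]
                coef_a = Wa @ np.linalg.solve(
                    core.x_loadings[:, :a_eff].T @ Wa, core.y_loadings[:a_eff]
                )
                pred = Xte @ coef_a + y_mean
            sq_err[a] += float(np.sum((y[held] - pred) ** 2))
    rmsecv = np.sqrt(sq_err / n)
    chosen = int(np.argmin(rmsecv))  # argmin returns the first (smallest) on ties
    return CVResult(
        lv_counts=np.arange(max_lv + 1), rmsecv=rmsecv, n_lv=chosen, n_splits=n_splits
    )


@dataclass
class UPLSModel:
    """A fitted unfolded-PLS viability model: scaling + factors + CV record."""

    scaling: ScalingParams
    y_mean: float
    core: PLSCore
    cv: CVResult
    geometry: AcquisitionGeometry
    split: SplitSpec
    response_mode: str = "dose_mean"

    def predict_values(self, values: np.ndarray) -> np.ndarray:
        """Predicted viability (%) for raw unfolded rows."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled = autoscale_apply(np.atleast_2d(values), self.scaling)
        return scaled @ self.core.coef + self.y_mean

    def predict(self, data: DataMatrix | list[ExcitationEmissionMatrix]) -> np.ndarray:
        if isinstance(data, list):
            data = assemble_matrix(data)
        if data.geometry != self.geometry:
            raise GeometryError("data geometry does not match the fitted model")
        return self.predict_values(data.values)


def dose_mean_response(matrix: DataMatrix, mtt_table: pd.DataFrame) -> np.ndarray:
    """Response vector: each sample inherits its dose's mean MTT viability."""
    means = mtt_table.groupby("dose_min")["viability_pct"].mean()
    doses = matrix.meta["dose_min"]
    missing = sorted(set(doses) - set(means.index))
    if missing:
        raise ValueError(f"no MTT reference values for dose(s) {missing}")
    return means.loc[doses].to_numpy()


def per_replicate_response(matrix: DataMatrix, mtt_table: pd.DataFrame) -> np.ndarray:
    """Optional response: pair EEM replicate r with MTT replicate r mod n.

    A heuristic pairing (the wells are physically distinct); provided for
    sensitivity analysis only.
    """
    out = np.empty(matrix.n_samples)
    for i, (dose, rep) in enumerate(
        zip(matrix.meta["dose_min"], matrix.meta["replicate"])
    ):
        vals = mtt_table.loc[mtt_table["dose_min"] == dose, "viability_pct"].to_numpy()
        if len(vals) == 0:
            raise ValueError(f"no MTT reference values for dose {dose}")
        out[i] = vals[int(rep) % len(vals)]
    return out


def fit_upls(
    train: DataMatrix,
    y_train: np.ndarray,
    *,
    split: SplitSpec | None = None,
    max_lv: int | None = None,
    n_splits: int = 10,
    response_mode: str = "dose_mean",
) -> UPLSModel:
    """Autoscale, choose the LV count by venetian-blinds RMSECV, fit PLS."""
    y_train = np.asarray(y_train, dtype=float).ravel()
    if max_lv is None:
        max_lv = max(1, min(15, train.n_samples - n_splits))
    cv = cross_validate(train.values, y_train, max_lv=max_lv, n_splits=n_splits)
    scaling = autoscale_fit(train.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        Xs = autoscale_apply(train.values, scaling)
    y_mean = float(y_train.mean())
    n_lv = max(cv.n_lv, 1)  # a 0-LV optimum still yields a mean-only coef of ~0
    core = fit_pls(Xs, y_train - y_mean, n_lv)
    if cv.n_lv == 0:
        core = PLSCore(
            weights=core.weights[:, :0],
            x_loadings=core.x_loadings[:, :0],
            y_loadings=core.y_loadings[:0],
            scores=core.scores[:, :0],
            coef=np.zeros(train.n_variables),
            n_lv=0,
        )
    return UPLSModel(
        scaling=scaling,
        y_mean=y_mean,
        core=core,
        cv=cv,
        geometry=train.geometry,
        split=split or SplitSpec(),
        response_mode=response_mode,
    )


@dataclass
class FitDiagnostics:
    """Identity-line diagnostics of predicted vs reference viability.

    OLS of predicted on reference: ideal calibration has slope 1,
    intercept 0, R² = 1.  CI half-widths use t(0.975, n−2).
    """

    slope: float
    intercept: float
    r_squared: float
    se_slope: float
    se_intercept: float
    ci_half_slope: float
    ci_half_intercept: float
    n: int


def linear_fit_diagnostics(
    predicted: np.ndarray, reference: np.ndarray
) -> FitDiagnostics:
    """OLS fit of predicted (y) on reference (x) with 95% CIs on a and b."""
    y = np.asarray(predicted, dtype=float).ravel()
    x = np.asarray(reference, dtype=float).ravel()
    if y.shape != x.shape or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("constant reference vector: slope undefined")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n = len(x)
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    sigma2 = ss_res / (n - 2)
    se_slope = float(np.sqrt(sigma2 / sxx))
    se_intercept = float(np.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx)))
    t_crit = float(stats.t.ppf(0.975, n - 2))
    return FitDiagnostics(
        slope=slope,
        intercept=intercept,
        r_squared=r_squared,
        se_slope=se_slope,
        se_intercept=se_intercept,
        ci_half_slope=t_crit * se_slope,
        ci_half_intercept=t_crit * se_intercept,
        n=n,
    )


def aggregate_by_dose(
    predictions: np.ndarray, doses: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Per-dose mean, sample SD (n−1) and count of predictions.

    A dose with a single sample reports SD as NaN with a warning.
    """
    df = pd.DataFrame({"dose_min": np.asarray(doses), "pred": np.asarray(predictions)})
    grouped = df.groupby("dose_min")["pred"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    singles = out.loc[out["n"] == 1, "dose_min"].tolist()
    if singles:
        warnings.warn(
            f"dose(s) {singles} have a single sample; SD undefined", stacklevel=2
        )
    return out
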