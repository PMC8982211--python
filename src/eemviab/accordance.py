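"""Method-accordance statistics for viability assays.

Two viability-testing methods (a reference colorimetric MTT assay and the
EEM-fluorescence soft sensor) are compared at three levels:

* **accuracy** — per UV dose, a two-sided two-sample t-test on the replicate
  means; an unrejected null means any difference between the methods'
  means is attributable to random error;
* **precision** — per dose, a two-sided F-test on the replicate variances;
* **correlation** — ordinary least squares of the soft-sensor dose means on
  the reference dose means; perfect accordance is the identity line
  (slope 1, intercept 0), so 95% confidence intervals on both parameters
  are checked for containment of those ideal values.

Within one method, all dose pairs are additionally compared by t-tests to
map which stress levels the method can discriminate; the partition of
doses into mutually indistinguishable groups is reported descriptively
(connected components of the non-significant-pair graph), since statistical
indistinguishability is not transitive.

Raw per-pair p-values are reported by default; Holm or Bonferroni
adjustment of the discrimination matrices is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import FitDiagnostics, linear_fit_diagnostics


@dataclass
class ViabilitySample:
    """Replicate viabilities for one method at one UV dose."""

    method: str  # MTT | EEM_train | EEM_test | EEM_all | ...
    dose_min: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError("a viability sample needs at least one replicate")
        if np.any(self.values < 0):
            raise ValueError("negative viability replicate")


@dataclass
class ComparisonResult:
    test: str  # "t" | "F"
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    variant: str = ""  # "pooled" | "welch" for t


def mtt_viability(
    treated_absorbances: np.ndarray, control_absorbances: np.ndarray
) -> float:
    """Viability (%) = 100 · mean(treated absorbance) / mean(control absorbance)."""
    treated = np.asarray(treated_absorbances, dtype=float).ravel()
    control = np.asarray(control_absorbances, dtype=float).ravel()
    if treated.size == 0 or control.size == 0:
        raise ValueError("absorbance lists must be non-empty")
    control_mean = control.mean()
    if control_mean <= 0:
        raise ValueError(f"non-positive control mean absorbance: {control_mean}")
    return 100.0 * float(treated.mean()) / float(control_mean)


def _check_two_samples(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("both samples need at least 2 values")
    return x1, x2


def t_test_two_sample(
    x1: np.ndarray, x2: np.ndarray, variant: str = "pooled"
) -> ComparisonResult:
    """Two-sided two-sample t-test on the means.

    ``pooled`` (Student's) uses the pooled variance with n1+n2−2 df;
    ``welch`` uses per-sample variances with Welch–Satterthwaite df.
    """
    x1, x2 = _check_two_samples(x1, x2)
    n1, n2 = len(x1), len(x2)
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 + v2 <= 0:
        raise ValueError("zero total variance: t statistic undefined")
    diff = x1.mean() - x2.mean()
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df: float = n1 + n2 - 2
    elif variant == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t_stat = float(diff / se)
    p = float(2.0 * stats.t.sf(abs(t_stat), df))
    return ComparisonResult(test="t", statistic=t_stat, df=float(df), p_value=p,
                            variant=variant)


def f_test_variance(x1: np.ndarray, x2: np.ndarray) -> ComparisonResult:
    """Two-sided F-test of variance equality: F = s1²/s2², p = 2·min(tails)."""
    x1, x2 = _check_two_samples(x1, x2)
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero variance in a sample: F statistic undefined")
    f_stat = float(v1 / v2)
    d1, d2 = len(x1) - 1, len(x2) - 1
    lower = float(stats.f.cdf(f_stat, d1, d2))
    upper = float(stats.f.sf(f_stat, d1, d2))
    p = min(1.0, 2.0 * min(lower, upper))
    return ComparisonResult(test="F", statistic=f_stat, df=(float(d1), float(d2)),
                            p_value=p)


@dataclass
class AccordanceTable:
    """Per-dose accuracy (t) and precision (F) p-values between two methods."""

    table: pd.DataFrame  # dose_min, t_p, f_p, t_flag, f_flag
    alpha: float
    method_a: str
    method_b: str
    t_variant: str

    @property
    def n_unflagged(self) -> int:
        """Doses at which neither the mean nor the variance test rejects."""
        return int((~(self.table["t_flag"] | self.table["f_flag"])).sum())


def per_timepoint_accordance(
    method_a: list[ViabilitySample],
    method_b: list[ViabilitySample],
    alpha: float = 0.05,
    t_variant: str = "pooled",
) -> AccordanceTable:
    """t/F accordance tests for every dose shared by the two methods.

    Both methods must cover exactly the same dose set.
    """
    a_by_dose = {s.dose_min: s for s in method_a}
    b_by_dose = {s.dose_min: s for s in method_b}
    unmatched = sorted(set(a_by_dose) ^ set(b_by_dose))
    if unmatched:
        raise ValueError(f"dose sets differ between methods: unmatched {unmatched}")
    rows = []
    for dose in sorted(a_by_dose):
        t_res = t_test_two_sample(a_by_dose[dose].values, b_by_dose[dose].values,
                                  variant=t_variant)
        f_res = f_test_variance(a_by_dose[dose].values, b_by_dose[dose].values)
        rows.append(
            {
                "dose_min": dose,
                "t_p": t_res.p_value,
                "f_p": f_res.p_value,
                "t_flag": t_res.p_value <= alpha,
                "f_flag": f_res.p_value <= alpha,
            }
        )
    return AccordanceTable(
        table=pd.DataFrame(rows),
        alpha=alpha,
        method_a=method_a[0].method if method_a else "",
        method_b=method_b[0].method if method_b else "",
        t_variant=t_variant,
    )


@dataclass
class DiscriminationMatrix:
    """Within-method dose × dose t-test p-values with significance flags."""

    method: str
    doses: np.ndarray
    p_values: np.ndarray  # symmetric, NaN diagonal
    flags: np.ndarray  # p <= alpha, False on the diagonal
    alpha: float

    def indistinguishable_groups(self) -> list[list[float]]:
        """Connected components of the non-significant-pair graph.

        A descriptive heuristic: indistinguishability is not transitive, so
        these are not equivalence classes in the statistical sense.
        """
        k = len(self.doses)
        unvisited = set(range(k))
        groups: list[list[float]] = []
        while unvisited:
            stack = [min(unvisited)]
            comp: list[int] = []
            while stack:
                i = stack.pop()
                if i not in unvisited:
                    continue
                unvisited.discard(i)
                comp.append(i)
                stack.extend(
                    j for j in unvisited if not self.flags[i, j]
                )
            groups.append([float(self.doses[i]) for i in sorted(comp)])
        return groups


def pairwise_discrimination(
    samples: list[ViabilitySample],
    alpha: float = 0.05,
    t_variant: str = "pooled",
    adjust: str | None = None,
) -> DiscriminationMatrix:
    """t-tests between every dose pair within one method.

    ``adjust`` ∈ {None, "bonferroni", "holm"} corrects the p-value matrix
    for the number of pairs; the default reports raw per-pair p-values.
    """
    if len(samples) < 2:
        raise ValueError("pairwise discrimination needs at least 2 doses")
    samples = sorted(samples, key=lambda s: s.dose_min)
    doses = np.array([s.dose_min for s in samples])
    k = len(samples)
    p = np.full((k, k), np.nan)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = np.array(
        [
            t_test_two_sample(samples[i].values, samples[j].values, t_variant).p_value
            for i, j in pairs
        ]
    )
    if adjust == "bonferroni":
        adj = np.minimum(1.0, raw * len(raw))
    elif adjust == "holm":
        order = np.argsort(raw)
        adj = np.empty_like(raw)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, raw[idx] * (len(raw) - rank))
            adj[idx] = min(1.0, running)
    elif adjust is None:
        adj = raw
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (i, j), val in zip(pairs, adj):
        p[i, j] = p[j, i] = val
    flags = np.zeros((k, k), dtype=bool)
    off = ~np.eye(k, dtype=bool)
    flags[off] = p[off] <= alpha
    return DiscriminationMatrix(
        method=samples[0].method, doses=doses, p_values=p, flags=flags, alpha=alpha
    )


@dataclass
class CorrelationFit:
    """Identity-line regression of soft-sensor dose means on reference means."""

    slope: float
    slope_ci_half: float
    intercept: float
    intercept_ci_half: float
    r_squared: float
    n: int
    contains_ideal_slope: bool  # CI of the slope contains 1
    contains_ideal_intercept: bool  # CI of the intercept contains 0

    @property
    def diagnostics(self) -> dict[str, float]:
        return {
            "slope": self.slope,
            "slope_ci_half": self.slope_ci_half,
            "intercept": self.intercept,
            "intercept_ci_half": self.intercept_ci_half,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def correlate_methods(
    reference_means: np.ndarray, sensor_means: np.ndarray, alpha: float = 0.05
) -> CorrelationFit:
    """OLS of sensor dose means on reference dose means with 95% CIs.

    Containment flags record whether the CI of the slope covers the ideal
    1 and the CI of the intercept covers the ideal 0.
    """
    if alpha != 0.05:
        # CI level follows alpha; diagnostics helper is hard-wired at 95%
        fit = _linear_fit_ci(reference_means, sensor_means, alpha)
    else:
        fit = linear_fit_diagnostics(np.asarray(sensor_means), np.asarray(reference_means))
    return CorrelationFit(
        slope=fit.slope,
        slope_ci_half=fit.ci_half_slope,
        intercept=fit.intercept,
        intercept_ci_half=fit.ci_half_intercept,
        r_squared=fit.r_squared,
        n=fit.n,
        contains_ideal_slope=abs(fit.slope - 1.0) <= fit.ci_half_slope,
        contains_ideal_intercept=abs(fit.intercept) <= fit.ci_half_intercept,
    )


def _linear_fit_ci(x: np.ndarray, y: np.ndarray, alpha: float) -> FitDiagnostics:
    fit = linear_fit_diagnostics(np.asarray(y), np.asarray(x))
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, fit.n - 2))
    return FitDiagnostics(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        se_slope=fit.se_slope,
        se_intercept=fit.se_intercept,
        ci_half_slope=t_crit * fit.se_slope,
        ci_half_intercept=t_crit * fit.se_intercept,
        n=fit.n,
    )
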