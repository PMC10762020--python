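"""Accuracy metrics and statistics for estimated-vs-reference RR.

Provides cycle-to-cycle alignment of an estimate series onto a
reference, absolute/relative error summaries, an ordinary-least-squares
linear fit (R^2, RMSE), a paired two-one-sided-tests (TOST) equivalence
procedure, and pairwise Wilcoxon rank-sum comparisons between groups of
estimates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from scipy import stats

from .containers import RRSeries
from .errors import InputError

log = logging.getLogger(__name__)

__all__ = [
    "AlignedRR",
    "EvalReport",
    "TostResult",
    "align",
    "error_metrics",
    "tost_equivalence",
    "ranksum_compare",
]


@dataclass
class AlignedRR:
    """Estimate/reference RR pairs on a common time grid."""

    times: np.ndarray
    estimated: np.ndarray
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.estimated = np.asarray(self.estimated, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)
        if not (self.times.shape == self.estimated.shape == self.reference.shape):
            raise InputError("times, estimated and reference must have equal length")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class TostResult:
    """Paired TOST outcome: equivalence iff the CI sits inside (-delta, +delta)."""

    bias: float
    ci_low: float
    ci_high: float
    p_lower: float
    p_upper: float
    delta: float
    confidence: float
    equivalent: bool


@dataclass
class EvalReport:
    """Error summary of an aligned estimate/reference comparison."""

    n: int
    abs_err_mean: float
    abs_err_median: float
    abs_err_sd: float
    rel_err_mean: float
    rel_err_median: float
    rel_err_sd: float
    rmse: float
    r2_fit: float
    r2_identity: float
    slope: float
    intercept: float

    def as_dict(self) -> dict:
        return asdict(self)

    def __str__(self) -> str:  # human-readable report
        return (
            f"n pairs            : {self.n}\n"
            f"abs error (bpm)    : mean {self.abs_err_mean:.3f}, "
            f"median {self.abs_err_median:.3f}, sd {self.abs_err_sd:.3f}\n"
            f"rel error (%)      : mean {self.rel_err_mean:.3f}, "
            f"median {self.rel_err_median:.3f}, sd {self.rel_err_sd:.3f}\n"
            f"RMSE (bpm)         : {self.rmse:.3f}\n"
            f"linear fit         : R^2 {self.r2_fit:.4f} "
            f"(slope {self.slope:.3f}, intercept {self.intercept:.3f})\n"
            f"identity-line R^2  : {self.r2_identity:.4f}"
        )


def align(
    est: RRSeries | tuple[np.ndarray, np.ndarray],
    ref_times: np.ndarray,
    ref_values: np.ndarray,
) -> AlignedRR:
    """Interpolate a reference RR series onto the estimate timestamps.

    Estimates outside the reference time support are dropped (count
    logged); no overlap at all is an error.
    """
    if isinstance(est, RRSeries):
        t_est, v_est = est.times, est.rr_smoothed
    else:
        t_est, v_est = (np.asarray(a, dtype=float) for a in est)
    ref_times = np.asarray(ref_times, dtype=float)
    ref_values = np.asarray(ref_values, dtype=float)
    if ref_times.size < 1:
        raise InputError("empty reference series")
    inside = (t_est >= ref_times[0]) & (t_est <= ref_times[-1])
    n_drop = int((~inside).sum())
    if n_drop:
        log.info("dropped %d estimate(s) outside the reference time support", n_drop)
    if not np.any(inside):
        raise InputError("estimate and reference time supports do not overlap")
    t = t_est[inside]
    return AlignedRR(
        times=t,
        estimated=v_est[inside],
        reference=np.interp(t, ref_times, ref_values),
    )


def error_metrics(a: AlignedRR) -> EvalReport:
    """Absolute/relative errors, RMSE, and linear-fit R^2 of est on ref.

    Pairs with a zero reference are excluded from the relative error
    (and logged). The headline R^2 comes from an OLS fit with
    intercept; the identity-line R^2 (1 - SS_res(identity)/SS_tot) is
    reported alongside.
    """
    if len(a) < 2:
        raise InputError("need at least 2 aligned pairs")
    diff = a.estimated - a.reference
    abs_err = np.abs(diff)
    nz = a.reference != 0
    if not np.all(nz):
        log.info("excluded %d pair(s) with zero reference from relative error", int((~nz).sum()))
    if not np.any(nz):
        raise InputError("relative error undefined: all reference values are zero")
    rel_err = 100.0 * abs_err[nz] / a.reference[nz]
    fit = stats.linregress(a.reference, a.estimated)
    ss_tot = float(np.sum((a.estimated - a.estimated.mean()) ** 2))
    r2_ident = 1.0 - float(np.sum(diff**2)) / ss_tot if ss_tot > 0 else 1.0
    return EvalReport(
        n=len(a),
        abs_err_mean=float(abs_err.mean()),
        abs_err_median=float(np.median(abs_err)),
        abs_err_sd=float(abs_err.std(ddof=1)),
        rel_err_mean=float(rel_err.mean()),
        rel_err_median=float(np.median(rel_err)),
        rel_err_sd=float(rel_err.std(ddof=1)) if rel_err.size > 1 else 0.0,
        rmse=float(np.sqrt(np.mean(diff**2))),
        r2_fit=float(fit.rvalue**2),
        r2_identity=r2_ident,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def tost_equivalence(a: AlignedRR, delta: float = 2.0, conf: float = 0.90) -> TostResult:
    """Paired two-one-sided-tests equivalence at +/- ``delta`` bpm.

    The estimate and reference are declared equivalent when the
    ``conf``-level confidence interval of the mean paired difference
    lies entirely inside (-delta, +delta) — equivalently, both
    one-sided tests reject at level (1 - conf) / 2.
    """
    if len(a) < 3:
        raise InputError("TOST needs at least 3 pairs")
    if delta <= 0:
        raise InputError("delta must be > 0")
    d = a.estimated - a.reference
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # analytic limit: the CI collapses to the point estimate
        eq = abs(bias) < delta
        p = 0.0 if eq else 1.0
        return TostResult(bias, bias, bias, p, p, delta, conf, eq)
    se = sd / np.sqrt(n)
    tcrit = stats.t.ppf(0.5 + conf / 2, df=n - 1)
    lo, hi = bias - tcrit * se, bias + tcrit * se
    p_lower = float(stats.t.sf((bias + delta) / se, df=n - 1))  # H0: mean <= -delta
    p_upper = float(stats.t.cdf((bias - delta) / se, df=n - 1))  # H0: mean >= +delta
    return TostResult(
        bias=bias,
        ci_low=float(lo),
        ci_high=float(hi),
        p_lower=p_lower,
        p_upper=p_upper,
        delta=delta,
        confidence=conf,
        equivalent=bool(-delta < lo and hi < delta),
    )


def ranksum_compare(groups: Sequence[np.ndarray], exact_max_n: int = 10) -> dict[tuple[int, int], float]:
    """Two-sided Wilcoxon rank-sum p-value for every pair of groups.

    Uses the exact null distribution when both groups have at most
    ``exact_max_n`` values and no ties span the pair, and the normal
    approximation with tie correction otherwise. A pair whose values
    are all identical returns p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise InputError(f"group {i} needs at least 2 values")
    out: dict[tuple[int, int], float] = {}
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            x, y = arrs[i], arrs[j]
            pooled = np.concatenate([x, y])
            if np.all(pooled == pooled[0]):
                out[(i, j)] = 1.0
                continue
            has_ties = np.unique(pooled).size < pooled.size
            small = max(x.size, y.size) <= exact_max_n
            method = "exact" if (small and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            out[(i, j)] = float(min(res.pvalue, 1.0))
    return out
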