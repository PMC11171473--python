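"""Regression fits and group/stage comparisons of the viscoelastic points.

Per (group, treatment stage) cell the natural frequency is fit as a linear
function of the equivalent blood pressure and the dynamic modulus as a
two-parameter exponential E'(p) = a exp(b p).  Cells are then contrasted —
between groups at matched stage and within group against that group's
control — with:

* the classic two-line ANCOVA sequence for f0: an F test for equal slopes
  (separate-lines vs common-slope model); only if the slopes do not differ
  significantly, an F test for equal elevations under the common slope;
* an extra-sum-of-squares F test for E': one shared (a, b) pair vs
  separate pairs, F with (2, n_A + n_B - 4) degrees of freedom.

Significance is per comparison at alpha = 0.05 with no multiplicity
correction by default (a Holm option exists).  Points are pooled across
subjects within a cell; per-subject random effects are out of scope.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .protocol import STAGE_LABELS

__all__ = [
    "LinearFitResult",
    "ExpFitResult",
    "ComparisonResult",
    "fit_linear",
    "fit_exponential",
    "compare_lines",
    "compare_curves",
    "default_contrast_plan",
    "run_comparisons",
]

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
_EPS_SS = 1e-12  # residual SS below this is treated as an exact fit


@dataclasses.dataclass(frozen=True)
class LinearFitResult:
    """OLS fit of y = intercept + slope * p."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    n: int
    rss: float
    df: int


@dataclasses.dataclass(frozen=True)
class ExpFitResult:
    """Least-squares fit of y = a * exp(b * p)."""

    a: float
    a_se: float
    b: float
    b_se: float
    n: int
    rss: float
    df: int
    converged: bool


@dataclasses.dataclass(frozen=True)
class ComparisonResult:
    contrast_id: str
    test: str  # "slopes" | "elevations" | "curves"
    F: float
    df1: int
    df2: int
    p_value: float
    significant: bool
    note: str = ""


def _as_xy(points) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(points, dtype=float)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return arr[:, 0], arr[:, 1]
    raise ValueError("points must be an (n, 2) array of (p, y) pairs")


def fit_linear(points) -> LinearFitResult:
    """Ordinary least squares with closed-form standard errors.

    ``points`` is an (n, 2) array of (pressure, f0) pairs; n >= 3 with at
    least two distinct pressures is required.
    """
    p, y = _as_xy(points)
    n = p.size
    if n < 3:
        raise ValueError(f"linear fit needs n >= 3 points, got {n}")
    if np.unique(p).size < 2:
        raise ValueError("linear fit is rank deficient: all pressures equal")
    res = sm.OLS(y, sm.add_constant(p)).fit()
    return LinearFitResult(
        slope=float(res.params[1]), slope_se=float(res.bse[1]),
        intercept=float(res.params[0]), intercept_se=float(res.bse[0]),
        n=n, rss=float(res.ssr), df=int(res.df_resid))


def fit_exponential(points, *, maxfev: int = 10000) -> ExpFitResult:
    """Least-squares fit of a*exp(b*p), initialised from the log-linear fit.

    All y must be > 0 (the modulus is positive by construction).  A fit
    that fails to converge is returned flagged, not raised; flagged fits
    are excluded from curve comparisons.
    """
    p, y = _as_xy(points)
    n = p.size
    if n < 3:
        raise ValueError(f"exponential fit needs n >= 3 points, got {n}")
    if np.any(y <= 0):
        raise ValueError("exponential fit requires y > 0")
    b0, loga0 = np.polyfit(p, np.log(y), 1)
    p0 = (math.exp(loga0), b0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                lambda x, a, b: a * np.exp(b * x), p, y, p0=p0, maxfev=maxfev)
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        return ExpFitResult(a=math.nan, a_se=math.nan, b=math.nan,
                            b_se=math.nan, n=n, rss=math.nan, df=n - 2,
                            converged=False)
    resid = y - popt[0] * np.exp(popt[1] * p)
    ses = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (math.nan,) * 2
    return ExpFitResult(a=float(popt[0]), a_se=float(ses[0]),
                        b=float(popt[1]), b_se=float(ses[1]),
                        n=n, rss=float(resid @ resid), df=n - 2,
                        converged=bool(converged))


def _f_test(rss_reduced: float, rss_full: float, df_extra: int,
            df_full: int) -> tuple[float, float]:
    """Extra-sum-of-squares F statistic and p-value for nested models."""
    if df_full <= 0:
        raise ValueError("no residual degrees of freedom in the full model")
    num = max(rss_reduced - rss_full, 0.0) / df_extra
    if rss_full < _EPS_SS:
        # exact fit: any excess RSS in the reduced model is decisive
        return (0.0, 1.0) if num < _EPS_SS else (math.inf, 0.0)
    F = num / (rss_full / df_full)
    return F, float(stats.f.sf(F, df_extra, df_full))


def compare_lines(points_a, points_b, *, alpha: float = ALPHA_DEFAULT,
                  contrast_id: str = "A_vs_B") -> list[ComparisonResult]:
    """Two-line ANCOVA: equal-slopes F test, then (if slopes do not differ
    significantly) equal-elevations F test under the common slope.

    Returns one result for the slope test and, when applicable, one for the
    elevation test.
    """
    pa, ya = _as_xy(points_a)
    pb, yb = _as_xy(points_b)
    fit_a = fit_linear(points_a)
    fit_b = fit_linear(points_b)
    n = fit_a.n + fit_b.n

    # common-slope model: per-dataset intercepts, shared slope
    p = np.concatenate([pa, pb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(pa.size), np.ones(pb.size)])
    X_common = np.column_stack([np.ones(n), g, p])
    rss_common = _lstsq_rss(X_common, y)
    rss_full = fit_a.rss + fit_b.rss
    F_s, p_s = _f_test(rss_common, rss_full, 1, n - 4)
    out = [ComparisonResult(contrast_id, "slopes", F_s, 1, n - 4, p_s,
                            p_s < alpha)]
    if p_s >= alpha:
        X_single = np.column_stack([np.ones(n), p])
        rss_single = _lstsq_rss(X_single, y)
        F_e, p_e = _f_test(rss_single, rss_common, 1, n - 3)
        out.append(ComparisonResult(contrast_id, "elevations", F_e, 1, n - 3,
                                    p_e, p_e < alpha))
    return out


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design in comparison model")
    resid = y - X @ coef
    return float(resid @ resid)


def compare_curves(points_a, points_b, *, alpha: float = ALPHA_DEFAULT,
                   contrast_id: str = "A_vs_B") -> ComparisonResult:
    """Extra-sum-of-squares F test for the exponential regression curves:
    one shared (a, b) pair vs separate pairs, df = (2, n_A + n_B - 4)."""
    fit_a = fit_exponential(points_a)
    fit_b = fit_exponential(points_b)
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("curve comparison requires both exponential fits "
                         "to have converged")
    pa, ya = _as_xy(points_a)
    pb, yb = _as_xy(points_b)
    pooled = np.column_stack([np.concatenate([pa, pb]),
                              np.concatenate([ya, yb])])
    fit_shared = fit_exponential(pooled)
    if not fit_shared.converged:
        raise ValueError("shared exponential fit did not converge")
    rss_sep = fit_a.rss + fit_b.rss
    n = fit_a.n + fit_b.n
    F, p = _f_test(fit_shared.rss, rss_sep, 2, n - 4)
    return ComparisonResult(contrast_id, "curves", F, 2, n - 4, p, p < alpha)


# ---------------------------------------------------------------------------
# Report over a study's points table


def default_contrast_plan(stages: Sequence[str] = STAGE_LABELS,
                          groups: Sequence[str] = ("sham", "pin"),
                          measures: Sequence[str] = ("f0", "Eprime"),
                          ) -> list[dict]:
    """The study's standard contrasts: between groups at every stage, and
    within each group every non-control stage against that group's control.
    """
    plan: list[dict] = []
    for measure in measures:
        if len(groups) >= 2:
            for stage in stages:
                plan.append({
                    "id": f"{measure}:{groups[0]}-vs-{groups[1]}@{stage}",
                    "measure": measure,
                    "cell_a": {"group": groups[0], "stage": stage},
                    "cell_b": {"group": groups[1], "stage": stage}})
        for group in groups:
            for stage in stages:
                if stage == "control":
                    continue
                plan.append({
                    "id": f"{measure}:{group}:{stage}-vs-control",
                    "measure": measure,
                    "cell_a": {"group": group, "stage": stage},
                    "cell_b": {"group": group, "stage": "control"}})
    return plan


def _cell_points(points: pd.DataFrame, group: str, stage: str,
                 measure: str) -> np.ndarray | None:
    ycol = "f0_Hz" if measure == "f0" else "Eprime_Pa"
    sel = points[(points["group"] == group) & (points["stage"] == stage)]
    if "qc_flags" in sel.columns:
        sel = sel[sel["qc_flags"].fillna("") == ""]
    sel = sel[np.isfinite(sel[ycol])]
    if len(sel) < 3 or sel["p_mmHg"].nunique() < 2:
        return None
    return np.column_stack([sel["p_mmHg"].to_numpy(),
                            sel[ycol].to_numpy(dtype=float)])


def _holm(pvals: list[float], alpha: float) -> list[bool]:
    order = np.argsort(pvals)
    m = len(pvals)
    out = [False] * m
    for rank, idx in enumerate(order):
        if pvals[idx] <= alpha / (m - rank):
            out[idx] = True
        else:
            break
    return out


def run_comparisons(points: pd.DataFrame, plan: Sequence[dict] | None = None,
                    *, alpha: float = ALPHA_DEFAULT, holm: bool = False,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every cell in the plan and run the planned comparisons.

    Returns ``(report, fits)``: one report row per comparison actually run
    (plus skipped rows with a reason), and one fits row per unique cell and
    measure.  QC-flagged points are excluded before fitting; cells with
    fewer than 3 usable points (or a single pressure level) cause their
    contrasts to be skipped with a reason, not an error.
    """
    if plan is None:
        stages = [s for s in STAGE_LABELS if s in set(points["stage"])]
        groups = [g for g in ("sham", "pin") if g in set(points["group"])]
        plan = default_contrast_plan(stages, groups)

    fit_rows = []
    fitted: dict[tuple, object] = {}

    def get_cell(group: str, stage: str, measure: str):
        key = (group, stage, measure)
        if key not in fitted:
            xy = _cell_points(points, group, stage, measure)
            fitted[key] = xy
            if xy is not None:
                if measure == "f0":
                    fit = fit_linear(xy)
                    fit_rows.append({"group": group, "stage": stage,
                                     "measure": measure, "n": fit.n,
                                     "param1": fit.intercept,
                                     "param1_se": fit.intercept_se,
                                     "param2": fit.slope,
                                     "param2_se": fit.slope_se,
                                     "rss": fit.rss, "converged": True})
                else:
                    fit = fit_exponential(xy)
                    fit_rows.append({"group": group, "stage": stage,
                                     "measure": measure, "n": fit.n,
                                     "param1": fit.a, "param1_se": fit.a_se,
                                     "param2": fit.b, "param2_se": fit.b_se,
                                     "rss": fit.rss,
                                     "converged": fit.converged})
        return fitted[key]

    report_rows = []
    for contrast in plan:
        cid, measure = contrast["id"], contrast["measure"]
        a, b = contrast["cell_a"], contrast["cell_b"]
        xy_a = get_cell(a["group"], a["stage"], measure)
        xy_b = get_cell(b["group"], b["stage"], measure)
        if xy_a is None or xy_b is None:
            empty = [f"{c['group']}/{c['stage']}" for c, xy in
                     ((a, xy_a), (b, xy_b)) if xy is None]
            report_rows.append({"contrast": cid, "measure": measure,
                                "test": "skipped", "F": math.nan,
                                "df1": 0, "df2": 0, "p_value": math.nan,
                                "significant": False,
                                "note": "empty or unusable cell(s): "
                                        + ", ".join(empty)})
            logger.warning("contrast %s skipped: unusable cells %s", cid, empty)
            continue
        try:
            if measure == "f0":
                results = compare_lines(xy_a, xy_b, alpha=alpha,
                                        contrast_id=cid)
            else:
                results = [compare_curves(xy_a, xy_b, alpha=alpha,
                                          contrast_id=cid)]
        except ValueError as exc:
            report_rows.append({"contrast": cid, "measure": measure,
                                "test": "skipped", "F": math.nan,
                                "df1": 0, "df2": 0, "p_value": math.nan,
                                "significant": False, "note": str(exc)})
            continue
        for r in results:
            report_rows.append({"contrast": cid, "measure": measure,
                                "test": r.test, "F": r.F, "df1": r.df1,
                                "df2": r.df2, "p_value": r.p_value,
                                "significant": r.significant, "note": r.note})

    report = pd.DataFrame(report_rows)
    if holm and not report.empty:
        run = report["test"].isin(["slopes", "curves"])
        adj = _holm(report.loc[run, "p_value"].tolist(), alpha)
        report.loc[run, "significant"] = adj
    fits = pd.DataFrame(fit_rows)
    return report, fits
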