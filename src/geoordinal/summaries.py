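"""Reporting surface: odds ratios, fit criteria, smooth curves with dual
bands, spatial significance classification and descriptive tables.

Presentation rounding (2 decimals for odds ratios, 3 for coefficients,
1 for criteria) happens only in the table writers; every computational
function returns full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import bspline_basis
from .exceptions import DataError, DomainError

__all__ = [
    "ComparisonRow",
    "SmoothCurve",
    "SpatialEffectSummary",
    "classify_regions",
    "comparison_table",
    "descriptive_table",
    "information_criteria",
    "odds_ratio",
    "smooth_curve",
    "write_coefficient_table",
    "write_curve",
    "write_regions",
]

_Z80 = norm.ppf(0.90)
_Z95 = norm.ppf(0.975)


# ---------------------------------------------------------------------------
# scalar transforms
# ---------------------------------------------------------------------------


def odds_ratio(coefficient: float, ci=None):
    """Exponentiate a coefficient (and optionally its interval bounds).

    Returns ``OR`` or ``(OR, (lo, hi))``.  Strictly monotone; maps 0 to 1
    exactly.  Rounding is left to presentation.
    """
    if ci is None:
        return float(np.exp(coefficient))
    lo, hi = ci
    if not (np.isfinite(coefficient) and np.isfinite(lo) and np.isfinite(hi)):
        raise DomainError("odds_ratio needs finite inputs")
    if lo > hi:
        raise DomainError("interval bounds out of order")
    return float(np.exp(coefficient)), (float(np.exp(lo)), float(np.exp(hi)))


def information_criteria(minus2ll: float, df: float, n: int):
    """``(AIC, BIC, GCV)`` from a deviance, effective df and sample size.

    AIC = -2LL + 2 df;  BIC = -2LL + df ln(n);
    GCV = (-2LL / n) / (1 - df / n)^2  (deviance-based).
    """
    if df <= 0 or df >= n:
        raise DomainError("need 0 < df < n")
    aic = minus2ll + 2.0 * df
    bic = minus2ll + df * np.log(n)
    gcv = (minus2ll / n) / (1.0 - df / n) ** 2
    return float(aic), float(bic), float(gcv)


# ---------------------------------------------------------------------------
# model-comparison rows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    minus2ll: float
    df: float
    aic: float
    bic: float
    gcv: float
    converged: bool = True

    def __post_init__(self):
        if abs(self.aic - self.minus2ll - 2.0 * self.df) > 1e-6 * max(
                1.0, abs(self.aic)):
            raise DomainError("AIC identity violated: AIC != -2LL + 2 df")


def comparison_table(fits: dict) -> pd.DataFrame:
    """Table-5-style layout: one row per model label."""
    rows = []
    for label, fit in fits.items():
        row = ComparisonRow(label, fit.minus2ll, fit.edf, fit.aic, fit.bic,
                            fit.gcv, fit.converged)
        rows.append(row)
    return pd.DataFrame(
        [{"model": r.label, "minus2LL": r.minus2ll, "df": r.df, "AIC": r.aic,
          "BIC": r.bic, "GCV": r.gcv, "converged": r.converged}
         for r in rows]
    )


# ---------------------------------------------------------------------------
# smooth curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothCurve:
    """Point estimate with 80% and 95% Wald bands on a covariate grid."""

    grid: np.ndarray
    estimate: np.ndarray
    lo80: np.ndarray
    hi80: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray

    def __post_init__(self):
        if not (np.all(self.lo95 <= self.lo80)
                and np.all(self.lo80 <= self.estimate)
                and np.all(self.estimate <= self.hi80)
                and np.all(self.hi80 <= self.hi95)):
            raise DomainError("band nesting violated")


def smooth_curve(fit, term_name: str, grid_size: int = 100) -> SmoothCurve:
    """Evaluate a fitted P-spline term on a grid spanning the observed range.

    Bands are pointwise empirical-Bayes Wald intervals from the term's
    covariance block.
    """
    term = _get_term(fit, term_name, kinds=("pspline",))
    meta = term.meta
    lo, hi = meta["x_range"]
    grid = np.linspace(lo, hi, grid_size)
    B = bspline_basis(grid, meta["term"], lo=meta["lo"], hi=meta["hi"])
    est = B @ term.coef
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, term.cov, B), 0.0))
    return SmoothCurve(
        grid=grid, estimate=est,
        lo80=est - _Z80 * se, hi80=est + _Z80 * se,
        lo95=est - _Z95 * se, hi95=est + _Z95 * se,
    )


def _get_term(fit, name, kinds):
    available = [n for n, t in fit.terms.items() if t.kind in kinds]
    if name not in fit.terms or fit.terms[name].kind not in kinds:
        raise DataError(f"no term {name!r}; available: {available}")
    return fit.terms[name]


# ---------------------------------------------------------------------------
# spatial classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialEffectSummary:
    """Per-region estimate, 95% interval and three-way significance class.

    ``positive`` iff the lower bound exceeds 0, ``negative`` iff the upper
    bound is below 0, else ``nonsignificant`` (the white/black/grey map
    classes of disease-mapping practice).
    """

    region: str
    estimate: float
    lower95: float
    upper95: float

    @property
    def significance(self) -> str:
        if self.lower95 > 0:
            return "positive"
        if self.upper95 < 0:
            return "negative"
        return "nonsignificant"


def classify_regions(fit, term_name: str = "spatial_str"):
    """Three-way classification of a spatial term's region effects.

    ``term_name='spatial_total'`` combines the structured and unstructured
    terms (sum, with their joint covariance).
    """
    if term_name == "spatial_total":
        est, cov, graph = _combined_spatial(fit)
    else:
        term = _get_term(fit, term_name, kinds=("mrf", "iid"))
        est, cov, graph = term.coef, term.cov, term.meta["graph"]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return [
        SpatialEffectSummary(
            region=graph.labels[r], estimate=float(est[r]),
            lower95=float(est[r] - _Z95 * se[r]),
            upper95=float(est[r] + _Z95 * se[r]),
        )
        for r in range(graph.n_regions)
    ]


def _combined_spatial(fit):
    spatial = [t for t in fit.terms.values() if t.kind in ("mrf", "iid")]
    if not spatial:
        raise DataError("fit has no spatial terms")
    graph = spatial[0].meta["graph"]
    idx = np.concatenate([t.idx for t in spatial])
    M = np.concatenate([t.transform for t in spatial], axis=1)
    psi = np.concatenate([fit.thresholds if fit.thresholds is not None
                          else np.zeros(0), fit.beta])
    est = M @ psi[idx]
    cov = M @ fit.cov[np.ix_(idx, idx)] @ M.T
    return est, cov, graph


# ---------------------------------------------------------------------------
# descriptive frequencies
# ---------------------------------------------------------------------------


def descriptive_table(data, denominator: int = None) -> pd.DataFrame:
    """Per-category counts and percentages.

    ``data`` is either an ``OrdinalDataset`` (counts taken from ``y``) or a
    sequence of category counts.  ``denominator`` defaults to the sum of
    the counts (the classified records); pass the full record count to use
    all records as the base instead.
    """
    if hasattr(data, "y"):
        y = np.asarray(data.y)
        cats = np.arange(y.min(), y.max() + 1)
        counts = np.array([(y == c).sum() for c in cats])
    else:
        counts = np.asarray(data, dtype=int)
        cats = np.arange(1, counts.size + 1)
    denom = int(denominator) if denominator is not None else int(counts.sum())
    return pd.DataFrame({
        "category": cats,
        "count": counts,
        "percent": 100.0 * counts / denom,
    })


# ---------------------------------------------------------------------------
# delimited-text exports (fixed column orders, deterministic formatting)
# ---------------------------------------------------------------------------

_FMT = "%.10g"


def write_coefficient_table(fit, path, level: float = 0.95) -> None:
    """term, level, estimate, lower95, upper95, OR, OR_lower, OR_upper."""
    rows = []
    for term, lev, est, lo, hi in fit.fixed_table(level):
        orr, (or_lo, or_hi) = odds_ratio(est, (lo, hi))
        rows.append({
            "term": term, "level": lev,
            "estimate": round(est, 3), "lower95": round(lo, 3),
            "upper95": round(hi, 3), "OR": round(orr, 2),
            "OR_lower": round(or_lo, 2), "OR_upper": round(or_hi, 2),
        })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FMT)


def write_curve(curve: SmoothCurve, path) -> None:
    """grid, estimate, lo80, hi80, lo95, hi95."""
    pd.DataFrame({
        "grid": curve.grid, "estimate": curve.estimate,
        "lo80": curve.lo80, "hi80": curve.hi80,
        "lo95": curve.lo95, "hi95": curve.hi95,
    }).to_csv(path, index=False, float_format=_FMT)


def write_regions(summaries, path) -> None:
    """region, estimate, lower95, upper95, class."""
    pd.DataFrame([{
        "region": s.region, "estimate": s.estimate,
        "lower95": s.lower95, "upper95": s.upper95,
        "class": s.significance,
    } for s in summaries]).to_csv(path, index=False, float_format=_FMT)
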