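"""Design and penalty matrix construction.

Term types supported: P-spline smooths of continuous covariates,
structured (MRF / graph-Laplacian) and unstructured (i.i.d.) region
effects, and effect-coded categorical fixed effects (+1 own level, -1
reference, 0 otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from .exceptions import ConfigurationError, DataError, DomainError, NumericsError
from .synthetic import AdjacencyGraph, OrdinalDataset

__all__ = [
    "DesignBlocks",
    "FixedTerm",
    "ModelSpec",
    "PSplineTerm",
    "PenalizedBlock",
    "SpatialTerm",
    "bspline_basis",
    "build_design",
    "center_constraint",
    "difference_penalty",
    "effect_code",
    "mrf_penalty",
]


# ---------------------------------------------------------------------------
# term declarations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSplineTerm:
    """P-spline smooth of one continuous covariate.

    Defaults are the conventional ones of the structured-additive software
    family: cubic B-splines, 20 inner knots, second-order difference
    penalty.  ``bounds`` default to the observed covariate range; knots are
    equidistant over it, extended by ``degree`` extra knots on each side.
    """

    name: str
    degree: int = 3
    n_inner_knots: int = 20
    penalty_order: int = 2
    bounds: Optional[tuple] = None

    def __post_init__(self):
        if self.degree < 0 or self.n_inner_knots < 0 or self.penalty_order < 1:
            raise ConfigurationError("invalid P-spline settings")
        if self.n_basis <= self.penalty_order:
            raise ConfigurationError(
                "number of basis functions must exceed the penalty order"
            )

    @property
    def n_basis(self):
        return self.n_inner_knots + self.degree + 1

    def knots(self, lo: float, hi: float) -> np.ndarray:
        """Full (extended, equidistant) knot vector over ``[lo, hi]``."""
        if not hi > lo:
            raise DomainError("empty covariate range")
        h = (hi - lo) / (self.n_inner_knots + 1)
        inner = np.linspace(lo, hi, self.n_inner_knots + 2)
        left = lo - h * np.arange(self.degree, 0, -1)
        right = hi + h * np.arange(1, self.degree + 1)
        return np.concatenate([left, inner, right])


@dataclass(frozen=True)
class SpatialTerm:
    """Region effect: ``structured`` (MRF penalty) or ``unstructured`` (iid)."""

    kind: str = "structured"
    name: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("structured", "unstructured"):
            raise ConfigurationError(f"unknown spatial kind {self.kind!r}")
        if self.name is None:
            object.__setattr__(self, "name", f"spatial_{self.kind[:3]}")


@dataclass(frozen=True)
class FixedTerm:
    """Effect-coded categorical covariate (one-vs-reference, +1/-1/0)."""

    name: str
    levels: tuple
    reference: str

    def __post_init__(self):
        if self.reference not in self.levels:
            raise ConfigurationError(
                f"reference {self.reference!r} not among levels {self.levels}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ConfigurationError("duplicate levels")

    @property
    def contrast_levels(self):
        return tuple(lev for lev in self.levels if lev != self.reference)


@dataclass(frozen=True)
class ModelSpec:
    """Declarative term list for one model.

    The response handling (binary intercept vs cumulative thresholds) is
    decided by the fitting routine, not here.
    """

    fixed: tuple = ()
    smooth: tuple = ()
    spatial: tuple = ()
    graph: Optional[AdjacencyGraph] = None

    def __post_init__(self):
        if self.spatial and self.graph is None:
            raise ConfigurationError("spatial terms require a graph")
        names = ([t.name for t in self.fixed] + [t.name for t in self.smooth]
                 + [t.name for t in self.spatial])
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate term names in model spec")


# ---------------------------------------------------------------------------
# basic constructors
# ---------------------------------------------------------------------------


def bspline_basis(x, term: PSplineTerm, *, lo=None, hi=None) -> np.ndarray:
    """Evaluate the B-spline basis of ``term`` at ``x`` (dense ``n x n_basis``).

    Rows form a partition of unity.  Points outside the knot range raise a
    :class:`DataError`; there is no silent extrapolation.
    """
    x = np.asarray(x, dtype=float)
    if lo is None:
        lo = term.bounds[0] if term.bounds else x.min()
    if hi is None:
        hi = term.bounds[1] if term.bounds else x.max()
    knots = term.knots(lo, hi)
    if np.any(x < lo) or np.any(x > hi):
        raise DataError(
            f"{term.name}: values outside the knot range [{lo}, {hi}]"
        )
    B = BSpline.design_matrix(x, knots, term.degree, extrapolate=False).toarray()
    assert B.shape[1] == term.n_basis
    return B


def difference_penalty(n_basis: int, order: int) -> np.ndarray:
    """``D_d' D_d`` for the d-th order difference operator on ``n_basis`` coefs."""
    if order < 1 or order >= n_basis:
        raise DomainError("difference order must satisfy 1 <= d < n_basis")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


def mrf_penalty(graph: AdjacencyGraph) -> np.ndarray:
    """MRF penalty = graph Laplacian ``diag(degree) - adjacency``."""
    return graph.laplacian()


def effect_code(labels, term: FixedTerm) -> np.ndarray:
    """Effect coding: one column per non-reference level.

    Entry is +1 at the column's own level, -1 at the reference level and 0
    elsewhere.  An unseen label raises :class:`DataError` naming it.
    """
    labels = np.asarray(labels, dtype=object)
    declared = set(term.levels)
    bad = sorted({str(v) for v in labels if v not in declared})
    if bad:
        raise DataError(f"{term.name}: unseen level(s) {bad}")
    cols = term.contrast_levels
    X = np.zeros((labels.size, len(cols)))
    is_ref = labels == term.reference
    for k, lev in enumerate(cols):
        X[labels == lev, k] = 1.0
        X[is_ref, k] = -1.0
    return X


def center_constraint(basis: np.ndarray, penalty: np.ndarray):
    """Reparameterize a term so its fitted values sum to zero over the data.

    Returns ``(basis_c, penalty_c, transform)`` where ``transform`` maps
    constrained coefficients back to the original coefficient scale
    (``c = transform @ c_constrained``).  The dimension drops by one and the
    penalty is transformed congruently (PSD is preserved).
    """
    basis = np.asarray(basis, dtype=float)
    if basis.shape[1] < 2:
        raise DomainError("need at least two basis columns to constrain")
    c = basis.sum(axis=0)
    nrm = np.linalg.norm(c)
    if nrm <= 1e-12 * max(1.0, np.abs(basis).max()) * basis.shape[0]:
        raise NumericsError("rank-deficient centering constraint (zero column sums)")
    proj = null_space(c[None, :])  # orthonormal, (q, q-1)
    if proj.shape[1] != basis.shape[1] - 1:
        raise NumericsError("centering constraint did not reduce dimension by one")
    return basis @ proj, proj.T @ penalty @ proj, proj


# ---------------------------------------------------------------------------
# assembled design blocks
# ---------------------------------------------------------------------------


@dataclass
class PenalizedBlock:
    """One penalized term, already centered, with its penalty.

    ``coef_transform`` maps the block's working coefficients back to the
    term's original coefficient scale (spline coefficients or per-region
    effects); ``meta`` carries what reporting needs (knots, graph...).
    """

    name: str
    kind: str  # 'pspline' | 'mrf' | 'iid'
    basis: np.ndarray
    penalty: np.ndarray
    coef_transform: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class DesignBlocks:
    """Global fixed-effect matrix plus one :class:`PenalizedBlock` per term."""

    X: np.ndarray
    x_names: list
    fixed_slices: dict
    blocks: list
    n_obs: int

    def __post_init__(self):
        for b in self.blocks:
            if b.basis.shape[0] != self.n_obs:
                raise NumericsError(f"block {b.name}: row count mismatch")
            ev = np.linalg.eigvalsh((b.penalty + b.penalty.T) / 2.0)
            if ev.min() < -1e-10 * max(1.0, ev.max()):
                raise NumericsError(f"block {b.name}: penalty not PSD")


def _per_component_centering(graph: AdjacencyGraph) -> np.ndarray:
    """Orthonormal basis of the space orthogonal to per-component constants.

    Size-one components (isolated regions) contribute no columns: their
    structured effect is pinned to zero by the component constraint.
    """
    comps = graph.components()
    cols = []
    for comp in comps:
        m = len(comp)
        if m == 1:
            continue
        # Helmert-style orthonormal contrasts within the component
        H = np.zeros((graph.n_regions, m - 1))
        for k in range(1, m):
            v = np.zeros(graph.n_regions)
            v[comp[:k]] = 1.0
            v[comp[k]] = -float(k)
            H[:, k - 1] = v / np.linalg.norm(v)
        cols.append(H)
    if not cols:
        raise ConfigurationError("graph has no component with >= 2 regions")
    return np.concatenate(cols, axis=1)


def build_design(dataset: OrdinalDataset, spec: ModelSpec, *,
                 intercept: bool = False) -> DesignBlocks:
    """Assemble fixed-effect columns and penalized blocks for a model.

    Smooth terms are centered over the observations, spatial terms over the
    regions (per connected component for the MRF), which makes them
    identifiable next to the intercept / thresholds.
    """
    n = dataset.n_obs
    x_parts, x_names = [], []
    fixed_slices = {}
    col = 0
    if intercept:
        x_parts.append(np.ones((n, 1)))
        x_names.append("(intercept)")
        col += 1
    for term in spec.fixed:
        if term.name not in dataset.v_cat:
            raise DataError(f"categorical column {term.name!r} not in dataset")
        Xc = effect_code(dataset.v_cat[term.name], term)
        x_parts.append(Xc)
        fixed_slices[term.name] = (slice(col, col + Xc.shape[1]),
                                   term.contrast_levels)
        x_names.extend(f"{term.name}[{lev}]" for lev in term.contrast_levels)
        col += Xc.shape[1]

    blocks = []
    for term in spec.smooth:
        if term.name not in dataset.x_cont:
            raise DataError(f"continuous column {term.name!r} not in dataset")
        x = np.asarray(dataset.x_cont[term.name], dtype=float)
        lo, hi = term.bounds if term.bounds else (x.min(), x.max())
        B = bspline_basis(x, term, lo=lo, hi=hi)
        K = difference_penalty(term.n_basis, term.penalty_order)
        Bc, Kc, T = center_constraint(B, K)
        blocks.append(PenalizedBlock(
            name=term.name, kind="pspline", basis=Bc, penalty=Kc,
            coef_transform=T,
            meta={"term": term, "lo": lo, "hi": hi,
                  "x_range": (float(x.min()), float(x.max()))},
        ))

    if spec.spatial:
        if dataset.region is None:
            raise DataError("model has spatial terms but dataset has no regions")
        g = spec.graph
        r = np.asarray(dataset.region)
        if r.min() < 0 or r.max() >= g.n_regions:
            raise DataError("region index outside the graph")
        E = np.zeros((n, g.n_regions))
        E[np.arange(n), r] = 1.0
        for term in spec.spatial:
            if term.kind == "structured":
                Z = _per_component_centering(g)
                K = Z.T @ mrf_penalty(g) @ Z
                kind = "mrf"
            else:
                # single global sum-to-zero; orthonormal columns keep the
                # identity penalty exactly the identity after projection
                _, _, Z = center_constraint(np.ones((1, g.n_regions)),
                                            np.eye(g.n_regions))
                K = Z.T @ Z
                kind = "iid"
            blocks.append(PenalizedBlock(
                name=term.name, kind=kind, basis=E @ Z, penalty=K,
                coef_transform=Z, meta={"graph": g},
            ))

    X = np.concatenate(x_parts, axis=1) if x_parts else np.zeros((n, 0))
    return DesignBlocks(X=X, x_names=x_names, fixed_slices=fixed_slices,
                        blocks=blocks, n_obs=n)
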