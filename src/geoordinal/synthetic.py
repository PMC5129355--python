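"""Synthetic data generation for geoadditive ordinal regression.

Everything downstream (design construction, penalized fitting, reporting)
is exercised against data produced here: region adjacency graphs, intrinsic
CAR (ICAR) spatial fields, nonlinear covariate effects and ordered outcomes
drawn from a cumulative-logit latent-variable model.

Conventions
-----------
* Region indices are ``0..n_regions-1`` internally; external files use the
  graph's string labels.
* The latent predictor ``w`` enters the outcome as ``P(y <= j) = F(theta_j - w)``
  with ``F`` the logistic CDF, so a *positive* contribution to ``w`` pushes
  probability mass toward *higher* outcome categories.
* Every stochastic operation takes an explicit integer seed (or an existing
  :class:`numpy.random.Generator`); there is no global random state.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import ConfigurationError, DataError, DomainError

__all__ = [
    "AdjacencyGraph",
    "CategoricalEffect",
    "OrdinalDataset",
    "SimulationSpec",
    "SimulationTruth",
    "category_probabilities",
    "lattice_with_appendix",
    "make_lattice_graph",
    "m3_scenario",
    "read_dataset",
    "read_graph",
    "sample_icar_field",
    "simulate_dataset",
    "write_dataset",
    "write_graph",
]


# ---------------------------------------------------------------------------
# adjacency graphs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected region neighbourhood structure.

    Parameters
    ----------
    n_regions
        Number of regions (nodes).
    edges
        Unordered neighbour pairs, stored as ``(i, j)`` tuples with
        ``i < j``.  Use :meth:`from_edges` to normalize arbitrary input.
    labels
        External string label per region.  Defaults to ``"1".."n"``.
    """

    n_regions: int
    edges: frozenset
    labels: tuple = None

    def __post_init__(self):
        if self.n_regions < 1:
            raise DomainError("graph needs at least one region")
        for e in self.edges:
            i, j = e
            if i == j:
                raise DataError(f"self-loop at region {i}")
            if not (0 <= i < j < self.n_regions):
                raise DataError(f"edge {e} outside 0..{self.n_regions - 1}")
        if self.labels is None:
            object.__setattr__(
                self, "labels", tuple(str(i + 1) for i in range(self.n_regions))
            )
        elif len(self.labels) != self.n_regions:
            raise DataError("label count does not match n_regions")

    @classmethod
    def from_edges(cls, n_regions, edges, labels=None):
        """Build a graph from an iterable of (possibly unordered) pairs."""
        norm = frozenset((min(i, j), max(i, j)) for i, j in edges)
        return cls(n_regions, norm, tuple(labels) if labels is not None else None)

    @property
    def n_edges(self):
        return len(self.edges)

    def neighbors(self):
        """Adjacency lists as a dict ``index -> sorted neighbour indices``."""
        nb = {i: [] for i in range(self.n_regions)}
        for i, j in self.edges:
            nb[i].append(j)
            nb[j].append(i)
        return {i: sorted(v) for i, v in nb.items()}

    def degrees(self):
        deg = np.zeros(self.n_regions, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency_matrix(self):
        a = np.zeros((self.n_regions, self.n_regions))
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        return a

    def laplacian(self):
        """Graph Laplacian ``diag(degree) - adjacency`` (the MRF penalty)."""
        return np.diag(self.degrees().astype(float)) - self.adjacency_matrix()

    def components(self):
        """Connected components as a list of sorted index lists (BFS)."""
        nb = self.neighbors()
        seen = np.zeros(self.n_regions, dtype=bool)
        comps = []
        for start in range(self.n_regions):
            if seen[start]:
                continue
            stack, comp = [start], []
            seen[start] = True
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in nb[u]:
                    if not seen[v]:
                        seen[v] = True
                        stack.append(v)
            comps.append(sorted(comp))
        return comps

    def index_of(self):
        """Map external label -> internal index."""
        return {lab: i for i, lab in enumerate(self.labels)}


def make_lattice_graph(n_rows: int, n_cols: int) -> AdjacencyGraph:
    """Rook-adjacency rectangular lattice with ``n_rows * n_cols`` regions.

    Interior nodes have degree 4.  Raises :class:`DomainError` for a zero
    or negative dimension.
    """
    if n_rows < 1 or n_cols < 1:
        raise DomainError("lattice dimensions must be >= 1")
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            k = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((k, k + 1))
            if r + 1 < n_rows:
                edges.append((k, k + n_cols))
    return AdjacencyGraph.from_edges(n_rows * n_cols, edges)


def lattice_with_appendix(n_rows: int = 6, n_cols: int = 6) -> AdjacencyGraph:
    """Lattice plus one extra node hanging off the last lattice node.

    The default ``6 x 6 + 1`` gives a connected 37-region graph, the
    stand-in for a 36-state map plus a capital territory.
    """
    base = make_lattice_graph(n_rows, n_cols)
    n = base.n_regions
    return AdjacencyGraph.from_edges(n + 1, set(base.edges) | {(n - 1, n)})


# --- neighbour-list text format -------------------------------------------
#
# line 1: region count
# then one line per region: label, neighbour count, neighbour labels.


def write_graph(graph: AdjacencyGraph, path) -> None:
    nb = graph.neighbors()
    with open(path, "w") as fh:
        fh.write(f"{graph.n_regions}\n")
        for i in range(graph.n_regions):
            labs = " ".join(graph.labels[j] for j in nb[i])
            fh.write(f"{graph.labels[i]} {len(nb[i])}{' ' if labs else ''}{labs}\n")


def read_graph(path) -> AdjacencyGraph:
    """Read the neighbour-list dialect; validates symmetry."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    lines = [ln.strip() for ln in tokens if ln.strip()]
    n = int(lines[0])
    if len(lines) != n + 1:
        raise DataError(f"expected {n} region lines, found {len(lines) - 1}")
    labels, neigh = [], []
    for ln in lines[1:]:
        parts = ln.split()
        lab, cnt = parts[0], int(parts[1])
        if len(parts) != 2 + cnt:
            raise DataError(f"region {lab}: declared {cnt} neighbours, "
                            f"listed {len(parts) - 2}")
        labels.append(lab)
        neigh.append(parts[2:])
    if len(set(labels)) != n:
        raise DataError("duplicate region labels in graph file")
    idx = {lab: i for i, lab in enumerate(labels)}
    edges = set()
    directed = set()
    for i, nbrs in enumerate(neigh):
        for lab in nbrs:
            if lab not in idx:
                raise DataError(f"unknown neighbour label {lab!r}")
            j = idx[lab]
            directed.add((i, j))
            edges.add((min(i, j), max(i, j)))
    for i, j in edges:
        if (i, j) not in directed or (j, i) not in directed:
            raise DataError(
                f"asymmetric adjacency between {labels[i]!r} and {labels[j]!r}"
            )
    return AdjacencyGraph.from_edges(n, edges, labels)


# ---------------------------------------------------------------------------
# intrinsic CAR sampling
# ---------------------------------------------------------------------------


def _as_rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_icar_field(graph: AdjacencyGraph, tau2: float, seed) -> np.ndarray:
    """Draw a structured spatial field from the intrinsic CAR prior.

    The draw lives in the space orthogonal to the per-component constant
    vectors of the graph Laplacian ``K`` and has covariance
    ``tau2 * pinv(K)`` there; the sum over each connected component is
    exactly zero.  ``tau2 = 0`` returns the zero field.

    Parameters
    ----------
    graph
        Region adjacency defining the MRF penalty.
    tau2
        Spatial variance (>= 0).
    seed
        Integer seed or an existing :class:`numpy.random.Generator`.
    """
    if tau2 < 0:
        raise DomainError("tau2 must be non-negative")
    rng = _as_rng(seed)
    if tau2 == 0:
        return np.zeros(graph.n_regions)
    lam, gamma = np.linalg.eigh(graph.laplacian())
    tol = max(lam.max(), 1.0) * 1e-10
    keep = lam > tol
    z = rng.standard_normal(keep.sum())
    f = gamma[:, keep] @ (z * np.sqrt(tau2 / lam[keep]))
    # eigenvectors are orthogonal to component indicators already; remove
    # residual rounding so the per-component sums are exactly zero
    for comp in graph.components():
        f[comp] -= f[comp].mean()
    return f


# ---------------------------------------------------------------------------
# cumulative-logit outcome machinery
# ---------------------------------------------------------------------------


def category_probabilities(thresholds, eta):
    """Category probabilities of the cumulative logistic model.

    ``p_j = F(theta_j - eta) - F(theta_{j-1} - eta)`` with
    ``theta_0 = -inf`` and ``theta_K = +inf``.  ``eta`` may be a scalar
    (returns shape ``(K,)``) or a vector (returns ``(n, K)``).
    """
    th = np.asarray(thresholds, dtype=float)
    if th.ndim != 1 or th.size < 1:
        raise DomainError("need at least one threshold")
    if np.any(np.diff(th) <= 0):
        raise DomainError("thresholds must be strictly increasing")
    eta_arr = np.atleast_1d(np.asarray(eta, dtype=float))
    cum = expit(th[None, :] - eta_arr[:, None])  # (n, K-1)
    full = np.concatenate(
        [np.zeros((eta_arr.size, 1)), cum, np.ones((eta_arr.size, 1))], axis=1
    )
    p = np.diff(full, axis=1)
    return p[0] if np.isscalar(eta) or np.asarray(eta).ndim == 0 else p


# ---------------------------------------------------------------------------
# simulation specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CategoricalEffect:
    """A categorical covariate with effect-coded true coefficients.

    ``coefficients`` maps each non-reference level to its coefficient; the
    reference level's implied contribution is ``-sum(coefficients)`` under
    the +1/-1/0 effect coding.  ``probabilities`` gives sampling weights per
    level (uniform if omitted).
    """

    levels: tuple
    reference: str
    coefficients: Mapping[str, float]
    probabilities: Mapping[str, float] = None

    def __post_init__(self):
        if self.reference not in self.levels:
            raise ConfigurationError(
                f"reference {self.reference!r} not among levels {self.levels}"
            )
        for lev in self.coefficients:
            if lev not in self.levels or lev == self.reference:
                raise ConfigurationError(f"coefficient for invalid level {lev!r}")
        missing = set(self.levels) - {self.reference} - set(self.coefficients)
        if missing:
            raise ConfigurationError(f"levels without coefficient: {sorted(missing)}")

    def contribution(self, level: str) -> float:
        if level == self.reference:
            return -float(sum(self.coefficients.values()))
        return float(self.coefficients[level])

    def level_probs(self):
        if self.probabilities is None:
            return np.full(len(self.levels), 1.0 / len(self.levels))
        p = np.array([self.probabilities[lev] for lev in self.levels], dtype=float)
        return p / p.sum()


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic geoadditive ordinal dataset.

    ``continuous`` declares covariate ranges (uniform sampling);
    ``smooth_functions`` maps a declared covariate to its true effect
    function.  A smooth referring to an undeclared covariate is a
    configuration error.
    """

    n_obs: int
    thresholds: tuple
    continuous: Mapping[str, tuple] = field(default_factory=dict)
    smooth_functions: Mapping[str, Callable] = field(default_factory=dict)
    fixed_effects: Mapping[str, CategoricalEffect] = field(default_factory=dict)
    tau2_str: float = 0.0
    tau2_unstr: float = 0.0
    graph: AdjacencyGraph = None
    region_weights: Sequence[float] = None
    seed: int = 0

    def __post_init__(self):
        th = np.asarray(self.thresholds, dtype=float)
        if th.size < 1 or np.any(np.diff(th) <= 0):
            raise ConfigurationError("thresholds must be strictly increasing")
        if self.n_obs < 1:
            raise ConfigurationError("n_obs must be positive")
        if self.tau2_str < 0 or self.tau2_unstr < 0:
            raise ConfigurationError("variances must be non-negative")
        unknown = set(self.smooth_functions) - set(self.continuous)
        if unknown:
            raise ConfigurationError(
                f"smooth_functions name undeclared covariates: {sorted(unknown)}"
            )
        if (self.tau2_str > 0 or self.tau2_unstr > 0 or self.graph is not None
                ) and self.graph is None:
            raise ConfigurationError("spatial variance requested without a graph")

    @property
    def n_categories(self):
        return len(self.thresholds) + 1


@dataclass(frozen=True)
class OrdinalDataset:
    """Per-observation outcome, covariates and region index.

    ``y`` holds ``1..K`` codes (or ``0/1`` after binary recoding),
    ``x_cont`` continuous covariates, ``v_cat`` categorical level labels,
    ``region`` internal region indices into the companion graph.
    """

    y: np.ndarray
    x_cont: Mapping[str, np.ndarray]
    v_cat: Mapping[str, np.ndarray]
    region: np.ndarray = None

    def __post_init__(self):
        n = self.n_obs
        for name, col in {**dict(self.x_cont), **dict(self.v_cat)}.items():
            if len(col) != n:
                raise DataError(f"column {name!r} has length {len(col)} != {n}")
        if self.region is not None and len(self.region) != n:
            raise DataError("region column length mismatch")

    @property
    def n_obs(self):
        return len(self.y)

    def validate(self, graph: AdjacencyGraph = None, n_categories: int = None):
        """Check outcome range and region indices against a graph."""
        y = np.asarray(self.y)
        if n_categories is not None and (y.min() < 0 or y.max() > n_categories):
            raise DataError("outcome outside declared category range")
        if graph is not None and self.region is not None:
            r = np.asarray(self.region)
            if r.min() < 0 or r.max() >= graph.n_regions:
                raise DataError("region index outside the companion graph")
        return self

    def to_frame(self, graph: AdjacencyGraph = None) -> pd.DataFrame:
        cols = {"y": np.asarray(self.y)}
        cols.update({k: np.asarray(v) for k, v in self.x_cont.items()})
        cols.update({k: np.asarray(v) for k, v in self.v_cat.items()})
        if self.region is not None:
            if graph is not None:
                cols["region"] = np.asarray(
                    [graph.labels[i] for i in np.asarray(self.region)]
                )
            else:
                cols["region"] = np.asarray(self.region)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SimulationTruth:
    """True effect values generated alongside a simulated dataset."""

    w: np.ndarray
    smooth_values: Mapping[str, np.ndarray]
    f_str: np.ndarray
    f_unstr: np.ndarray
    fixed_values: Mapping[str, np.ndarray]
    spec: SimulationSpec


def simulate_dataset(spec: SimulationSpec):
    """Simulate an :class:`OrdinalDataset` from a :class:`SimulationSpec`.

    Returns ``(dataset, truth)`` where ``truth`` carries every true effect
    component for recovery testing.  Deterministic given ``spec.seed``.
    """
    rng = _as_rng(spec.seed)
    n = spec.n_obs
    w = np.zeros(n)

    x_cont, smooth_values = {}, {}
    for name, (lo, hi) in spec.continuous.items():
        x_cont[name] = rng.uniform(lo, hi, n)
    for name, fn in spec.smooth_functions.items():
        smooth_values[name] = np.asarray(fn(x_cont[name]), dtype=float)
        w += smooth_values[name]

    v_cat, fixed_values = {}, {}
    for name, eff in spec.fixed_effects.items():
        draws = rng.choice(len(eff.levels), size=n, p=eff.level_probs())
        labels = np.asarray(eff.levels, dtype=object)[draws]
        v_cat[name] = labels
        contrib = np.array([eff.contribution(lev) for lev in eff.levels])
        fixed_values[name] = contrib[draws]
        w += fixed_values[name]

    region = None
    f_str = np.zeros(0)
    f_unstr = np.zeros(0)
    if spec.graph is not None:
        g = spec.graph
        if spec.region_weights is not None:
            pw = np.asarray(spec.region_weights, dtype=float)
            region = rng.choice(g.n_regions, size=n, p=pw / pw.sum())
        else:
            region = rng.integers(0, g.n_regions, size=n)
        f_str = sample_icar_field(g, spec.tau2_str, rng)
        f_unstr = rng.standard_normal(g.n_regions) * np.sqrt(spec.tau2_unstr)
        w += f_str[region] + f_unstr[region]

    cum = expit(np.asarray(spec.thresholds)[None, :] - w[:, None])
    u = rng.random(n)
    y = 1 + (u[:, None] > cum).sum(axis=1)

    ds = OrdinalDataset(y=y, x_cont=x_cont, v_cat=v_cat, region=region)
    truth = SimulationTruth(
        w=w, smooth_values=smooth_values, f_str=f_str, f_unstr=f_unstr,
        fixed_values=fixed_values, spec=spec,
    )
    return ds, truth


def m3_scenario(n_obs: int = 5000, seed: int = 0, *,
                tau2_str: float = 0.3, tau2_unstr: float = 0.03) -> SimulationSpec:
    """Default geoadditive scenario: U-shape + sigmoid smooths, two binary
    fixed effects and a correlated 37-region spatial field.

    Variance magnitudes are chosen for testability (the motivating analysis
    never reports them); thresholds echo the magnitudes of a published
    intercept-only ordinal fit.
    """
    graph = lattice_with_appendix(6, 6)
    return SimulationSpec(
        n_obs=n_obs,
        thresholds=(-1.9, 0.1, 1.6),
        continuous={"mage": (16.0, 48.0), "mbmi": (15.0, 35.0)},
        smooth_functions={
            "mage": lambda a: 0.9 * ((a - 32.0) / 12.0) ** 2 - 0.45,
            "mbmi": lambda b: 0.8 * expit((b - 22.0) / 2.0) - 0.4,
        },
        fixed_effects={
            "sex": CategoricalEffect(
                levels=("female", "male"), reference="female",
                coefficients={"male": 0.30},
            ),
            "iron": CategoricalEffect(
                levels=("no", "yes"), reference="no",
                coefficients={"yes": -0.25},
                probabilities={"no": 0.55, "yes": 0.45},
            ),
        },
        tau2_str=tau2_str,
        tau2_unstr=tau2_unstr,
        graph=graph,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# delimited-text dataset IO
# ---------------------------------------------------------------------------


def write_dataset(dataset: OrdinalDataset, path, graph: AdjacencyGraph = None):
    """Write comma-separated text with a header; region as external label."""
    dataset.to_frame(graph).to_csv(path, index=False)


def read_dataset(path, *, graph: AdjacencyGraph = None,
                 continuous=(), categorical=(), response="y",
                 region_column="region") -> OrdinalDataset:
    """Read a delimited dataset written by :func:`write_dataset`.

    Region labels are matched against ``graph.labels`` (exact string match
    after trimming); unknown labels are fatal and listed.
    """
    df = pd.read_csv(path, dtype={region_column: str} if graph is not None else None)
    region = None
    if graph is not None and region_column in df.columns:
        idx = graph.index_of()
        labs = df[region_column].astype(str).str.strip()
        bad = sorted(set(labs) - set(idx))
        if bad:
            raise DataError(f"region labels absent from graph: {bad}")
        region = labs.map(idx).to_numpy()
    return OrdinalDataset(
        y=df[response].to_numpy(),
        x_cont={c: df[c].to_numpy(dtype=float) for c in continuous},
        v_cat={c: df[c].astype(str).to_numpy() for c in categorical},
        region=region,
    )
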