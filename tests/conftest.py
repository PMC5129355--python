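import numpy as np
import pytest

import geoordinal as go


@pytest.fixture(scope="session")
def path3():
    """Three-node path graph 0-1-2."""
    return go.AdjacencyGraph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture(scope="session")
def graph37():
    return go.lattice_with_appendix(6, 6)


@pytest.fixture(scope="session")
def small_cumulative_data():
    """K=3 dataset with one binary fixed effect, n=30 (oracle scale)."""
    rng = np.random.default_rng(42)
    sex = rng.choice(["female", "male"], size=30)
    w = np.where(sex == "male", 0.5, -0.5)
    cum = 1.0 / (1.0 + np.exp(-(np.array([-0.5, 0.8])[None, :] - w[:, None])))
    u = rng.random(30)
    y = 1 + (u[:, None] > cum).sum(axis=1)
    # ensure all categories appear
    y[:3] = [1, 2, 3]
    return go.OrdinalDataset(y=y, x_cont={}, v_cat={"sex": sex})


@pytest.fixture(scope="session")
def small_binary_data():
    rng = np.random.default_rng(0)
    n = 40  # small enough for the brute-force oracle, no quasi-separation
    sex = rng.choice(["female", "male"], size=n)
    grp = rng.choice(["a", "b", "c"], size=n)
    eta = -0.3 + 0.8 * (sex == "male") - 0.4 * (grp == "b")
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return go.OrdinalDataset(y=y, x_cont={}, v_cat={"sex": sex, "grp": grp})


@pytest.fixture(scope="session")
def m3_model_spec(graph37):
    """Model spec matching the default m3 scenario."""
    return go.ModelSpec(
        fixed=(go.FixedTerm("sex", ("female", "male"), "female"),
               go.FixedTerm("iron", ("no", "yes"), "no")),
        smooth=(go.PSplineTerm("mage", n_inner_knots=10),
                go.PSplineTerm("mbmi", n_inner_knots=10)),
        spatial=(go.SpatialTerm("structured"), go.SpatialTerm("unstructured")),
        graph=graph37,
    )


@pytest.fixture(scope="session")
def m3_fit(m3_model_spec):
    """One moderately sized geoadditive cumulative fit, shared across tests."""
    spec = go.m3_scenario(n_obs=2500, seed=11)
    ds, truth = go.simulate_dataset(spec)
    fit = go.fit_cumulative(ds, m3_model_spec)
    return spec, ds, truth, fit
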