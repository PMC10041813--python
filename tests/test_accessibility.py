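import math

import numpy as np
import pandas as pd
import pytest

from bloodaccess import (
    DecayParams,
    FloatingCatchmentModel,
    classify_spai,
    decay_weight,
    selection_weights,
    spai,
    supply_demand_ratio,
)
from bloodaccess.accessibility import aggregate_subcounty, compare_marginalization

BETA_DEFAULT = 60.0**2 / math.log(100.0)  # ~781.56


def _random_system(rng, n_ea=30, n_f=4, t_hi=55.0):
    T = pd.DataFrame(rng.uniform(0.0, t_hi, (n_ea, n_f)),
                     index=[f"E{i}" for i in range(n_ea)],
                     columns=[f"F{j}" for j in range(n_f)])
    P = pd.Series(rng.uniform(50.0, 2000.0, n_ea), index=T.index)
    S = pd.Series(rng.uniform(100.0, 5000.0, n_f), index=T.columns)
    return T, P, S


def test_decay_weight_analytics():
    p = DecayParams()
    assert p.beta == pytest.approx(BETA_DEFAULT, rel=1e-9)
    assert decay_weight(0.0, p) == 1.0
    assert decay_weight(math.sqrt(p.beta), p) == pytest.approx(math.exp(-1.0), rel=1e-12)
    assert decay_weight(60.0, p) == pytest.approx(0.01, abs=1e-6)  # calibrated edge
    assert decay_weight(60.0001, p) == 0.0  # hard cutoff
    assert decay_weight(np.inf, p) == 0.0
    with pytest.raises(ValueError, match="non-negative"):
        decay_weight(-1.0, p)


def test_decay_params_validation():
    with pytest.raises(ValueError):
        DecayParams(t_max=-5.0)
    with pytest.raises(ValueError):
        DecayParams(t_max=60.0, beta=0.0)


def test_selection_weights_normalise_within_catchment():
    p = DecayParams()
    one = selection_weights(pd.DataFrame([[12.0, 90.0]]), p)
    np.testing.assert_allclose(one.to_numpy(), [[1.0, 0.0]])
    equidistant = selection_weights(pd.DataFrame([[25.0, 25.0]]), p)
    np.testing.assert_allclose(equidistant.to_numpy(), [[0.5, 0.5]])
    two = selection_weights(pd.DataFrame([[10.0, 30.0]]), p)
    w10, w30 = math.exp(-100.0 / p.beta), math.exp(-900.0 / p.beta)
    np.testing.assert_allclose(two.to_numpy(), [[w10 / (w10 + w30), w30 / (w10 + w30)]], rtol=1e-9)
    np.testing.assert_allclose(two.to_numpy(), [[0.7357, 0.2643]], atol=1e-4)
    none = selection_weights(pd.DataFrame([[70.0, 90.0]]), p)
    np.testing.assert_allclose(none.to_numpy(), [[0.0, 0.0]])


def test_beta_limit_gives_uniform_selection():
    T = pd.DataFrame([[5.0, 40.0, 58.0, 70.0]])
    G = selection_weights(T, DecayParams(t_max=60.0, beta=1e9))
    np.testing.assert_allclose(G.to_numpy(), [[1 / 3, 1 / 3, 1 / 3, 0.0]], atol=1e-6)


def test_supply_demand_ratio_examples():
    p = DecayParams()
    # single EA at the facility: R = S / (G P W) = 50 / 100
    T = pd.DataFrame([[0.0]])
    G = selection_weights(T, p)
    W = pd.DataFrame(decay_weight(T.to_numpy(), p))
    R = supply_demand_ratio(G, pd.Series([100.0]), W, pd.Series([50.0]))
    assert R.iloc[0] == pytest.approx(0.5)
    # two EAs at t=0 double the demand
    T = pd.DataFrame([[0.0], [0.0]])
    G = selection_weights(T, p)
    W = pd.DataFrame(decay_weight(T.to_numpy(), p))
    R = supply_demand_ratio(G, pd.Series([100.0, 100.0]), W, pd.Series([50.0]))
    assert R.iloc[0] == pytest.approx(0.25)
    # an EA beyond the catchment contributes nothing
    T = pd.DataFrame([[0.0], [75.0]])
    G = selection_weights(T, p)
    W = pd.DataFrame(decay_weight(T.to_numpy(), p))
    R = supply_demand_ratio(G, pd.Series([100.0, 1e9]), W, pd.Series([50.0]))
    assert R.iloc[0] == pytest.approx(0.5)


def test_supply_demand_flags_and_errors():
    p = DecayParams()
    T = pd.DataFrame([[70.0]])  # nobody reaches the facility
    G = selection_weights(T, p)
    W = pd.DataFrame(decay_weight(T.to_numpy(), p))
    R = supply_demand_ratio(G, pd.Series([100.0]), W, pd.Series([50.0]))
    assert R.isna().iloc[0]
    with pytest.raises(ValueError, match="non-negative"):
        supply_demand_ratio(G, pd.Series([-1.0]), W, pd.Series([50.0]))


def test_spai_single_pair_and_no_access():
    p = DecayParams()
    T = pd.DataFrame([[0.0], [90.0]])
    G = selection_weights(T, p)
    W = pd.DataFrame(decay_weight(T.to_numpy(), p))
    R = supply_demand_ratio(G, pd.Series([100.0, 500.0]), W, pd.Series([50.0]))
    vals = spai(G, R, W)
    assert vals.iloc[0] == pytest.approx(0.5)
    assert vals.iloc[1] == 0.0


def test_supply_conservation_identity():
    rng = np.random.default_rng(21)
    for _ in range(10):
        T, P, S = _random_system(rng)
        res = FloatingCatchmentModel(T, P, S).fit()
        lhs = float((P * res.spai).sum())
        rhs = float(S[res.R.notna()].sum())
        assert lhs == pytest.approx(rhs, rel=1e-12)


def test_increasing_supply_weakly_increases_spai():
    rng = np.random.default_rng(22)
    T, P, S = _random_system(rng)
    base = FloatingCatchmentModel(T, P, S).fit().spai
    S2 = S.copy()
    S2.iloc[1] *= 2.0
    bigger = FloatingCatchmentModel(T, P, S2).fit().spai
    assert (bigger >= base - 1e-12).all()


def test_classification_boundaries_and_partition():
    vals = pd.Series([0.5, 1.5, 1.51, 0.0, 7.0])
    cls = classify_spai(vals, mode="fixed")
    assert list(cls) == ["low", "moderate", "high", "low", "high"]
    assert cls.value_counts().sum() == len(vals)


def test_quantile_classification_and_constant_warning():
    vals = pd.Series(np.linspace(0, 1, 100))
    cls = classify_spai(vals, mode="quantile")
    counts = cls.value_counts()
    assert counts["low"] == pytest.approx(40, abs=1)
    assert counts["moderate"] == pytest.approx(40, abs=1)
    assert counts["high"] == pytest.approx(20, abs=1)
    with pytest.warns(UserWarning, match="constant"):
        flat = classify_spai(pd.Series([1.0] * 5), mode="quantile")
    assert (flat == "moderate").all()
    with pytest.raises(ValueError, match="unknown"):
        classify_spai(vals, mode="tertile")


def test_subcounty_aggregation_matches_naive_tally():
    rng = np.random.default_rng(30)
    n = 60
    vals = pd.Series(rng.uniform(0, 3, n), index=range(n))
    cls = classify_spai(vals)
    sub = pd.Series(rng.integers(0, 4, n), index=range(n))
    pop = pd.Series(rng.uniform(10, 500, n), index=range(n))
    table = aggregate_subcounty(vals, cls, sub, pop)
    for sc in range(4):
        sel = sub == sc
        assert table.loc[sc, "mean_spai"] == pytest.approx(vals[sel].mean())
        for lab in ("low", "moderate", "high"):
            manual = pop[sel & (cls == lab)].sum()
            assert table.loc[sc, f"persons_{lab}"] == pytest.approx(manual)
        pct = sum(table.loc[sc, f"pct_{lab}"] for lab in ("low", "moderate", "high"))
        assert pct == pytest.approx(100.0, abs=0.01)
    assert table.loc["county", "persons"] == pytest.approx(pop.sum())


def test_aggregation_single_class_and_even_split():
    vals = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
    cls = pd.Series(["low"] * 3, index=list("abc"))
    sub = pd.Series([0, 0, 0], index=list("abc"))
    pop = pd.Series([10.0, 10.0, 10.0], index=list("abc"))
    t = aggregate_subcounty(vals, cls, sub, pop)
    assert t.loc[0, "pct_low"] == pytest.approx(100.0)
    cls2 = pd.Series(["low", "moderate", "high"], index=list("abc"))
    t2 = aggregate_subcounty(vals, cls2, sub, pop)
    for lab in ("low", "moderate", "high"):
        assert t2.loc[0, f"pct_{lab}"] == pytest.approx(100.0 / 3.0, abs=0.05)


def test_aggregation_rejects_orphan_eas():
    vals = pd.Series([1.0, 2.0], index=["a", "b"])
    cls = classify_spai(vals)
    with pytest.raises(ValueError, match="no sub-county"):
        aggregate_subcounty(vals, cls, pd.Series({"a": 0}), pd.Series({"a": 1.0, "b": 1.0}))


def test_marginalization_comparison_identities():
    tt = pd.Series({0: 100.0, 1: 50.0})
    same = compare_marginalization(tt, tt)
    assert (same["difference"] == 0).all()
    # low-SPAI flags a superset of the beyond-1h population
    superset = tt * 1.8
    comp = compare_marginalization(tt, superset)
    assert (comp["ratio"] >= 1.0).all()


def test_congested_demand_flags_more_than_travel_time(small_bundle, small_cost, small_graph):
    """With supply-demand accounting, underserved areas exceed the pure
    travel-time marginalisation (the index captures congestion)."""
    from bloodaccess import accumulate_cost, catchment_population, od_matrix

    b = small_bundle
    trans = b.facilities[b.facilities["transfusing"]]
    T = od_matrix(small_cost, trans, b.ea_centroids, b.dem, graph=small_graph)
    supply = trans.set_index("id")["admissions"].astype(float)
    res = FloatingCatchmentModel(T, b.ea_populations, supply).fit()
    tt = accumulate_cost(small_cost, trans, b.dem, graph=small_graph)
    zonal = catchment_population(tt, b.population, b.subcounty_labels, [30, 60])
    tt_marg = float(zonal.loc["county", "beyond_60min"])
    low = res.classes == "low"
    spai_low = float(b.ea_populations[low[low].index].sum())
    assert spai_low >= tt_marg
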