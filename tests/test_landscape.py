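"""Function landscapes: effects, interactions, curves, rankings, graph."""

import math

import numpy as np
import pandas as pd
import pytest

from combiplate.errors import IncompleteLandscapeError, ValidationError
from combiplate.landscape import (
    FunctionLandscape,
    adjacency_graph,
    diversity_function_curve,
    effects_table,
    functional_effect,
    interactions_table,
    pairwise_interaction,
    rank_consortia,
    third_order_interaction,
)
from combiplate.synth import (
    LandscapeGeneratorConfig,
    generate_landscape,
    singleton_coefficients,
)


def landscape_from_means(means: dict[int, float], m: int) -> FunctionLandscape:
    return FunctionLandscape(m, {k: np.array([v]) for k, v in means.items()})


@pytest.fixture
def additive_m5():
    effects = [0.5, -0.2, 0.3, 0.1, 0.4]
    cfg = LandscapeGeneratorConfig(5, singleton_coefficients(effects, 5))
    return generate_landscape(cfg).landscape, effects


# ---------------------------------------------------------------------------
# Functional effects


def test_functional_effect_is_a_difference():
    ls = landscape_from_means({0b00: 1.0, 0b01: 1.3, 0b10: 1.0, 0b11: 1.3}, 2)
    assert functional_effect(1, 0, ls).effect == pytest.approx(0.3)
    assert functional_effect(2, 0, ls).effect == 0.0


def test_effect_rejects_background_containing_strain():
    ls = landscape_from_means({i: float(i) for i in range(4)}, 2)
    with pytest.raises(ValidationError, match="contains"):
        functional_effect(1, 0b01, ls)


def test_additive_landscape_has_constant_effects(additive_m5):
    ls, effects = additive_m5
    table = effects_table(ls)
    assert len(table) == 5 * 16
    for k, true_effect in enumerate(effects, start=1):
        vals = table.loc[table["strain"] == k, "effect"]
        np.testing.assert_allclose(vals, true_effect, atol=1e-12)


def test_missing_code_raises_incompleteness_error_naming_it():
    values = {i: np.array([1.0]) for i in range(8) if i != 0b101}
    ls = FunctionLandscape(3, values)
    with pytest.raises(IncompleteLandscapeError, match="101"):
        effects_table(ls)


# ---------------------------------------------------------------------------
# Pairwise and third-order interactions


def test_pairwise_interaction_arithmetic():
    # F(b)=1.0, F(b+i)=1.5, F(b+j)=1.4, F(b+ij)=1.6 -> eps = -0.3
    ls = landscape_from_means({0b00: 1.0, 0b01: 1.5, 0b10: 1.4, 0b11: 1.6}, 2)
    rec = pairwise_interaction(1, 2, 0, ls)
    assert rec.epsilon == pytest.approx(-0.3)


def test_additive_landscape_has_zero_interactions(additive_m5):
    ls, _ = additive_m5
    table = interactions_table(ls)
    assert len(table) == math.comb(5, 2) * 8
    np.testing.assert_allclose(table["epsilon"], 0.0, atol=1e-12)


def test_planted_pairwise_term_is_recovered_in_every_background():
    coeffs = singleton_coefficients([0.5, -0.2, 0.3, 0.1, 0.4], 5)
    coeffs[0b00011] = -0.37  # pair (1,2)
    ls = generate_landscape(LandscapeGeneratorConfig(5, coeffs)).landscape
    table = interactions_table(ls, pairs=[(1, 2)])
    np.testing.assert_allclose(table["epsilon"], -0.37, atol=1e-12)
    others = interactions_table(ls, pairs=[(3, 4), (2, 5)])
    np.testing.assert_allclose(others["epsilon"], 0.0, atol=1e-12)


def test_interaction_equals_effect_difference_exhaustively():
    """eps_ij(b) = dF_i(b+j) − dF_i(b) at every valid (i, j, b), m=5."""
    coeffs = singleton_coefficients([0.5, -0.2, 0.3, 0.1, 0.4], 5)
    coeffs.update({0b00011: -0.3, 0b10100: 0.2, 0b01110: 0.15})
    ls = generate_landscape(LandscapeGeneratorConfig(5, coeffs)).landscape
    m = 5
    for i in range(1, m + 1):
        for j in range(1, m + 1):
            if i == j:
                continue
            bi, bj = 1 << (i - 1), 1 << (j - 1)
            for b in range(1 << m):
                if b & (bi | bj):
                    continue
                eps = pairwise_interaction(i, j, b, ls).epsilon
                diff = (
                    functional_effect(i, b | bj, ls).effect
                    - functional_effect(i, b, ls).effect
                )
                assert eps == pytest.approx(diff, abs=1e-12)


def test_third_order_interaction_recovers_planted_coefficient():
    coeffs = singleton_coefficients([0.5, -0.2, 0.3, 0.1, 0.4], 5)
    coeffs[0b00111] = 0.42  # trio (1,2,3)
    ls = generate_landscape(LandscapeGeneratorConfig(5, coeffs)).landscape
    assert third_order_interaction(1, 2, 3, ls) == pytest.approx(0.42, abs=1e-12)
    assert third_order_interaction(1, 2, 4, ls) == pytest.approx(0.0, abs=1e-12)


def test_third_order_zero_on_additive_plus_pairwise():
    coeffs = singleton_coefficients([0.5, -0.2, 0.3], 3)
    coeffs.update({0b011: -0.3, 0b101: 0.1, 0b110: 0.2})
    ls = generate_landscape(LandscapeGeneratorConfig(3, coeffs)).landscape
    assert third_order_interaction(1, 2, 3, ls) == pytest.approx(0.0, abs=1e-12)


def test_negative_pairs_with_positive_trio():
    """A trio whose pairwise interactions are all negative can still engage
    in a positive third-order interaction that rescues its function."""
    coeffs = singleton_coefficients([0.6, 0.5, 0.4], 3)
    coeffs.update({0b011: -0.2, 0b101: -0.25, 0b110: -0.15, 0b111: 0.5})
    ls = generate_landscape(LandscapeGeneratorConfig(3, coeffs)).landscape
    for pair in [(1, 2), (1, 3), (2, 3)]:
        assert pairwise_interaction(*pair, 0, ls).epsilon < 0
    assert third_order_interaction(1, 2, 3, ls) > 0


def test_replicate_order_does_not_matter():
    rng = np.random.default_rng(0)
    values = {i: rng.normal(size=3) for i in range(8)}
    ls1 = FunctionLandscape(3, values)
    ls2 = FunctionLandscape(3, {k: v[::-1] for k, v in values.items()})
    t1 = interactions_table(ls1)
    t2 = interactions_table(ls2)
    pd.testing.assert_frame_equal(t1, t2)


# ---------------------------------------------------------------------------
# Curves, ranking, graph


def test_diversity_curve_group_sizes_are_binomial(additive_m5):
    ls, _ = additive_m5
    curve = diversity_function_curve(ls)
    assert curve["n_consortia"].tolist() == [math.comb(5, r) for r in range(6)]
    assert curve.loc[curve["richness"] == 5, "n_consortia"].iloc[0] == 1


def test_diversity_curve_peaks_where_planted():
    # strong positive singles with strong negative pairs: peak at richness 1
    coeffs = singleton_coefficients([1.0, 1.0, 1.0, 1.0], 4)
    coeffs.update({m: -1.5 for m in range(1, 16) if bin(m).count("1") == 2})
    ls = generate_landscape(LandscapeGeneratorConfig(4, coeffs)).landscape
    curve = diversity_function_curve(ls)
    assert curve.loc[curve["mean_function"].idxmax(), "richness"] == 1


def test_ranking_descends_with_deterministic_ties():
    ls = landscape_from_means({0: 0.0, 1: 2.0, 2: 2.0, 3: 1.0}, 2)
    ranked = rank_consortia(ls)
    assert ranked["consortium_binary"].tolist() == ["01", "10", "11", "00"]
    top1 = rank_consortia(ls, top_n=1)
    assert len(top1) == 1 and top1["consortium_binary"].iloc[0] == "01"


def test_constant_landscape_ranking_is_code_order():
    ls = landscape_from_means({i: 1.0 for i in range(8)}, 3)
    ranked = rank_consortia(ls)
    assert ranked["consortium_int"].tolist() == list(range(8))


@pytest.mark.parametrize("m, n_edges", [(1, 1), (3, 12), (8, 1024)])
def test_adjacency_graph_edge_count(m, n_edges):
    edges = adjacency_graph(m)
    assert len(edges) == n_edges == m * (1 << (m - 1))
    # every edge is a single-bit flip
    for r in edges.itertuples():
        assert int(r.code_with, 2) - int(r.code_without, 2) == 1 << (r.strain - 1)


# ---------------------------------------------------------------------------
# Container behaviour


def test_empty_consortium_defaults_to_zero_with_warning():
    values = {i: np.array([1.0]) for i in range(1, 8)}
    with pytest.warns(UserWarning, match="empty"):
        ls = FunctionLandscape(3, values)
    assert ls.mean(0) == 0.0
    assert ls.is_complete  # imputed blank completes the cube


def test_frame_round_trip():
    rng = np.random.default_rng(1)
    values = {i: rng.normal(size=2) for i in range(16)}
    ls = FunctionLandscape(4, values)
    back = FunctionLandscape.from_frame(ls.to_frame())
    for mask in range(16):
        np.testing.assert_allclose(back.values[mask], values[mask])
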