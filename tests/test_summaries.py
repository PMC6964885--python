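import numpy as np
import pytest

import partworth as pw

# population-mean vector on the coded scale: remission slope 0.10/point,
# strong aversions to the binary risks
MU = np.array([0.10, -0.04, 0.05, 0.0, -0.05, 0.03, 0.02, -0.5, -0.3, -0.72])


def _draws(n=400, sd=0.01, seed=0):
    rng = np.random.default_rng(seed)
    return MU + sd * rng.standard_normal((n, MU.size))


def test_scaling_factor_and_extremes(schema, coding):
    """Remission spans +/-3 utility at slope 0.10 -> factor 10/3, extremes +/-10."""
    su = pw.scale_utilities(MU[None, :], schema, coding)
    assert su.scale_factors[0] == pytest.approx(10.0 / 3.0)
    rem = su.table[su.table.attribute == "remission"].sort_values("level")
    np.testing.assert_allclose(rem["median"], [-10.0, 0.0, 10.0])


def test_single_draw_medians_equal_that_draw(schema, coding):
    su = pw.scale_utilities(MU[None, :], schema, coding)
    assert (su.table["median"] == su.table["lo"]).all()
    assert (su.table["median"] == su.table["hi"]).all()


def test_scaled_utilities_bounded_with_max_ten(schema, coding):
    su = pw.scale_utilities(_draws(), schema, coding)
    all_draws = np.concatenate(list(su.scaled_draws.values()), axis=1)
    assert np.nanmax(np.abs(all_draws)) <= 10.0 + 1e-9
    np.testing.assert_allclose(np.nanmax(np.abs(all_draws), axis=1), 10.0)


def test_scaling_preserves_within_attribute_ordering(schema, coding):
    """Scaling is a positive monotone transform of each draw's utilities."""
    draws = _draws(100, sd=0.05, seed=3)
    su = pw.scale_utilities(draws, schema, coding)
    levels = pw.summaries._level_utilities(draws, schema, coding)
    for a, raw in zip(schema, levels):
        order_raw = np.argsort(raw, axis=-1)
        order_scaled = np.argsort(su.scaled_draws[a.name], axis=-1)
        np.testing.assert_array_equal(order_raw, order_scaled)


def test_relative_importance_of_known_ranges(schema, coding):
    """Utility ranges 6:3:1-style proportions map to percentages directly."""
    toy = pw.AttributeSchema(
        (
            pw.Attribute("a", "linear", (0.0, 6.0), "higher", 3.0),
            pw.Attribute("b", "linear", (0.0, 3.0), "higher", 1.5),
            pw.Attribute("c", "linear", (0.0, 1.0), "higher", 0.5),
        )
    )
    cm = pw.CodingMap.from_schema(toy)
    ri = pw.relative_importance(np.ones((1, 3)), toy, cm)
    np.testing.assert_allclose(ri["importance"], [60.0, 30.0, 10.0])


def test_zero_range_attribute_has_zero_importance(schema, coding):
    mu = MU.copy()
    mu[2:7] = 0.0  # flatten dosing
    ri = pw.relative_importance(mu[None, :], schema, coding)
    assert float(ri.set_index("attribute").loc["dosing", "importance"]) == 0.0


def test_importance_sums_to_100_on_every_draw(schema, coding):
    draws = _draws(250, sd=0.2, seed=9)
    levels = pw.summaries._level_utilities(draws, schema, coding)
    ranges = np.stack([u.max(axis=-1) - u.min(axis=-1) for u in levels], axis=-1)
    ri_draws = 100 * ranges / ranges.sum(axis=-1, keepdims=True)
    np.testing.assert_allclose(ri_draws.sum(axis=-1), 100.0)
    ri = pw.relative_importance(draws, schema, coding)
    assert ri["importance"].sum() == pytest.approx(100.0)


def test_mrs_closed_form(schema, coding):
    """Slope 0.10/point and binary gap 1.44 utils -> 14.4 remission points."""
    table = pw.mrs(MU[None, :], schema, coding)
    row = table.set_index("attribute").loc["infection_cancer"]
    assert row["mrs"] == pytest.approx(2 * 0.72 / 0.10)  # 14.4
    assert pw.mrs(MU[None, :], schema, coding).set_index("attribute").loc[
        "prednisone", "mrs"
    ] == pytest.approx(2 * 0.5 / 0.10)


def test_mrs_zero_aversion_and_scale_invariance(schema, coding):
    mu = MU.copy()
    mu[7] = 0.0
    t = pw.mrs(mu[None, :], schema, coding).set_index("attribute")
    assert t.loc["prednisone", "mrs"] == 0.0
    doubled = pw.mrs(2 * MU[None, :], schema, coding)
    base = pw.mrs(MU[None, :], schema, coding)
    np.testing.assert_allclose(doubled["mrs"], base["mrs"])


def test_mrs_matches_grid_search_oracle(schema, coding):
    """Grid search for the remission increase equating two profiles' utilities."""
    table = pw.mrs(MU[None, :], schema, coding)
    slope = MU[0]
    for _, row in table.iterrows():
        ai = schema.index(row["attribute"])
        cols = coding.columns[ai]
        beta_level = MU[cols[0]]
        # profile P1 carries the disliked level (+1 coding), P0 the preferred (-1);
        # find the remission increase r that equates total utilities on a 0.01 grid
        grid = np.arange(0.0, 60.0, 0.01)
        gap = np.abs((grid * slope) - (-2 * beta_level))
        r_star = grid[gap.argmin()]
        assert abs(row["mrs"] - r_star) <= 0.01


def test_ri_and_mrs_invariant_to_positive_rescaling(schema, coding):
    draws = _draws(50, sd=0.05, seed=12)
    scale = 3.7
    ri_a = pw.relative_importance(draws, schema, coding)
    ri_b = pw.relative_importance(scale * draws, schema, coding)
    np.testing.assert_allclose(ri_a["importance"], ri_b["importance"], atol=1e-10)
    mrs_a = pw.mrs(draws, schema, coding)
    mrs_b = pw.mrs(scale * draws, schema, coding)
    np.testing.assert_allclose(mrs_a["mrs"], mrs_b["mrs"], atol=1e-10)


def test_unstable_benefit_slope_warns(schema, coding):
    rng = np.random.default_rng(1)
    draws = _draws(200, sd=0.01, seed=2)
    draws[:, 0] = rng.normal(0.0, 0.05, size=200)  # slope straddles zero
    with pytest.warns(RuntimeWarning, match="slope"):
        pw.mrs(draws, schema, coding)


def test_empty_posterior_rejected(schema, coding):
    with pytest.raises(ValueError, match="draws"):
        pw.scale_utilities(np.zeros((0, 10)), schema, coding)
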