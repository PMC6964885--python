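import dataclasses
import logging

import numpy as np
import pytest
import partworth as pw


@pytest.fixture(scope="module")
def profiles():
    return pw.crohn_treatment_profiles()


def _beta_bank(col_values: dict, n_draws=50, n_pat=20, p=10):
    bank = np.zeros((n_draws, n_pat, p))
    for col, val in col_values.items():
        bank[..., col] = val
    return bank


def test_outcome_distribution_logit_arithmetic():
    """Median 0.5 with CrI (0.269, 0.731) -> log-odds mean 0, sd ~ 0.5102."""
    d = pw.fit_outcome_distribution(0.5, 0.269, 0.731)
    assert d.mean_logodds == pytest.approx(0.0, abs=1e-12)
    assert d.sd_logodds == pytest.approx(0.5102, abs=1e-3)
    rng = np.random.default_rng(0)
    samples = d.sample(rng, size=100_000)
    assert abs(np.median(samples) - 0.5) < 0.01


def test_degenerate_interval_is_point_mass():
    d = pw.fit_outcome_distribution(0.4, 0.4, 0.4)
    assert d.sd_logodds == 0.0
    assert (d.sample(np.random.default_rng(1), size=100) == 0.4).all()


def test_interval_ordering_enforced():
    with pytest.raises(ValueError):
        pw.fit_outcome_distribution(0.5, 0.6, 0.7)
    with pytest.raises(ValueError):
        pw.fit_outcome_distribution(1.0, 0.5, 1.0)


def test_published_remission_interval_coverage(profiles):
    """Infliximab remission 48% (33-64): ~95% of samples inside the interval."""
    inflix = profiles[0]
    rng = np.random.default_rng(2)
    s = inflix.remission.sample(rng, size=100_000)
    inside = np.mean((s > 0.33) & (s < 0.64))
    assert abs(inside - 0.95) < 0.01
    assert abs(np.median(s) - 0.48) < 0.005


def test_profile_utility_identities(profiles, schema, coding):
    outcomes = {"remission": 50.0, "wdae": 15.5}
    assert pw.profile_utility(profiles[0], np.zeros(10), outcomes, coding) == 0.0
    # two profiles differing only in the infection/cancer flag differ by 2*beta
    beta = np.zeros(10)
    beta[9] = -0.7
    flipped = dataclasses.replace(profiles[0], infection_cancer="No")
    u_yes = pw.profile_utility(profiles[0], beta, outcomes, coding)
    u_no = pw.profile_utility(flipped, beta, outcomes, coding)
    assert u_no - u_yes == pytest.approx(-2 * beta[9])


def test_profile_utility_hand_computed(profiles, schema, coding):
    """Spreadsheet-style sum for adalimumab at fixed outcomes and beta."""
    beta = np.array([0.1, -0.05, 0.2, 0.1, -0.1, 0.05, -0.15, -0.3, -0.2, -0.6])
    outcomes = {"remission": 61.0, "wdae": 2.3}
    # adalimumab: injection q2w (4th dosing level -> column 6 of the 5 effects
    # columns is index 2+3), prednisone Yes, blood/liver No, infection/cancer Yes
    expected = (
        0.1 * (61.0 - 50.0)
        + (-0.05) * (2.3 - 15.5)
        + beta[2 + 3]  # dosing level index 3
        + (-0.3) * (+1)  # prednisone Yes
        + (-0.2) * (-1)  # blood/liver No
        + (-0.6) * (+1)  # infection/cancer Yes
    )
    got = pw.profile_utility(profiles[2], beta, outcomes, coding)
    assert got == pytest.approx(expected, abs=1e-12)


def test_identical_profiles_split_evenly(profiles):
    twin = dataclasses.replace(profiles[0], name="twin")
    bank = _beta_bank({0: 0.1})
    res = pw.simulate_menu([profiles[0], twin], bank, n_draws=8000, seed=5)
    assert abs(res.mean_probs["infliximab"] - 0.5) < 0.03
    np.testing.assert_allclose(res.patient_probs.sum(axis=1), 1.0)


def test_pure_risk_aversion_forces_vedolizumab(profiles):
    """Only vedolizumab avoids the infection/cancer risk."""
    bank = _beta_bank({9: -1.0})
    res = pw.simulate_menu(profiles, bank, n_draws=400, seed=6)
    assert res.mean_probs["vedolizumab"] == 1.0
    assert (res.modal_treatment == "vedolizumab").all()


def test_pure_benefit_with_point_outcomes_forces_highest_remission(profiles):
    a = dataclasses.replace(
        profiles[0], name="high", remission=pw.fit_outcome_distribution(0.63, 0.63, 0.63)
    )
    b = dataclasses.replace(
        profiles[0], name="low", remission=pw.fit_outcome_distribution(0.36, 0.36, 0.36)
    )
    bank = _beta_bank({0: 0.1})
    res = pw.simulate_menu([a, b], bank, n_draws=400, seed=7)
    assert res.mean_probs["high"] == 1.0


def test_menu_probabilities_and_modal_shares_normalised(profiles):
    rng = np.random.default_rng(8)
    bank = rng.normal(0, 0.2, size=(40, 15, 10))
    bank[..., 0] = np.abs(bank[..., 0])
    res = pw.simulate_menu(profiles, bank, n_draws=2000, seed=9)
    np.testing.assert_allclose(res.patient_probs.sum(axis=1), 1.0)
    assert res.modal_shares.sum() == pytest.approx(1.0)


def test_pairwise_matrix_complementarity(profiles):
    bank = _beta_bank({0: 0.08, 9: -0.5})
    mat = pw.simulate_pairs(profiles, bank, n_draws=1500, seed=10)
    arr = mat.to_numpy()
    off = ~np.eye(len(arr), dtype=bool)
    np.testing.assert_allclose((arr + arr.T)[off], 1.0, atol=1e-12)
    assert np.isnan(np.diag(arr)).all()


def test_pair_ordering_symmetry(profiles):
    """P(A over B) from the (A,B) menu ~ 1 - P(B over A) from (B,A)."""
    bank = _beta_bank({0: 0.05})
    ab = pw.simulate_menu([profiles[0], profiles[4]], bank, n_draws=6000, seed=11)
    ba = pw.simulate_menu([profiles[4], profiles[0]], bank, n_draws=6000, seed=12)
    p1 = float(ab.mean_probs["infliximab"])
    p2 = 1.0 - float(ba.mean_probs["azathioprine"])
    assert abs(p1 - p2) < 0.03


def test_constant_utility_shift_leaves_preferences_unchanged(profiles):
    """Adding a common part-worth to all profiles cannot change choices."""
    bank = _beta_bank({0: 0.05, 9: -0.3})
    base = pw.simulate_menu(profiles, bank, n_draws=1500, seed=13)
    # prednisone is "Yes" for every base profile, so its part-worth is a
    # constant shift across the menu
    bank2 = bank.copy()
    bank2[..., 7] = -5.0
    shifted = pw.simulate_menu(profiles, bank2, n_draws=1500, seed=13)
    np.testing.assert_allclose(
        base.patient_probs.to_numpy(), shifted.patient_probs.to_numpy()
    )


def test_remission_stochastic_dominance_is_monotone(profiles):
    """Shifting a profile's remission distribution up can't hurt it."""
    bank = _beta_bank({0: 0.08})
    lo = dataclasses.replace(
        profiles[0], name="lo", remission=pw.fit_outcome_distribution(0.40, 0.30, 0.51)
    )
    hi = dataclasses.replace(
        profiles[0], name="hi", remission=pw.fit_outcome_distribution(0.55, 0.44, 0.66)
    )
    comparator = profiles[4]
    p_lo = pw.simulate_menu([lo, comparator], bank, n_draws=4000, seed=14)
    p_hi = pw.simulate_menu([hi, comparator], bank, n_draws=4000, seed=14)
    assert float(p_hi.mean_probs["hi"]) >= float(p_lo.mean_probs["lo"]) - 0.02


def test_sensitivity_scenarios(profiles):
    base = pw.apply_sensitivity(profiles, "base")
    assert base == profiles
    no_pred = pw.apply_sensitivity(profiles, "no_prednisone_biologics")
    assert sum(a != b for a, b in zip(profiles, no_pred)) == 4
    assert all(
        p.prednisone == "No"
        for p in no_pred
        if p.name in ("infliximab", "infliximab_azathioprine", "adalimumab", "vedolizumab")
    )
    tnf = pw.apply_sensitivity(profiles, "antitnf_blood_liver")
    assert sum(a != b for a, b in zip(profiles, tnf)) == 2
    with pytest.raises(ValueError, match="unknown scenario"):
        pw.apply_sensitivity(profiles, "bogus")


def test_extrapolation_logged_and_clamp_mode(profiles, caplog, schema, coding):
    """Methotrexate's WDAE median (38%) exceeds the 30% design maximum."""
    bank = _beta_bank({1: -0.05})
    with caplog.at_level(logging.WARNING, logger="partworth.scenarios"):
        res = pw.simulate_menu([profiles[5], profiles[4]], bank, n_draws=300, seed=15)
    assert res.n_extrapolated > 0
    assert any("outside the designed range" in r.message for r in caplog.records)
    clamped = pw.simulate_menu(
        [profiles[5], profiles[4]], bank, n_draws=300, seed=15, extrapolation="clamp"
    )
    assert clamped.patient_probs.shape == res.patient_probs.shape


def test_small_draw_count_warns(profiles):
    bank = _beta_bank({0: 0.1})
    with pytest.warns(RuntimeWarning, match="unstable"):
        pw.simulate_menu(profiles[:2], bank, n_draws=50, seed=16)
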