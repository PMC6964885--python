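from math import comb

import numpy as np
import pytest

import partworth as pw


def _cohort(design, coding, n=40, seed=500, **inject):
    mu = 5 * np.array([0.10, -0.04, 0.05, 0.0, -0.05, 0.03, 0.02, -0.5, -0.4, -0.6])
    sigma = np.diag(np.full(10, 0.01**2))
    spec = pw.PopulationSpec(n, (pw.ClassSpec(1.0, mu, sigma),), **inject)
    prefs = pw.simulate_population(spec, seed=seed)
    choices = pw.simulate_choices(design, prefs, coding, seed=seed + 1)
    return prefs, choices


def test_dominated_task_pass_and_fail(small_design):
    dom = np.array([w.dominated for w in small_design.warmups])
    ok = (dom + 1) % 3
    choices = pw.RespondentChoices(
        respondent_ids=["fails", "passes", "missing"],
        versions=np.zeros(3, dtype=int),
        choices=np.zeros((3, 13), dtype=int),
        warmup_choices=np.array([[dom[0], ok[1]], [ok[0], ok[1]], [-1, ok[1]]]),
    )
    rep = pw.check_dominated(small_design, choices)
    assert rep["status"].tolist() == ["fail", "pass", "na"]


def test_rational_cohort_never_fails_warmups(small_design, coding):
    """Strong, well-behaved preferences never pick the dominated option."""
    _, choices = _cohort(small_design, coding, n=60)
    rep = pw.validity_report(choices, small_design)
    assert rep.failure_rate == 0.0


def test_injected_pathologies_are_recalled_perfectly(small_design, coding):
    prefs, choices = _cohort(
        small_design, coding, n=30,
        n_straightliners=3, n_attribute_dominant={"remission": 2, "prednisone": 2},
    )
    positions = pw.position_profile(choices)
    dominance = pw.attribute_dominance(choices, small_design)
    for i, b in enumerate(prefs.behaviors):
        if b.startswith("straightline"):
            assert positions["straightline"].iloc[i]
        elif b.startswith("dominant:"):
            assert b.split(":", 1)[1] in dominance["dominant_attributes"].iloc[i]


def test_position_shares_recount(small_design, coding):
    _, choices = _cohort(small_design, coding, n=25)
    rep = pw.validity_report(choices, small_design)
    np.testing.assert_allclose(rep.position_shares.sum(), 1.0)
    manual = np.bincount(choices.choices.ravel(), minlength=3) / choices.choices.size
    np.testing.assert_allclose(rep.position_shares, manual)


def _exact_straightline_probability(n_tasks=13, threshold=9):
    """P(max trinomial count > threshold) by enumeration over all outcomes."""
    total = 0.0
    for a in range(n_tasks + 1):
        for b in range(n_tasks - a + 1):
            c = n_tasks - a - b
            if max(a, b, c) > threshold:
                total += comb(n_tasks, a) * comb(n_tasks - a, b) / 3**n_tasks
    return total


def test_random_chooser_straightline_rate_matches_enumeration(small_design):
    """Monte-Carlo flag rate agrees with the exact 3^13 trinomial probability."""
    p_exact = _exact_straightline_probability()
    n = 40_000
    rng = np.random.default_rng(903)
    choices = pw.RespondentChoices(
        respondent_ids=[f"r{i}" for i in range(n)],
        versions=np.zeros(n, dtype=int),
        choices=rng.integers(3, size=(n, 13)),
    )
    flagged = pw.position_profile(choices)["straightline"].mean()
    se = np.sqrt(p_exact * (1 - p_exact) / n)
    assert abs(flagged - p_exact) < 4 * se + 1e-6


def test_random_chooser_dominance_rate_matches_enumeration(small_design, coding, schema):
    """beta=0 choosers attain per-task best levels at the enumerated rate."""
    ai = schema.index("remission")
    a = schema[ai]
    version = 0
    p_exact = 1.0
    for t in range(small_design.n_tasks):
        ranks = np.array(
            [a.level_rank(int(li)) for li in small_design.cells[version, t, :, ai]]
        )
        p_exact *= np.mean(ranks == ranks.max())
    n = 30_000
    rng = np.random.default_rng(904)
    choices = pw.RespondentChoices(
        respondent_ids=[f"r{i}" for i in range(n)],
        versions=np.zeros(n, dtype=int),
        choices=rng.integers(3, size=(n, 13)),
    )
    dom = pw.attribute_dominance(choices, small_design)
    rate = np.mean([("remission" in row) for row in dom["dominant_attributes"]])
    se = np.sqrt(p_exact * (1 - p_exact) / n)
    assert abs(rate - p_exact) < 4 * se + 1e-6


def test_dominance_is_monotone_in_tasks(small_design, coding):
    """Restricting to fewer tasks can only add dominant respondents."""
    _, choices = _cohort(small_design, coding, n=20, seed=905)
    full = pw.attribute_dominance(choices, small_design)
    truncated_design = pw.ChoiceDesign(
        schema=small_design.schema, cells=small_design.cells[:, :6], warmups=small_design.warmups
    )
    truncated = pw.RespondentChoices(
        respondent_ids=choices.respondent_ids,
        versions=choices.versions,
        choices=choices.choices[:, :6],
    )
    part = pw.attribute_dominance(truncated, truncated_design)
    for f, p in zip(full["dominant_attributes"], part["dominant_attributes"]):
        assert set(f) <= set(p)


def test_dosing_never_evaluated_for_dominance(small_design, coding):
    _, choices = _cohort(small_design, coding, n=10, seed=906)
    dom = pw.attribute_dominance(choices, small_design)
    for row in dom["dominant_attributes"]:
        assert "dosing" not in row
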