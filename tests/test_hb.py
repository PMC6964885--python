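import numpy as np
import pytest

import partworth as pw
from partworth.hb import mnl_loglik


def test_indifference_loglik_is_uniform():
    """beta = 0 over 13 tasks x 3 alternatives gives 13 * log(1/3)."""
    rng = np.random.default_rng(0)
    tasks = rng.normal(size=(13, 3, 4))
    ll = mnl_loglik(np.zeros(4), tasks, np.zeros(13, dtype=int))
    assert ll == pytest.approx(13 * np.log(1 / 3), abs=1e-12)


def test_loglik_matches_probability_enumeration():
    """Random toys: log-likelihood equals naive per-task probability products."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        tasks = rng.normal(size=(2, 3, 5))
        beta = rng.normal(size=5)
        chosen = rng.integers(3, size=2)
        expected = 0.0
        for t in range(2):
            u = np.exp(tasks[t] @ beta)
            expected += np.log(u[chosen[t]] / u.sum())
        assert mnl_loglik(beta, tasks, chosen) == pytest.approx(expected, abs=1e-10)


def test_loglik_invariant_to_utility_translation():
    rng = np.random.default_rng(1)
    tasks = rng.normal(size=(4, 3, 6))
    beta = rng.normal(size=6)
    chosen = rng.integers(3, size=4)
    base = mnl_loglik(beta, tasks, chosen)
    # shifting every alternative in a task by the same covariate row adds a
    # common constant to all utilities and must leave the likelihood unchanged
    shift = rng.normal(size=(4, 1, 6))
    assert mnl_loglik(beta, tasks + shift, chosen) == pytest.approx(base, abs=1e-9)


def test_nonfinite_beta_rejected():
    with pytest.raises(ValueError, match="finite"):
        mnl_loglik(np.array([np.nan]), np.zeros((1, 2, 1)), np.zeros(1, dtype=int))


@pytest.fixture(scope="module")
def small_fit(small_design, coding, logit_cohort):
    _, choices = logit_cohort
    settings = pw.MCMCSettings(n_chains=2, n_burnin=300, n_monitor=600, thin=3, seed=31)
    return pw.fit_hb(choices, small_design, coding, settings)


def test_fit_is_deterministic(small_design, coding, logit_cohort, small_fit):
    _, choices = logit_cohort
    settings = pw.MCMCSettings(n_chains=2, n_burnin=300, n_monitor=600, thin=3, seed=31)
    again = pw.fit_hb(choices, small_design, coding, settings)
    np.testing.assert_array_equal(small_fit.mu, again.mu)
    np.testing.assert_array_equal(small_fit.beta, again.beta)


def test_draw_counts_and_sigma_positive_definite(small_fit):
    assert small_fit.n_draws == 600 // 3
    sig = small_fit.sigma.reshape(-1, small_fit.p, small_fit.p)
    for m in sig[::17]:
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        assert np.linalg.eigvalsh(m).min() > 0


def test_identical_respondents_are_exchangeable(small_design, coding):
    """Two clones of the same choice record get matching posteriors."""
    rng = np.random.default_rng(3)
    row = rng.integers(3, size=13)
    choices = pw.RespondentChoices(
        respondent_ids=["a", "b", "c", "d"],
        versions=np.zeros(4, dtype=int),
        choices=np.tile(row, (4, 1)),
    )
    settings = pw.MCMCSettings(n_chains=2, n_burnin=400, n_monitor=1200, thin=2, seed=5)
    post = pw.fit_hb(choices, small_design, coding, settings)
    meds = np.median(post.beta_draws(), axis=0)  # (4, p)
    spread = np.abs(meds - meds.mean(axis=0)).max()
    assert spread < 0.35  # Monte-Carlo error band for identical records


def test_posterior_recovers_population_mean(small_fit, logit_cohort):
    prefs, _ = logit_cohort
    mu_true = prefs.betas.mean(axis=0)
    mu_est = np.median(small_fit.mu_draws(), axis=0)
    r = np.corrcoef(mu_true, mu_est)[0, 1]
    # loose bar: 40 respondents and a few hundred draws; the full-scale
    # recovery check runs in the acceptance suite
    assert r > 0.8


def test_interval_width_shrinks_with_more_respondents(schema, coding):
    """Posterior for the population mean contracts as the cohort doubles."""
    mu = np.array([0.08, -0.04, 0.05, 0.0, -0.05, 0.03, 0.02, -0.4, -0.3, -0.5])
    sigma = np.diag(np.full(10, 0.05**2))
    design = pw.generate_design(schema, n_versions=5, n_tasks=13, n_alts=3, seed=61)
    widths = []
    for n in (25, 100):
        spec = pw.PopulationSpec(n, (pw.ClassSpec(1.0, mu, sigma),))
        prefs = pw.simulate_population(spec, seed=62)
        choices = pw.simulate_choices(design, prefs, coding, seed=63)
        settings = pw.MCMCSettings(
            n_chains=2, n_burnin=400, n_monitor=800, thin=4, seed=64
        )
        post = pw.fit_hb(choices, design, coding, settings)
        draws = post.mu_draws()
        widths.append(
            np.mean(np.percentile(draws, 97.5, axis=0) - np.percentile(draws, 2.5, axis=0))
        )
    assert widths[1] < widths[0]


def test_settings_validation():
    with pytest.raises(ValueError, match="chains"):
        pw.MCMCSettings(n_chains=1)
    with pytest.raises(ValueError, match="positive"):
        pw.MCMCSettings(n_burnin=0)
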