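"""Preference-weighted treatment ranking from network-meta-analysis outputs.

Each candidate maintenance therapy is a :class:`TreatmentProfile`: two
stochastic outcomes — probability of maintaining remission at 1 year and
probability of withdrawal due to adverse events (WDAE) — published as
median (95% CrI) from a network meta-analysis, plus fixed dosing and risk
attributes.  The published interval summaries are reconstructed as normal
distributions on the log-odds scale, which respects the (0, 1) support and
the asymmetry of the printed intervals.

The simulation fuses these outcome distributions with part-worth posteriors:
in each of ``n_draws`` iterations one shared outcome draw is taken per
treatment and each patient applies an own posterior part-worth draw, choosing
the treatment with the highest total utility.  Averaging over iterations
gives per-patient choice probabilities, cohort first-choice shares and
pairwise preference probabilities.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .hb import HBPosterior
from .schema import AttributeSchema, CodingMap, crohn_schema

__all__ = [
    "OutcomeDistribution",
    "TreatmentProfile",
    "PreferenceSimResult",
    "fit_outcome_distribution",
    "profile_utility",
    "simulate_menu",
    "simulate_pairs",
    "apply_sensitivity",
    "crohn_treatment_profiles",
    "SCENARIOS",
]

logger = logging.getLogger(__name__)

_Z975 = 1.959964


@dataclass(frozen=True)
class OutcomeDistribution:
    """Probability outcome summarised as median (95% CrI), sampled logit-normal."""

    median: float
    lo: float
    hi: float
    mean_logodds: float
    sd_logodds: float

    def sample(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Draws on the probability scale."""
        if self.sd_logodds == 0.0:
            return np.full(size if size is not None else (), self.median)
        return expit(rng.normal(self.mean_logodds, self.sd_logodds, size=size))


def fit_outcome_distribution(median: float, lo: float, hi: float) -> OutcomeDistribution:
    """Reconstruct a sampler from a printed median and 95% credible interval.

    Normal on the log-odds scale: mean = logit(median),
    sd = (logit(hi) - logit(lo)) / (2 * 1.959964).  A degenerate interval
    (lo = median = hi) gives a point mass.
    """
    if not (0.0 < lo <= median <= hi < 1.0):
        raise ValueError("need 0 < lo <= median <= hi < 1")
    sd = (logit(hi) - logit(lo)) / (2.0 * _Z975)
    return OutcomeDistribution(
        median=median, lo=lo, hi=hi, mean_logodds=float(logit(median)), sd_logodds=float(sd)
    )


@dataclass(frozen=True)
class TreatmentProfile:
    """A treatment's outcome distributions plus fixed attribute levels."""

    name: str
    remission: OutcomeDistribution
    wdae: OutcomeDistribution
    dosing: str
    prednisone: str  # "Yes" / "No"
    blood_liver: str
    infection_cancer: str


def crohn_treatment_profiles() -> list[TreatmentProfile]:
    """The six maintenance therapies with their published NMA summaries.

    Remission and WDAE are median (95% CrI) probabilities; the categorical
    attributes are the base-case assignments (sensitivity variants are
    produced by :func:`apply_sensitivity`).
    """
    f = fit_outcome_distribution
    return [
        TreatmentProfile(
            "infliximab", f(0.48, 0.33, 0.64), f(0.12, 0.063, 0.25),
            "IV infusion every 8 weeks", "Yes", "No", "Yes",
        ),
        TreatmentProfile(
            "infliximab_azathioprine", f(0.63, 0.44, 0.80), f(0.12, 0.045, 0.27),
            "daily tablets + IV infusion every 8 weeks", "Yes", "Yes", "Yes",
        ),
        TreatmentProfile(
            "adalimumab", f(0.61, 0.46, 0.75), f(0.023, 0.012, 0.042),
            "injection every 2 weeks", "Yes", "No", "Yes",
        ),
        TreatmentProfile(
            "vedolizumab", f(0.41, 0.27, 0.57), f(0.030, 0.014, 0.061),
            "IV infusion every 8 weeks", "Yes", "No", "No",
        ),
        TreatmentProfile(
            "azathioprine", f(0.36, 0.24, 0.49), f(0.15, 0.079, 0.26),
            "daily tablets", "Yes", "Yes", "Yes",
        ),
        TreatmentProfile(
            "methotrexate", f(0.42, 0.25, 0.61), f(0.38, 0.12, 0.83),
            "weekly injection", "Yes", "Yes", "Yes",
        ),
    ]


_BIOLOGICS = ("infliximab", "infliximab_azathioprine", "adalimumab", "vedolizumab")
_ANTI_TNF = ("infliximab", "adalimumab")

SCENARIOS = ("base", "no_prednisone_biologics", "antitnf_blood_liver")


def apply_sensitivity(
    profiles: list[TreatmentProfile], scenario: str
) -> list[TreatmentProfile]:
    """Return profiles under a named sensitivity scenario.

    ``no_prednisone_biologics`` drops the initial prednisone course for the
    four biologic-based therapies; ``antitnf_blood_liver`` adds the blood
    count / liver reaction risk to the two anti-TNF agents; ``base`` returns
    the profiles unchanged.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {SCENARIOS}")
    if scenario == "base":
        return list(profiles)
    out = []
    for pr in profiles:
        if scenario == "no_prednisone_biologics" and pr.name in _BIOLOGICS:
            pr = dataclasses.replace(pr, prednisone="No")
        elif scenario == "antitnf_blood_liver" and pr.name in _ANTI_TNF:
            pr = dataclasses.replace(pr, blood_liver="Yes")
        out.append(pr)
    return out


def _profile_covariates(
    profiles: list[TreatmentProfile],
    rem_pct: np.ndarray,
    wdae_pct: np.ndarray,
    schema: AttributeSchema,
    coding: CodingMap,
    extrapolation: str,
) -> np.ndarray:
    """Coded covariate rows (n_treat, p) given sampled outcome percentages."""
    ai_rem, ai_wdae = schema.index("remission"), schema.index("wdae")
    ai_dos = schema.index("dosing")
    rem_att, wdae_att = schema[ai_rem], schema[ai_wdae]
    if extrapolation == "clamp":
        rem_pct = np.clip(rem_pct, min(rem_att.levels), max(rem_att.levels))
        wdae_pct = np.clip(wdae_pct, min(wdae_att.levels), max(wdae_att.levels))
    X = np.zeros((len(profiles), coding.n_columns))
    X[:, coding.columns[ai_rem][0]] = rem_pct - rem_att.center
    X[:, coding.columns[ai_wdae][0]] = wdae_pct - wdae_att.center
    for j, pr in enumerate(profiles):
        dos_li = list(schema[ai_dos].levels).index(pr.dosing)
        cols = coding.columns[ai_dos]
        if dos_li < len(cols):
            X[j, cols[dos_li]] = 1.0
        else:
            X[j, list(cols)] = -1.0
        for attr, val in (
            ("prednisone", pr.prednisone),
            ("blood_liver", pr.blood_liver),
            ("infection_cancer", pr.infection_cancer),
        ):
            ai = schema.index(attr)
            li = list(schema[ai].levels).index(val)
            X[j, coding.columns[ai][0]] = 1.0 if li == 0 else -1.0
    return X


def profile_utility(
    profile: TreatmentProfile,
    beta: np.ndarray,
    sampled_outcomes: dict,
    coding: CodingMap,
    schema: AttributeSchema | None = None,
    extrapolation: str = "allow",
) -> float:
    """Total utility of one profile: sum of its attribute part-utilities.

    ``sampled_outcomes`` carries ``remission`` and ``wdae`` in percentage
    points.  Outcomes beyond the designed attribute range are linearly
    extrapolated with a logged warning (or clamped with
    ``extrapolation="clamp"``).
    """
    schema = schema or crohn_schema()
    rem = float(sampled_outcomes["remission"])
    wd = float(sampled_outcomes["wdae"])
    _warn_extrapolation(schema, np.array([rem]), np.array([wd]))
    x = _profile_covariates(
        [profile], np.array([rem]), np.array([wd]), schema, coding, extrapolation
    )[0]
    return float(x @ np.asarray(beta, dtype=float))


def _warn_extrapolation(schema: AttributeSchema, rem_pct: np.ndarray, wdae_pct: np.ndarray) -> int:
    n_out = 0
    for name, vals in (("remission", rem_pct), ("wdae", wdae_pct)):
        a = schema[schema.index(name)]
        lo, hi = min(a.levels), max(a.levels)
        out = int(((vals < lo) | (vals > hi)).sum())
        if out:
            n_out += out
            logger.warning(
                "%d sampled %s values fall outside the designed range [%g, %g]; "
                "part-worths extrapolated linearly", out, name, lo, hi,
            )
    return n_out


@dataclass
class PreferenceSimResult:
    """Per-patient and cohort-level treatment preference probabilities."""

    treatments: list[str]
    patient_probs: pd.DataFrame  # (n_patients, n_treat) choice probabilities
    modal_treatment: pd.Series  # per patient
    modal_shares: pd.Series  # fraction of patients by modal treatment
    mean_probs: pd.Series  # cohort mean choice probabilities
    n_draws: int
    seed: int
    n_extrapolated: int = 0


def _beta_draw_bank(posterior) -> np.ndarray:
    """(n_draws_avail, n_patients, p) bank of part-worth draws."""
    if isinstance(posterior, HBPosterior):
        return posterior.beta_draws()
    arr = np.asarray(posterior, dtype=float)
    if arr.ndim != 3:
        raise ValueError("posterior must be HBPosterior or (draws, patients, p) array")
    return arr


def simulate_menu(
    profiles: list[TreatmentProfile],
    posterior,
    n_draws: int = 10_000,
    seed: int = 0,
    schema: AttributeSchema | None = None,
    coding: CodingMap | None = None,
    extrapolation: str = "allow",
    chunk: int = 1000,
) -> PreferenceSimResult:
    """Monte-Carlo first-choice simulation over a menu of treatments.

    Per iteration: one shared outcome draw per treatment (remission and WDAE
    sampled independently on the log-odds scale), one own posterior
    part-worth draw per patient; each patient picks the argmax-utility
    treatment, exact ties broken uniformly at random.  Deterministic given
    ``seed``.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 treatment profiles")
    if n_draws < 100:
        warnings.warn("n_draws < 100 gives unstable estimates", RuntimeWarning, stacklevel=2)
    schema = schema or crohn_schema()
    coding = coding or CodingMap.from_schema(schema)
    bank = _beta_draw_bank(posterior)
    n_avail, n_pat, p = bank.shape
    if p != coding.n_columns:
        raise ValueError("part-worth length does not match the coding map")
    rng = np.random.default_rng(seed)
    names = [pr.name for pr in profiles]
    n_treat = len(profiles)
    counts = np.zeros((n_pat, n_treat), dtype=np.int64)
    n_extrap = 0
    for start in range(0, n_draws, chunk):
        d = min(chunk, n_draws - start)
        rem = np.stack(
            [pr.remission.sample(rng, size=d) for pr in profiles], axis=1
        ) * 100.0  # (d, n_treat) percent
        wd = np.stack([pr.wdae.sample(rng, size=d) for pr in profiles], axis=1) * 100.0
        n_extrap += _warn_extrapolation(schema, rem, wd)
        X = np.stack(
            [
                _profile_covariates(profiles, rem[i], wd[i], schema, coding, extrapolation)
                for i in range(d)
            ]
        )  # (d, n_treat, p)
        idx = rng.integers(n_avail, size=(d, n_pat))
        B = bank[idx, np.arange(n_pat)[None, :], :]  # (d, n_pat, p)
        util = np.einsum("dnp,dtp->dnt", B, X)
        # uniform tie-break via a vanishing random jitter
        util = util + rng.random(util.shape) * 1e-9
        pick = util.argmax(axis=-1)  # (d, n_pat)
        for t in range(n_treat):
            counts[:, t] += (pick == t).sum(axis=0)
    probs = counts / n_draws
    patient_probs = pd.DataFrame(probs, columns=names)
    modal = patient_probs.idxmax(axis=1)
    modal_shares = modal.value_counts(normalize=True).reindex(names, fill_value=0.0)
    return PreferenceSimResult(
        treatments=names,
        patient_probs=patient_probs,
        modal_treatment=modal,
        modal_shares=modal_shares,
        mean_probs=patient_probs.mean(axis=0),
        n_draws=n_draws,
        seed=seed,
        n_extrapolated=n_extrap,
    )


def simulate_pairs(
    profiles: list[TreatmentProfile],
    posterior,
    n_draws: int = 10_000,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Pairwise preference matrix: P(row treatment preferred to column).

    Each unordered pair runs its own two-treatment menu simulation (seeded
    from the pair index), and P(B, A) = 1 - P(A, B) by construction, so the
    matrix constraint holds exactly.  Diagonal entries are NaN.
    """
    names = [pr.name for pr in profiles]
    mat = pd.DataFrame(np.full((len(names), len(names)), np.nan), index=names, columns=names)
    children = np.random.SeedSequence(seed).spawn(len(names) * (len(names) - 1) // 2)
    k = 0
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            sub_seed = int(children[k].generate_state(1)[0] & 0x7FFFFFFF)
            k += 1
            res = simulate_menu(
                [profiles[i], profiles[j]], posterior, n_draws=n_draws, seed=sub_seed, **kwargs
            )
            p_ij = float(res.mean_probs.iloc[0])
            mat.iloc[i, j] = p_ij
            mat.iloc[j, i] = 1.0 - p_ij
    return mat
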