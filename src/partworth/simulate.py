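"""Synthetic respondent populations with known preference structure.

The generator draws individual part-worth vectors from a finite mixture of
multivariate normals — exactly the population structure the hierarchical
model and the latent-class mixture assume — and simulates multinomial-logit
choices on a given design.  Pathological respondents (straight-liners and
single-attribute-dominant choosers) can be injected to exercise the validity
detectors, which must recall them perfectly by construction.

The default two-class population mirrors the qualitative structure found in
the Crohn's disease cohort this package models: a 55% benefit-driven class
with a steep remission slope, and a 45% risk-averse class with strong
aversions to prednisone and to the rare infection/cancer risk.  The
magnitudes are package choices for realistic fixtures, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import RespondentChoices
from .design import ChoiceDesign
from .schema import CodingMap, crohn_schema

__all__ = [
    "ClassSpec",
    "PopulationSpec",
    "TruePreferences",
    "simulate_population",
    "simulate_choices",
    "crohn_population",
]


@dataclass(frozen=True)
class ClassSpec:
    share: float
    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be p x p")
        if not np.allclose(self.sigma, self.sigma.T):
            raise ValueError("sigma must be symmetric")
        eig = np.linalg.eigvalsh(self.sigma)
        if eig.min() < -1e-10:
            raise ValueError("sigma must be positive semi-definite")


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture population plus counts of injected pathological respondents."""

    n_respondents: int
    classes: tuple[ClassSpec, ...]
    n_straightliners: int = 0
    n_attribute_dominant: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("need at least one respondent")
        shares = [c.share for c in self.classes]
        if abs(sum(shares) - 1.0) > 1e-8:
            raise ValueError("class shares must sum to 1")
        n_inject = self.n_straightliners + sum(self.n_attribute_dominant.values())
        if n_inject > self.n_respondents:
            raise ValueError("more injected respondents than respondents")


@dataclass
class TruePreferences:
    """Ground truth: class labels, true part-worths, behavioural types."""

    betas: np.ndarray  # (n_resp, p)
    class_labels: np.ndarray  # (n_resp,)
    behaviors: list[str]  # "logit" | "straightline:<pos>" | "dominant:<attr>"

    @property
    def n_respondents(self) -> int:
        return self.betas.shape[0]


def simulate_population(spec: PopulationSpec, seed: int = 0) -> TruePreferences:
    """Draw respondents: class by share, part-worths from the class normal.

    The first injected respondents (in id order) are relabelled as
    straight-liners and attribute-dominant choosers; their beta vectors are
    kept so recovery tests can still compare against them.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_respondents
    shares = np.array([c.share for c in spec.classes])
    labels = rng.choice(len(spec.classes), size=n, p=shares)
    p = spec.classes[0].mu.size
    betas = np.empty((n, p))
    for k, c in enumerate(spec.classes):
        idx = np.where(labels == k)[0]
        if idx.size:
            betas[idx] = rng.multivariate_normal(
                c.mu, c.sigma, size=idx.size, method="eigh"
            )
    behaviors = ["logit"] * n
    positions = ("left", "middle", "right")
    i = 0
    for s in range(spec.n_straightliners):
        behaviors[i] = f"straightline:{positions[s % 3]}"
        i += 1
    for attr, count in spec.n_attribute_dominant.items():
        for _ in range(count):
            behaviors[i] = f"dominant:{attr}"
            i += 1
    return TruePreferences(betas=betas, class_labels=labels, behaviors=behaviors)


def choice_probabilities(utilities: np.ndarray) -> np.ndarray:
    """Softmax over the last axis with the usual overflow guard."""
    u = utilities - utilities.max(axis=-1, keepdims=True)
    e = np.exp(u)
    return e / e.sum(axis=-1, keepdims=True)


def simulate_choices(
    design: ChoiceDesign,
    prefs: TruePreferences,
    coding: CodingMap,
    seed: int = 0,
) -> RespondentChoices:
    """Simulate every respondent's main-task and warm-up answers.

    Logit respondents choose alternative ``j`` with probability
    ``exp(x_j' beta_i) / sum_k exp(x_k' beta_i)``; straight-liners always pick
    their fixed screen position; dominant respondents always pick the
    alternative with the best available level of their attribute, breaking
    ties at random from the same stream.  Versions are assigned uniformly at
    random.
    """
    if coding.n_columns != prefs.betas.shape[1]:
        raise ValueError("part-worth length does not match the coding map")
    rng = np.random.default_rng(seed)
    n = prefs.n_respondents
    versions = rng.integers(design.n_versions, size=n)
    coded = coding.code_design(design.cells)  # (V, T, A, p)
    choices = np.empty((n, design.n_tasks), dtype=np.int64)
    n_w = design.n_warmups
    warm = np.full((n, n_w), -1, dtype=np.int64) if n_w else None
    warm_cells = (
        np.stack([w.cells for w in design.warmups]) if n_w else None
    )  # (W, A, n_attrs)
    warm_coded = coding.code_design(warm_cells) if n_w else None
    pos_index = {"left": 0, "middle": 1, "right": 2}
    for i in range(n):
        v = int(versions[i])
        behavior = prefs.behaviors[i]
        if behavior.startswith("straightline:"):
            pos = pos_index[behavior.split(":", 1)[1]]
            choices[i] = min(pos, design.n_alts - 1)
            if n_w:
                warm[i] = min(pos, design.n_alts - 1)
        elif behavior.startswith("dominant:"):
            attr = behavior.split(":", 1)[1]
            ai = design.schema.index(attr)
            choices[i] = _dominant_choices(design.cells[v], design.schema, ai, rng)
            if n_w:
                warm[i] = _dominant_choices(warm_cells, design.schema, ai, rng)
        else:
            u = coded[v] @ prefs.betas[i]  # (T, A)
            choices[i] = _sample_rows(choice_probabilities(u), rng)
            if n_w:
                uw = warm_coded @ prefs.betas[i]
                warm[i] = _sample_rows(choice_probabilities(uw), rng)
    return RespondentChoices(
        respondent_ids=[f"r{i:04d}" for i in range(n)],
        versions=versions,
        choices=choices,
        warmup_choices=warm,
    )


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = probs.cumsum(axis=-1)
    u = rng.random(probs.shape[:-1] + (1,))
    return (u > cum[..., :-1]).sum(axis=-1).astype(np.int64)


def _dominant_choices(
    task_cells: np.ndarray, schema, attr_index: int, rng: np.random.Generator
) -> np.ndarray:
    """Pick the alternative with the best available level of one attribute."""
    a = schema[attr_index]
    out = np.empty(task_cells.shape[0], dtype=np.int64)
    for t in range(task_cells.shape[0]):
        ranks = np.array(
            [a.level_rank(int(li)) for li in task_cells[t, :, attr_index]]
        )
        best = np.where(ranks == ranks.max())[0]
        out[t] = best[0] if best.size == 1 else rng.choice(best)
    return out


def crohn_population(
    n_respondents: int = 155,
    n_straightliners: int = 0,
    n_attribute_dominant: dict | None = None,
    heterogeneity: float = 1.0,
) -> PopulationSpec:
    """Default two-class synthetic cohort (55% benefit-driven, 45% risk-averse).

    Part-worths are on the coded scale of :func:`~partworth.schema.crohn_schema`:
    linear slopes per percentage point, effects-coded columns for dosing and
    the binary risks.  The benefit-driven class trades roughly 4 remission
    points against the infection/cancer risk; the risk-averse class requires
    tens of points, so the mixture average lands in the low teens —
    a realistic benefit-risk trade-off for this disease area.
    ``heterogeneity`` scales the within-class standard deviations.
    """
    # columns: rem, wdae, dosing(5), prednisone, blood_liver, infection_cancer
    mu_benefit = np.array(
        [0.10, -0.040, 0.05, 0.00, -0.05, 0.03, 0.02, -0.15, -0.15, -0.20]
    )
    mu_risk = np.array(
        [0.030, -0.050, 0.05, 0.00, -0.05, 0.03, 0.02, -0.90, -0.45, -1.00]
    )
    sd = heterogeneity * np.array(
        [0.03, 0.015, 0.10, 0.10, 0.10, 0.10, 0.10, 0.25, 0.20, 0.30]
    )
    sigma = np.diag(sd**2)
    return PopulationSpec(
        n_respondents=n_respondents,
        classes=(
            ClassSpec(0.55, mu_benefit, sigma),
            ClassSpec(0.45, mu_risk, sigma),
        ),
        n_straightliners=n_straightliners,
        n_attribute_dominant=n_attribute_dominant or {},
    )
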