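"""Internal-validity audits for choice data.

Three inattention/heuristic patterns are screened:

* **dominated-task failures** — choosing the objectively worse option in a
  warm-up task that contains a dominated alternative;
* **straight-lining** — choosing the same screen position in all or nearly
  all tasks (default flag: more than 9 of 13 tasks);
* **attribute dominance** — always choosing the alternative with the best
  available level of a single ordered attribute, suggesting a lexicographic
  rule rather than trading off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import RespondentChoices
from .design import ChoiceDesign
from .schema import AttributeSchema

__all__ = [
    "check_dominated",
    "position_profile",
    "attribute_dominance",
    "ValidityReport",
    "validity_report",
]


def check_dominated(design: ChoiceDesign, choices: RespondentChoices) -> pd.DataFrame:
    """Per-respondent pass/fail on the dominated-alternative warm-up tasks.

    A respondent fails if they chose the dominated alternative in at least
    one warm-up; missing warm-up answers (coded -1) make the respondent
    not assessable (status ``"na"``).
    """
    if not design.warmups:
        raise ValueError("design has no warm-up tasks")
    dom = np.array([w.dominated for w in design.warmups])
    n_w = len(dom)
    rows = []
    warm = choices.warmup_choices
    for i, rid in enumerate(choices.respondent_ids):
        if warm is None or warm.shape[1] < n_w or (warm[i, :n_w] < 0).any():
            status, n_failed = "na", -1
        else:
            n_failed = int((warm[i, :n_w] == dom).sum())
            status = "fail" if n_failed > 0 else "pass"
        rows.append({"respondent_id": rid, "status": status, "n_failed": n_failed})
    return pd.DataFrame(rows)


def position_profile(
    choices: RespondentChoices, straightline_threshold: float = 9 / 13
) -> pd.DataFrame:
    """Counts of choices by screen position and straight-lining flags.

    A respondent is flagged when any single position's share of main tasks
    exceeds ``straightline_threshold``.
    """
    n_alts = int(choices.choices.max()) + 1
    counts = np.stack(
        [(choices.choices == j).sum(axis=1) for j in range(n_alts)], axis=1
    )
    shares = counts / choices.n_tasks
    flagged = (shares > straightline_threshold).any(axis=1)
    df = pd.DataFrame(
        counts, columns=[f"position_{j}" for j in range(n_alts)]
    )
    df.insert(0, "respondent_id", choices.respondent_ids)
    df["max_share"] = shares.max(axis=1)
    df["straightline"] = flagged
    return df


def attribute_dominance(
    choices: RespondentChoices, design: ChoiceDesign, schema: AttributeSchema | None = None
) -> pd.DataFrame:
    """Which ordered attributes each respondent is 'dominant' on.

    Dominant on attribute a: in every main task the chosen alternative
    attains the best available level of a in that task (shared-best levels
    count as attaining).  Unordered attributes are never evaluated.
    """
    schema = schema or design.schema
    rows = []
    ordered = schema.ordered_indices
    # per version/task/attribute: which alternatives attain the best rank
    for i, rid in enumerate(choices.respondent_ids):
        v = int(choices.versions[i])
        dominant = []
        for ai in ordered:
            a = schema[ai]
            ok = True
            for t in range(design.n_tasks):
                ranks = np.array(
                    [a.level_rank(int(li)) for li in design.cells[v, t, :, ai]]
                )
                if ranks[choices.choices[i, t]] < ranks.max():
                    ok = False
                    break
            if ok:
                dominant.append(a.name)
        rows.append({"respondent_id": rid, "dominant_attributes": dominant})
    return pd.DataFrame(rows)


@dataclass
class ValidityReport:
    """Cohort-level audit: warm-up failures, positions, dominance."""

    dominated: pd.DataFrame
    positions: pd.DataFrame
    dominance: pd.DataFrame
    failure_rate: float
    position_shares: np.ndarray
    n_straightliners: int
    dominance_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "failure_rate": self.failure_rate,
            "position_shares": self.position_shares.tolist(),
            "n_straightliners": self.n_straightliners,
            "dominance_counts": self.dominance_counts,
        }


def validity_report(
    choices: RespondentChoices,
    design: ChoiceDesign,
    straightline_threshold: float = 9 / 13,
) -> ValidityReport:
    """Run all three audits and aggregate cohort rates."""
    dominated = check_dominated(design, choices)
    positions = position_profile(choices, straightline_threshold)
    dominance = attribute_dominance(choices, design)
    assessed = dominated[dominated["status"] != "na"]
    failure_rate = (
        float((assessed["status"] == "fail").mean()) if len(assessed) else float("nan")
    )
    pos_cols = [c for c in positions.columns if c.startswith("position_")]
    totals = positions[pos_cols].to_numpy().sum(axis=0)
    shares = totals / totals.sum()
    counts: dict[str, int] = {}
    for attrs in dominance["dominant_attributes"]:
        for a in attrs:
            counts[a] = counts.get(a, 0) + 1
    return ValidityReport(
        dominated=dominated,
        positions=positions,
        dominance=dominance,
        failure_rate=failure_rate,
        position_shares=shares,
        n_straightliners=int(positions["straightline"].sum()),
        dominance_counts=counts,
    )
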