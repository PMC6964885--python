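"""In-memory container for respondent choice records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ChoiceDesign

__all__ = ["RespondentChoices"]


@dataclass
class RespondentChoices:
    """Observed (or simulated) choices, one row of tasks per respondent.

    ``choices[i, t]`` is the alternative index respondent ``i`` chose in main
    task ``t`` of their assigned design version.  Warm-up answers are kept
    separately and never enter the likelihood.
    """

    respondent_ids: list[str]
    versions: np.ndarray  # (n_resp,) design version index per respondent
    choices: np.ndarray  # (n_resp, n_tasks) chosen alternative indices
    warmup_choices: np.ndarray | None = None  # (n_resp, n_warmups), -1 = missing

    def __post_init__(self) -> None:
        self.versions = np.asarray(self.versions, dtype=np.int64)
        self.choices = np.asarray(self.choices, dtype=np.int64)
        if self.warmup_choices is not None:
            self.warmup_choices = np.asarray(self.warmup_choices, dtype=np.int64)
        if len(self.respondent_ids) != len(self.versions):
            raise ValueError("one version per respondent required")
        if self.choices.shape[0] != len(self.respondent_ids):
            raise ValueError("one choice row per respondent required")
        if self.choices.shape[1] == 0:
            raise ValueError("respondents with zero tasks cannot be analysed")

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    @property
    def n_tasks(self) -> int:
        return self.choices.shape[1]

    def validate_against(self, design: ChoiceDesign) -> None:
        if self.versions.min() < 0 or self.versions.max() >= design.n_versions:
            raise ValueError("respondent assigned to unknown design version")
        if self.choices.min() < 0 or self.choices.max() >= design.n_alts:
            raise ValueError("chosen alternative out of range for the design")
        if self.n_tasks != design.n_tasks:
            raise ValueError("task count does not match the design")
        if self.warmup_choices is not None and self.warmup_choices.size:
            if self.warmup_choices.shape[1] != design.n_warmups:
                raise ValueError("warm-up count does not match the design")
            if self.warmup_choices.max() >= design.n_alts:
                raise ValueError("warm-up choice out of range for the design")
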