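"""Choice-set construction: balanced-overlap fractional designs and warm-ups.

The generator emulates the goals of commercial balanced-overlap designs:
within every survey version each level of each attribute appears nearly
equally often (level balance), while a controllable fraction of task ×
attribute cells deliberately repeats a level across alternatives (overlap),
which lightens the respondent's cognitive load at a small efficiency cost.

The algorithm is a documented, reproducible heuristic: start from perfectly
balanced random level columns, then hill-climb with within-attribute swaps —
which preserve level balance exactly — against a penalty combining duplicate
alternatives and the distance of the overlap rate from its target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .schema import AttributeSchema

__all__ = [
    "WarmupTask",
    "ChoiceDesign",
    "DesignAudit",
    "generate_design",
    "make_warmups",
    "audit_design",
    "find_dominated",
]


@dataclass(frozen=True)
class WarmupTask:
    """A warm-up choice task containing exactly one dominated alternative."""

    cells: np.ndarray  # (n_alts, n_attrs) level indices
    dominated: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "cells", np.asarray(self.cells, dtype=np.int64))


@dataclass
class ChoiceDesign:
    """versions x tasks x alternatives grid of attribute-level assignments."""

    schema: AttributeSchema
    cells: np.ndarray  # (n_versions, n_tasks, n_alts, n_attrs) level indices
    warmups: list[WarmupTask] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.ndim != 4:
            raise ValueError("cells must be (versions, tasks, alternatives, attributes)")
        if self.cells.shape[3] != len(self.schema):
            raise ValueError("attribute axis does not match schema")

    @property
    def n_versions(self) -> int:
        return self.cells.shape[0]

    @property
    def n_tasks(self) -> int:
        return self.cells.shape[1]

    @property
    def n_alts(self) -> int:
        return self.cells.shape[2]

    @property
    def n_warmups(self) -> int:
        return len(self.warmups)


def find_dominated(task_cells: np.ndarray, schema: AttributeSchema) -> list[int]:
    """Indices of alternatives dominated by some other alternative in a task.

    Alternative ``j`` is dominated by ``k`` when ``k`` is weakly better on
    every ordered attribute and strictly better on at least one; unordered
    attributes (e.g. dosing regimen) carry no better-direction and are
    ignored.
    """
    task_cells = np.asarray(task_cells)
    n_alts = task_cells.shape[0]
    ordered = schema.ordered_indices
    if not ordered:
        return []
    ranks = np.array(
        [[schema[ai].level_rank(int(task_cells[j, ai])) for ai in ordered] for j in range(n_alts)]
    )
    out = []
    for j in range(n_alts):
        for k in range(n_alts):
            if k == j:
                continue
            if np.all(ranks[k] >= ranks[j]) and np.any(ranks[k] > ranks[j]):
                out.append(j)
                break
    return out


def _overlap_rate(cells: np.ndarray) -> float:
    """Fraction of task x attribute cells where >= 2 alternatives share a level."""
    s = np.sort(cells, axis=-2)  # sort along the alternative axis
    shared = (s[..., 1:, :] == s[..., :-1, :]).any(axis=-2)
    return float(shared.mean())


def _duplicate_count(cells: np.ndarray) -> int:
    """Number of within-task alternative pairs identical on all attributes."""
    n_alts = cells.shape[-2]
    count = 0
    for j in range(n_alts):
        for k in range(j + 1, n_alts):
            count += int(np.all(cells[..., j, :] == cells[..., k, :], axis=-1).sum())
    return count


def _balanced_column(n_cells: int, n_levels: int, rng: np.random.Generator) -> np.ndarray:
    base, extra = divmod(n_cells, n_levels)
    counts = np.full(n_levels, base)
    counts[rng.permutation(n_levels)[:extra]] += 1
    col = np.repeat(np.arange(n_levels), counts)
    rng.shuffle(col)
    return col


def generate_design(
    schema: AttributeSchema,
    n_versions: int = 100,
    n_tasks: int = 13,
    n_alts: int = 3,
    overlap_target: float = 0.6,
    seed: int = 0,
    max_sweeps: int = 200,
) -> ChoiceDesign:
    """Generate a balanced-overlap choice design, deterministic given ``seed``.

    Each version starts from independently shuffled, perfectly level-balanced
    columns; within-attribute swaps then remove duplicate alternatives and
    steer the overlap rate toward ``overlap_target``.  Swapping two cells of
    the same attribute never changes level counts, so balance deviation stays
    at its initial <= 1 occurrence.

    Note the achievable overlap floor: any attribute with fewer levels than
    alternatives must share a level in every task (pigeonhole), so with the
    default six-attribute schema and 3 alternatives the overall rate cannot
    fall below 0.5.  The optimizer converges to the closest achievable rate.
    """
    if n_alts < 2:
        raise ValueError("need at least 2 alternatives")
    if not 0 <= overlap_target < 1:
        raise ValueError("overlap_target must be in [0, 1)")
    n_profiles = int(np.prod([a.n_levels for a in schema], dtype=np.int64))
    if n_alts > n_profiles:
        raise ValueError(
            f"{n_alts} distinct alternatives infeasible: only {n_profiles} profiles exist"
        )
    rng = np.random.default_rng(seed)
    n_attrs = len(schema)
    n_cells = n_tasks * n_alts
    versions = np.empty((n_versions, n_tasks, n_alts, n_attrs), dtype=np.int64)
    for v in range(n_versions):
        cells = np.empty((n_tasks, n_alts, n_attrs), dtype=np.int64)
        for ai, a in enumerate(schema):
            cells[:, :, ai] = _balanced_column(n_cells, a.n_levels, rng).reshape(
                n_tasks, n_alts
            )
        versions[v] = _improve_version(cells, overlap_target, rng, max_sweeps)
    return ChoiceDesign(schema=schema, cells=versions)


def _penalty(cells: np.ndarray, overlap_target: float) -> float:
    return 10.0 * _duplicate_count(cells) + abs(_overlap_rate(cells) - overlap_target)


def _improve_version(
    cells: np.ndarray, overlap_target: float, rng: np.random.Generator, max_sweeps: int
) -> np.ndarray:
    n_tasks, n_alts, n_attrs = cells.shape
    pen = _penalty(cells, overlap_target)
    # one swap moves the overlap count by at most 2 cells; stop once the
    # overlap sits within half a cell of the closest achievable rate
    tol = 0.5 / (n_tasks * n_attrs)
    for _ in range(max_sweeps):
        if pen <= tol:
            break
        improved = False
        for _ in range(n_tasks * n_attrs):
            ai = rng.integers(n_attrs)
            t1, t2 = rng.integers(n_tasks, size=2)
            a1, a2 = rng.integers(n_alts, size=2)
            if t1 == t2 and a1 == a2:
                continue
            c1, c2 = cells[t1, a1, ai], cells[t2, a2, ai]
            if c1 == c2:
                continue
            cells[t1, a1, ai], cells[t2, a2, ai] = c2, c1
            new = _penalty(cells, overlap_target)
            if new < pen:
                pen = new
                improved = True
            else:
                cells[t1, a1, ai], cells[t2, a2, ai] = c1, c2
        if not improved:
            break
    return cells


def make_warmups(schema: AttributeSchema, n: int = 2, seed: int = 0) -> list[WarmupTask]:
    """Build ``n`` warm-up tasks, each with exactly one dominated alternative.

    Warm-ups use simplified trade-offs: unordered attributes are held
    constant across the three alternatives, and the dominated option is
    weakly worse than one competitor on every ordered attribute and strictly
    worse on at least one.  They are flagged so estimation excludes them.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if not schema.ordered_indices:
        raise ValueError("warm-ups require at least one ordered attribute")
    rng = np.random.default_rng(seed)
    ordered = set(schema.ordered_indices)
    tasks: list[WarmupTask] = []
    while len(tasks) < n:
        base = np.array([rng.integers(a.n_levels) for a in schema])
        dom = base.copy()
        strict = False
        for ai in schema.ordered_indices:
            a = schema[ai]
            worse = [
                li
                for li in range(a.n_levels)
                if a.level_rank(li) < a.level_rank(int(base[ai]))
            ]
            if worse and (rng.random() < 0.6 or not strict):
                dom[ai] = int(rng.choice(worse))
                strict = True
        if not strict:
            continue
        third = base.copy()
        for ai in schema.ordered_indices:
            third[ai] = rng.integers(schema[ai].n_levels)
        cells = np.stack([base, dom, third])
        order = rng.permutation(3)
        cells = cells[order]
        dom_idx = int(np.where(order == 1)[0][0])
        if find_dominated(cells, schema) == [dom_idx]:
            tasks.append(WarmupTask(cells=cells, dominated=dom_idx))
    return tasks


@dataclass
class DesignAudit:
    """Brute-force recount of a design's balance, overlap and degeneracies."""

    level_frequencies: dict[str, np.ndarray]  # attr -> (n_versions, n_levels)
    max_balance_deviation: float
    balance_deviation_by_attribute: dict[str, float]
    overlap_rate: float
    duplicate_task_count: int
    dominated_main_count: int

    def to_dict(self) -> dict:
        return {
            "max_balance_deviation": self.max_balance_deviation,
            "balance_deviation_by_attribute": self.balance_deviation_by_attribute,
            "overlap_rate": self.overlap_rate,
            "duplicate_task_count": self.duplicate_task_count,
            "dominated_main_count": self.dominated_main_count,
        }


def audit_design(design: ChoiceDesign, schema: AttributeSchema | None = None) -> DesignAudit:
    """Recount per-version level frequencies, overlap and dominated alternatives.

    Accidentally dominated alternatives in main tasks are reported, not
    forbidden: screening them out would distort level balance.
    """
    schema = schema or design.schema
    cells = design.cells
    n_versions, n_tasks, n_alts, _ = cells.shape
    n_cells = n_tasks * n_alts
    freqs: dict[str, np.ndarray] = {}
    devs: dict[str, float] = {}
    for ai, a in enumerate(schema):
        f = np.zeros((n_versions, a.n_levels), dtype=np.int64)
        for li in range(a.n_levels):
            f[:, li] = (cells[..., ai] == li).reshape(n_versions, -1).sum(axis=1)
        freqs[a.name] = f
        devs[a.name] = float(np.abs(f - n_cells / a.n_levels).max())
    dominated = sum(
        len(find_dominated(cells[v, t], schema))
        for v in range(n_versions)
        for t in range(n_tasks)
    )
    return DesignAudit(
        level_frequencies=freqs,
        max_balance_deviation=max(devs.values()),
        balance_deviation_by_attribute=devs,
        overlap_rate=_overlap_rate(cells),
        duplicate_task_count=_duplicate_count(cells),
        dominated_main_count=dominated,
    )
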