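"""Reporting quantities derived from posterior part-worths.

Three summaries are produced from draws of the population mean mu:

* **Scaled utilities** — zero-centered level utilities rescaled per draw so
  the largest absolute level utility maps to 10; the reporting range is
  -10 (strong aversion) to +10 (strong preference).
* **Relative importance (RI)** — each attribute's utility range (best minus
  worst level) as a percentage of the summed ranges; sums to 100 on every
  draw.
* **Marginal rate of substitution (MRS)** — the absolute increase in chance
  of remission (percentage points) a respondent would require to accept an
  undesirable attribute level, i.e. the utility gap to the preferred level
  divided by the remission slope per point.

All credible intervals are equal-tailed 2.5/97.5 posterior percentiles.
Summaries default to population-mean draws; pass ``pool_individuals=True``
to use pooled per-respondent draws instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hb import HBPosterior
from .schema import AttributeSchema, CodingMap

__all__ = ["ScaledUtilities", "scale_utilities", "relative_importance", "mrs"]


def _draw_matrix(posterior: HBPosterior | np.ndarray, pool_individuals: bool) -> np.ndarray:
    if isinstance(posterior, np.ndarray):
        draws = np.atleast_2d(np.asarray(posterior, dtype=float))
    elif pool_individuals:
        b = posterior.beta_draws()
        draws = b.reshape(-1, b.shape[-1])
    else:
        draws = posterior.mu_draws()
    if draws.size == 0:
        raise ValueError("posterior has no draws")
    return draws


def _level_utilities(
    draws: np.ndarray, schema: AttributeSchema, coding: CodingMap
) -> list[np.ndarray]:
    """Zero-centered level utilities per attribute, each (n_draws, n_levels)."""
    out = []
    for ai in range(len(schema)):
        u = coding.level_utilities(ai, draws)
        out.append(u - u.mean(axis=-1, keepdims=True))
    return out


@dataclass
class ScaledUtilities:
    """Per-draw scaled level utilities and their posterior summaries."""

    table: pd.DataFrame  # attribute, level, median, lo, hi
    scale_factors: np.ndarray  # (n_draws,)
    scaled_draws: dict[str, np.ndarray]  # attribute -> (n_draws, n_levels)
    degenerate_draws: int = 0


def scale_utilities(
    posterior: HBPosterior | np.ndarray,
    schema: AttributeSchema,
    coding: CodingMap,
    pool_individuals: bool = False,
) -> ScaledUtilities:
    """Scale each draw's level utilities so the largest magnitude is 10.

    Linear attributes are evaluated at their design levels around the center
    and zero-centered; effects-coded utilities are zero-sum already.  The
    scale factor is per draw (10 / max |level utility|), so every draw's
    extreme is exactly +/-10; medians and 95% CrIs are then taken across
    draws.  All-zero draws cannot be scaled and are flagged.
    """
    draws = _draw_matrix(posterior, pool_individuals)
    levels = _level_utilities(draws, schema, coding)
    max_abs = np.max(
        np.concatenate([np.abs(u) for u in levels], axis=-1), axis=-1
    )
    degenerate = int((max_abs == 0).sum())
    with np.errstate(divide="ignore"):
        factors = np.where(max_abs > 0, 10.0 / max_abs, np.nan)
    rows = []
    scaled_draws: dict[str, np.ndarray] = {}
    for a, u in zip(schema, levels):
        su = u * factors[:, None]
        scaled_draws[a.name] = su
        med = np.nanmedian(su, axis=0)
        lo = np.nanpercentile(su, 2.5, axis=0)
        hi = np.nanpercentile(su, 97.5, axis=0)
        for li, lv in enumerate(a.levels):
            rows.append(
                {
                    "attribute": a.name,
                    "level": lv,
                    "median": med[li],
                    "lo": lo[li],
                    "hi": hi[li],
                }
            )
    return ScaledUtilities(
        table=pd.DataFrame(rows),
        scale_factors=factors,
        scaled_draws=scaled_draws,
        degenerate_draws=degenerate,
    )


def relative_importance(
    posterior: HBPosterior | np.ndarray,
    schema: AttributeSchema,
    coding: CodingMap,
    pool_individuals: bool = False,
) -> pd.DataFrame:
    """Attribute importance as percentage of total utility range.

    Per draw, importance = 100 * range / sum of ranges, so the vector sums
    to 100 exactly on every draw; the reported point estimate is the
    posterior mean (which therefore also sums to 100), with median and 95%
    CrI alongside.
    """
    draws = _draw_matrix(posterior, pool_individuals)
    levels = _level_utilities(draws, schema, coding)
    ranges = np.stack(
        [u.max(axis=-1) - u.min(axis=-1) for u in levels], axis=-1
    )  # (n_draws, n_attrs)
    total = ranges.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("all-zero draw: importance undefined")
    ri = 100.0 * ranges / total
    return pd.DataFrame(
        {
            "attribute": schema.names,
            "importance": ri.mean(axis=0),
            "median": np.median(ri, axis=0),
            "lo": np.percentile(ri, 2.5, axis=0),
            "hi": np.percentile(ri, 97.5, axis=0),
        }
    )


def mrs(
    posterior: HBPosterior | np.ndarray,
    schema: AttributeSchema,
    coding: CodingMap,
    items: list[tuple[str, object]] | None = None,
    benefit_attribute: str = "remission",
    pool_individuals: bool = False,
) -> pd.DataFrame:
    """Remission points required to accept each undesirable attribute level.

    For each (attribute, level) item the per-draw MRS is the utility gap
    between the attribute's preferred level and the target level, divided by
    the benefit slope per percentage point; for an effects-coded binary this
    reduces to 2|beta| / beta_remission when the level is disliked.  Items
    default to the non-preferred level of every ordered binary attribute.
    A warning is attached when the benefit slope crosses zero in more than
    1% of draws (the ratio is then unstable).
    """
    draws = _draw_matrix(posterior, pool_individuals)
    ai_ben = schema.index(benefit_attribute)
    a_ben = schema[ai_ben]
    if a_ben.kind != "linear":
        raise ValueError("benefit attribute must be linear (slope per point)")
    slope = draws[:, coding.columns[ai_ben][0]]
    sign_frac = float(np.mean(slope <= 0))
    if sign_frac > 0.01:
        warnings.warn(
            f"benefit slope crosses zero in {100 * sign_frac:.1f}% of draws; "
            "MRS ratios are unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    if items is None:
        items = []
        for a in schema:
            if a.kind == "binary" and a.is_ordered:
                disliked = [lv for lv in a.levels if lv != a.ordering][0]
                items.append((a.name, disliked))
    rows = []
    for name, level in items:
        ai = schema.index(name)
        a = schema[ai]
        if not a.is_ordered:
            raise ValueError(f"attribute {name!r} has no preferred level")
        u = coding.level_utilities(ai, draws)  # (n_draws, L)
        li = list(a.levels).index(level)
        best = int(np.argmax([a.level_rank(j) for j in range(a.n_levels)]))
        gap = u[..., best] - u[..., li]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = gap / slope
        rows.append(
            {
                "attribute": name,
                "level": level,
                "mrs": float(np.median(ratio)),
                "lo": float(np.percentile(ratio, 2.5)),
                "hi": float(np.percentile(ratio, 97.5)),
                "slope_sign_flip_frac": sign_frac,
            }
        )
    return pd.DataFrame(rows)
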