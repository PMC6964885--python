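"""File formats: schemas (JSON/YAML), designs and choices (CSV), posteriors.

CSV dialect is UTF-8, comma-separated, '.' decimal; respondent ids are
opaque strings.  Choice files are long-format with columns
``respondent_id, version, task, alternative_chosen, is_warmup``; missing
warm-up answers are coded -1.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import RespondentChoices
from .design import ChoiceDesign, WarmupTask
from .hb import HBPosterior, MCMCSettings
from .schema import AttributeSchema

__all__ = [
    "read_schema",
    "write_schema",
    "read_design",
    "write_design",
    "read_choices",
    "write_choices",
    "save_posterior",
    "load_posterior",
]

CHOICES_COLUMNS = ["respondent_id", "version", "task", "alternative_chosen", "is_warmup"]


def write_schema(schema: AttributeSchema, path: str | Path) -> None:
    path = Path(path)
    d = schema.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2) + "\n")


def read_schema(path: str | Path) -> AttributeSchema:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return AttributeSchema.from_dict(d)


def write_design(design: ChoiceDesign, path: str | Path, warmups_path: str | Path | None = None) -> None:
    """Long-format CSV: version, task, alternative, one level-index column per attribute."""
    v, t, a = np.meshgrid(
        np.arange(design.n_versions),
        np.arange(design.n_tasks),
        np.arange(design.n_alts),
        indexing="ij",
    )
    df = pd.DataFrame({"version": v.ravel(), "task": t.ravel(), "alternative": a.ravel()})
    flat = design.cells.reshape(-1, len(design.schema))
    for ai, name in enumerate(design.schema.names):
        df[name] = flat[:, ai]
    df.to_csv(path, index=False)
    if warmups_path is not None:
        payload = [
            {"cells": w.cells.tolist(), "dominated": w.dominated} for w in design.warmups
        ]
        Path(warmups_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_design(
    schema: AttributeSchema, path: str | Path, warmups_path: str | Path | None = None
) -> ChoiceDesign:
    df = pd.read_csv(path)
    n_versions = int(df["version"].max()) + 1
    n_tasks = int(df["task"].max()) + 1
    n_alts = int(df["alternative"].max()) + 1
    df = df.sort_values(["version", "task", "alternative"])
    cells = (
        df[schema.names].to_numpy(dtype=np.int64).reshape(n_versions, n_tasks, n_alts, -1)
    )
    warmups = []
    if warmups_path is not None:
        for w in json.loads(Path(warmups_path).read_text()):
            warmups.append(WarmupTask(cells=np.asarray(w["cells"]), dominated=int(w["dominated"])))
    return ChoiceDesign(schema=schema, cells=cells, warmups=warmups)


def write_choices(choices: RespondentChoices, path: str | Path) -> None:
    rows = []
    for i, rid in enumerate(choices.respondent_ids):
        v = int(choices.versions[i])
        for t in range(choices.n_tasks):
            rows.append((rid, v, t, int(choices.choices[i, t]), 0))
        if choices.warmup_choices is not None:
            for t in range(choices.warmup_choices.shape[1]):
                rows.append((rid, v, t, int(choices.warmup_choices[i, t]), 1))
    pd.DataFrame(rows, columns=CHOICES_COLUMNS).to_csv(path, index=False)


def read_choices(path: str | Path, design: ChoiceDesign | None = None) -> RespondentChoices:
    """Parse and validate a long-format choices CSV.

    Duplicate (respondent, task) rows, unknown versions and out-of-range
    alternatives raise errors naming the offending row number (1-based data
    rows, excluding the header).
    """
    df = pd.read_csv(path)
    missing = [c for c in CHOICES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"choices file missing columns: {missing}")
    df = df.reset_index(drop=True)
    dup = df.duplicated(subset=["respondent_id", "task", "is_warmup"], keep="first")
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise ValueError(f"duplicate (respondent, task) entry at data row {row}")
    if design is not None:
        bad_v = ~df["version"].between(0, design.n_versions - 1)
        if bad_v.any():
            row = int(df.index[bad_v][0]) + 1
            raise ValueError(f"unknown design version at data row {row}")
        main = df["is_warmup"] == 0
        bad_a = main & ~df["alternative_chosen"].between(0, design.n_alts - 1)
        if bad_a.any():
            row = int(df.index[bad_a][0]) + 1
            raise ValueError(f"chosen alternative out of range at data row {row}")
    ids = list(dict.fromkeys(df["respondent_id"].astype(str)))
    main = df[df["is_warmup"] == 0]
    warm = df[df["is_warmup"] == 1]
    n_tasks = int(main["task"].max()) + 1
    versions = np.empty(len(ids), dtype=np.int64)
    choices = np.full((len(ids), n_tasks), -1, dtype=np.int64)
    for i, rid in enumerate(ids):
        sub = main[main["respondent_id"].astype(str) == rid]
        if len(sub) != n_tasks:
            raise ValueError(f"respondent {rid!r} has {len(sub)} of {n_tasks} main tasks")
        versions[i] = int(sub["version"].iloc[0])
        choices[i, sub["task"].to_numpy()] = sub["alternative_chosen"].to_numpy()
    warm_arr = None
    if len(warm):
        n_w = int(warm["task"].max()) + 1
        warm_arr = np.full((len(ids), n_w), -1, dtype=np.int64)
        for i, rid in enumerate(ids):
            sub = warm[warm["respondent_id"].astype(str) == rid]
            warm_arr[i, sub["task"].to_numpy()] = sub["alternative_chosen"].to_numpy()
    out = RespondentChoices(
        respondent_ids=ids, versions=versions, choices=choices, warmup_choices=warm_arr
    )
    if design is not None:
        out.validate_against(design)
    return out


def save_posterior(posterior: HBPosterior, path: str | Path) -> None:
    """Persist draws as a compressed npz plus settings metadata."""
    s = posterior.settings
    np.savez_compressed(
        path,
        beta=posterior.beta,
        mu=posterior.mu,
        sigma=posterior.sigma,
        loglik=posterior.loglik,
        acceptance=posterior.acceptance,
        respondent_ids=np.array(posterior.respondent_ids),
        settings=json.dumps(
            {
                "n_chains": s.n_chains,
                "n_burnin": s.n_burnin,
                "n_monitor": s.n_monitor,
                "thin": s.thin,
                "seed": s.seed,
            }
            if s
            else {}
        ),
    )


def load_posterior(path: str | Path) -> HBPosterior:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["settings"]))
        settings = MCMCSettings(**meta) if meta else None
        return HBPosterior(
            beta=z["beta"],
            mu=z["mu"],
            sigma=z["sigma"],
            loglik=z["loglik"],
            acceptance=z["acceptance"],
            respondent_ids=[str(r) for r in z["respondent_ids"]],
            settings=settings,
        )
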