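"""End-to-end synthetic pipeline with one global seed and a run manifest.

``run_pipeline`` chains the stages design -> simulate -> fit -> summarize ->
lca -> validity -> scenarios, writing every output as text (CSV/JSON) into
the configured directory plus a manifest recording settings, effective
per-stage seeds, convergence summary and SHA-256 checksums.  The global seed
deterministically spawns independent per-stage seeds, so a re-run with the
same config is byte-identical while stages stay statistically independent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .design import audit_design, generate_design, make_warmups
from .diagnostics import gelman_rubin
from .hb import MCMCSettings, fit_hb
from .latent_class import assign_classes, fit_lc
from .scenarios import apply_sensitivity, crohn_treatment_profiles, simulate_menu, simulate_pairs
from .schema import CodingMap, crohn_schema
from .simulate import crohn_population, simulate_choices, simulate_population
from .summaries import mrs, relative_importance, scale_utilities
from .validity import validity_report

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

ALL_STAGES = ("design", "simulate", "fit", "summarize", "lca", "validity", "scenarios")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Pipeline configuration; defaults reproduce the study-scale conditions
    except for iteration counts, which callers set to their compute budget."""

    out_dir: str | Path = "run_output"
    seed: int = 0
    schema_path: str | Path | None = None
    choices_path: str | Path | None = None  # analyse observed data instead of simulating
    stages: tuple[str, ...] = ALL_STAGES
    design: dict = field(
        default_factory=lambda: {
            "n_versions": 100, "n_tasks": 13, "n_alts": 3,
            "overlap_target": 0.6, "n_warmups": 2,
        }
    )
    population: dict = field(
        default_factory=lambda: {
            "n_respondents": 155, "n_straightliners": 0, "n_attribute_dominant": {},
        }
    )
    mcmc: dict = field(default_factory=dict)  # overrides for MCMCSettings
    lca: dict = field(default_factory=lambda: {"classes": [1, 2], "n_starts": 5})
    scenarios: dict = field(default_factory=lambda: {"scenario": "base", "n_draws": 10_000})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**d)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for label, p in (("schema_path", self.schema_path), ("choices_path", self.choices_path)):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} does not exist: {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(ss: np.random.SeedSequence, index: int) -> int:
    return int(ss.spawn(index + 1)[index].generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order and return the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {stage: _stage_seed(ss, i) for i, stage in enumerate(ALL_STAGES)}
    manifest: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": [], "outputs": {}}

    schema = pio.read_schema(config.schema_path) if config.schema_path else crohn_schema()
    coding = CodingMap.from_schema(schema)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        try:
            _run_stage(stage, config, schema, coding, seeds[stage], state, emit, manifest)
        except Exception as exc:  # noqa: BLE001 - structured halt
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
            raise PipelineError(stage, exc) from exc
        manifest["stages"].append(stage)
    manifest["outputs"] = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest


def _run_stage(stage, config, schema, coding, seed, state, emit, manifest):
    out_json = lambda obj: (lambda path: Path(path).write_text(json.dumps(obj, indent=2, default=str) + "\n"))

    if stage == "design":
        d = dict(config.design)
        n_warm = d.pop("n_warmups", 2)
        design = generate_design(schema, seed=seed, **d)
        design.warmups = make_warmups(schema, n=n_warm, seed=seed + 1)
        state["design"] = design
        emit("schema.json", lambda p: pio.write_schema(schema, p))
        emit("design.csv", lambda p: pio.write_design(design, p))
        warm_payload = [
            {"cells": w.cells.tolist(), "dominated": w.dominated} for w in design.warmups
        ]
        emit("warmups.json", out_json(warm_payload))
        audit = audit_design(design)
        emit("design_audit.json", out_json(audit.to_dict()))

    elif stage == "simulate":
        design = state["design"]
        pop = crohn_population(**config.population)
        prefs = simulate_population(pop, seed=seed)
        choicedata = simulate_choices(design, prefs, coding, seed=seed + 1)
        state["prefs"], state["choices"] = prefs, choicedata
        emit("choices.csv", lambda p: pio.write_choices(choicedata, p))
        truth = {
            "class_labels": prefs.class_labels.tolist(),
            "behaviors": prefs.behaviors,
            "betas": np.round(prefs.betas, 10).tolist(),
        }
        emit("ground_truth.json", out_json(truth))

    elif stage == "fit":
        design = state["design"]
        choicedata = state.get("choices")
        if choicedata is None:
            if config.choices_path is None:
                raise ValueError("fit stage needs simulated or loaded choices")
            choicedata = pio.read_choices(config.choices_path, design)
            state["choices"] = choicedata
        settings = MCMCSettings(**{**config.mcmc, "seed": seed})
        posterior = fit_hb(choicedata, design, coding, settings)
        state["posterior"] = posterior
        gr = gelman_rubin(posterior)
        manifest["gelman_rubin"] = {
            "max_psrf": gr.max_psrf,
            "converged": gr.converged,
            "degenerate": gr.degenerate,
        }
        mu = posterior.mu_draws()
        rows = ["parameter,median,lo,hi"]
        for j in range(mu.shape[1]):
            med, lo, hi = (
                np.median(mu[:, j]),
                np.percentile(mu[:, j], 2.5),
                np.percentile(mu[:, j], 97.5),
            )
            rows.append(f"mu[{j}],{med!r},{lo!r},{hi!r}")
        emit("posterior_mu_summary.csv", lambda p: Path(p).write_text("\n".join(rows) + "\n"))
        emit("gelman_rubin.json", out_json({k: v for k, v in gr.values.items()}))

    elif stage == "summarize":
        posterior = state["posterior"]
        su = scale_utilities(posterior, schema, coding)
        ri = relative_importance(posterior, schema, coding)
        mrs_table = mrs(posterior, schema, coding)
        emit("scaled_utilities.csv", lambda p: su.table.to_csv(p, index=False))
        emit("relative_importance.csv", lambda p: ri.to_csv(p, index=False))
        emit("mrs.csv", lambda p: mrs_table.to_csv(p, index=False))
        state["summaries"] = {"scaled": su, "ri": ri, "mrs": mrs_table}

    elif stage == "lca":
        design, choicedata = state["design"], state["choices"]
        comparison = []
        solutions = {}
        for k in config.lca.get("classes", [1, 2]):
            sol = fit_lc(
                choicedata, design, coding, n_classes=k,
                n_starts=config.lca.get("n_starts", 5), seed=seed + k,
            )
            solutions[k] = sol
            comparison.append(
                {"n_classes": k, "loglik": sol.loglik, "n_params": sol.n_params, "bic": sol.bic}
            )
        best_k = min(comparison, key=lambda r: r["bic"])["n_classes"]
        best = solutions[best_k]
        assign = assign_classes(best)
        state["lca"] = {"best": best, "assignment": assign}
        emit(
            "lca_comparison.csv",
            lambda p: Path(p).write_text(
                "n_classes,loglik,n_params,bic\n"
                + "\n".join(f"{r['n_classes']},{r['loglik']!r},{r['n_params']},{r['bic']!r}" for r in comparison)
                + "\n"
            ),
        )
        member_rows = ["respondent_id," + ",".join(f"class_{k}" for k in range(best.n_classes)) + ",assigned"]
        for i, rid in enumerate(choicedata.respondent_ids):
            probs = ",".join(repr(float(x)) for x in best.responsibilities[i])
            member_rows.append(f"{rid},{probs},{int(assign.assignments[i])}")
        emit("lca_membership.csv", lambda p: Path(p).write_text("\n".join(member_rows) + "\n"))

    elif stage == "validity":
        design, choicedata = state["design"], state["choices"]
        report = validity_report(choicedata, design)
        emit("validity.json", out_json(report.to_dict()))
        emit("validity_positions.csv", lambda p: report.positions.to_csv(p, index=False))
        state["validity"] = report

    elif stage == "scenarios":
        posterior = state["posterior"]
        profiles = apply_sensitivity(
            crohn_treatment_profiles(), config.scenarios.get("scenario", "base")
        )
        n_draws = config.scenarios.get("n_draws", 10_000)
        menu = simulate_menu(profiles, posterior, n_draws=n_draws, seed=seed, schema=schema, coding=coding)
        pairs = simulate_pairs(profiles, posterior, n_draws=n_draws, seed=seed + 1, schema=schema, coding=coding)
        emit("scenario_patient_probs.csv", lambda p: menu.patient_probs.to_csv(p, index=False))
        emit("scenario_pairwise.csv", lambda p: pairs.to_csv(p))
        cohort = {
            "modal_shares": {k: float(v) for k, v in menu.modal_shares.items()},
            "mean_probs": {k: float(v) for k, v in menu.mean_probs.items()},
            "n_draws": menu.n_draws,
            "n_extrapolated": menu.n_extrapolated,
        }
        emit("scenario_cohort.json", out_json(cohort))
        state["scenarios"] = {"menu": menu, "pairs": pairs}
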