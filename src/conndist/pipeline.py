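"""End-to-end orchestration: QC -> connectome -> NBS -> metrics -> prediction -> mediation.

A pipeline run is a pure function of (inputs, configuration, global seed):
the global seed deterministically spawns per-stage seeds, every
intermediate artifact is written to the run directory, and a manifest
(parameter echo, versions, seeds, stage outcomes) suffices to re-execute
the run exactly.  When NBS finds no significant component, the prediction
and mediation stages are skipped with an explicit notice (they are defined
on the identified component).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import EdgeIndex, RegionSet, build_connectome, vectorize
from .mediation import mediate
from .nbs import NbsConfig, edge_glm, nbs_test
from .network_metrics import connectogram_edges, strength_table
from .prediction import CVConfig, component_feature, cv_predict
from .qc import MEAN_FD_EXCLUDE_MM, SCRUB_FD_MM
from .simulate import SimConfig, simulate_cohort, write_cohort

log = logging.getLogger("conndist")


@dataclass
class PipelineConfig:
    """Full pipeline configuration (see ``PipelineConfig.from_yaml``)."""

    out_dir: str = "conndist_run"
    seed: int = 0
    outcome_convention: str = "t1_minus_t3"
    mean_fd_exclude: float = MEAN_FD_EXCLUDE_MM
    scrub_fd: float = SCRUB_FD_MM
    simulate: dict | None = None          # SimConfig kwargs; None = use inputs
    inputs: dict = field(default_factory=dict)  # phenotype/membership/matrices paths
    nbs: dict = field(default_factory=dict)     # NbsConfig kwargs
    cv: dict = field(default_factory=dict)      # CVConfig kwargs
    mediation: dict = field(default_factory=dict)  # n_boot, ci_method

    def __post_init__(self):
        if self.mean_fd_exclude <= 0 or self.scrub_fd <= 0:
            raise ValueError("QC thresholds must be positive")
        if self.simulate is None:
            for key in ("phenotype", "membership", "matrices"):
                if key not in self.inputs:
                    raise ValueError(f"inputs missing required path {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input path does not exist: {self.inputs[key]}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stage_seeds(seed: int) -> dict:
    names = ("simulate", "nbs", "cv", "mediation")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _load_input_cohort(config: PipelineConfig):
    """Assemble a cohort from user-supplied files (phenotype, membership,
    per-subject square matrix files named <subject_id>.tsv)."""
    from .simulate import Cohort  # container reuse

    phenotype = pd.read_csv(config.inputs["phenotype"])
    regions = RegionSet.from_frame(pd.read_csv(config.inputs["membership"]))
    index = EdgeIndex(regions.n_regions)
    mdir = Path(config.inputs["matrices"])
    rows = []
    for sid in phenotype["subject_id"]:
        path = mdir / f"{sid}.tsv"
        if not path.exists():
            raise ValueError(f"missing matrix file for subject {sid}: {path}")
        rows.append(vectorize(np.loadtxt(path), index))
    return Cohort(
        phenotype=phenotype,
        edge_table=np.vstack(rows),
        edge_index=index,
        regions=regions,
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure writes a FAILED marker naming the stage (partial
    outputs are retained) and re-raises.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "conndist_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "global_seed": config.seed,
        "stage_seeds": seeds,
        "config": {
            k: v for k, v in asdict(config).items() if k != "out_dir"
        },
        "stages": {},
    }
    summary: list = []
    stage = "setup"
    try:
        # --- cohort ------------------------------------------------------
        stage = "cohort"
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", seeds["simulate"])
            sim = SimConfig(**sim_kwargs)
            cohort, truth = simulate_cohort(sim)
            write_cohort(cohort, truth, out / "cohort")
            manifest["stages"]["cohort"] = {"source": "synthetic", "seed": sim.seed}
            summary.append(
                f"Synthetic cohort: {sim.n_subjects} subjects, "
                f"{sim.n_regions} regions, {sim.effect_edges} planted edges."
            )
        else:
            cohort = _load_input_cohort(config)
            manifest["stages"]["cohort"] = {"source": "files"}
            summary.append(
                f"Loaded cohort: {cohort.n_subjects} subjects, "
                f"{cohort.regions.n_regions} regions."
            )
        cohort.phenotype.to_csv(out / "phenotype.csv", index=False)
        cohort.regions.to_frame().to_csv(out / "membership.csv", index=False)

        outcome = cohort.outcome(config.outcome_convention)
        covariates = cohort.covariates()
        cov_names = ("age", "sex", "mean_fd")

        # --- edge-wise GLM + NBS ----------------------------------------
        stage = "nbs"
        nbs_kwargs = dict(config.nbs)
        nbs_kwargs.setdefault("seed", seeds["nbs"])
        nbs_config = NbsConfig(**nbs_kwargs)
        stats = edge_glm(
            cohort.edge_table, outcome, covariates,
            outcome_name="delta_distress", covariate_names=cov_names,
        )
        pd.DataFrame(
            {
                "edge": np.arange(stats.n_edges),
                "region_a": cohort.edge_index.pairs[:, 0],
                "region_b": cohort.edge_index.pairs[:, 1],
                "t": stats.t_values,
            }
        ).to_csv(out / "edge_stats.csv", index=False)
        components = nbs_test(
            cohort.edge_table, outcome, covariates, nbs_config,
            outcome_name="delta_distress", covariate_names=cov_names,
        )
        with open(out / "components.json", "w") as fh:
            json.dump(
                [
                    {
                        "edge_list": [list(e) for e in c.edge_list],
                        "n_edges": c.n_edges,
                        "sign_profile": c.sign_profile,
                        "p_fwe": c.p_fwe,
                        "significant": c.significant,
                    }
                    for c in components
                ],
                fh,
                indent=1,
            )
        significant = [c for c in components if c.significant]
        manifest["stages"]["nbs"] = {
            "n_components": len(components),
            "n_significant": len(significant),
            "config": asdict(nbs_config),
        }
        if significant:
            top = significant[0]
            summary.append(
                f"NBS: significant component of {top.n_edges} edges "
                f"(p_fwe={top.p_fwe:.4g}; "
                f"{top.sign_profile['negative']} negative / "
                f"{top.sign_profile['positive']} positive t)."
            )
        else:
            summary.append(
                "NBS: no significant component at "
                f"alpha={nbs_config.alpha}; prediction and mediation skipped."
            )
            manifest["stages"]["prediction"] = {"skipped": "no significant component"}
            manifest["stages"]["mediation"] = {"skipped": "no significant component"}

        if significant:
            component = significant[0]
            # --- network metrics ----------------------------------------
            stage = "network_metrics"
            table = strength_table(component, stats, cohort.regions)
            table.nodes.to_csv(out / "node_strength.csv", index=False)
            table.network_pairs.to_csv(out / "network_pair_strength.csv", index=False)
            connectogram_edges(component, stats, cohort.regions).to_csv(
                out / "connectogram_edges.csv", index=False
            )
            hubs = table.hubs()
            manifest["stages"]["network_metrics"] = {
                "top_hubs": hubs["label"].tolist(),
            }
            if len(hubs):
                summary.append(
                    "Hubs (strength, degree>10): "
                    + ", ".join(
                        f"{r.label} ({r.strength:.2f})" for r in hubs.itertuples()
                    )
                )

            # --- prediction ---------------------------------------------
            stage = "prediction"
            cv_kwargs = dict(config.cv)
            cv_kwargs.setdefault("seed", seeds["cv"])
            cv_config = CVConfig(**cv_kwargs)
            feature = component_feature(cohort.edge_table, component)
            cv_result = cv_predict(feature, outcome, cv_config)
            with open(out / "prediction.json", "w") as fh:
                json.dump(
                    {
                        "r_predicted_actual": cv_result.r_predicted_actual,
                        "p_permutation": cv_result.p_permutation,
                        "n_folds": cv_config.n_folds,
                        "n_repeats": cv_config.n_repeats,
                    },
                    fh,
                    indent=1,
                )
            manifest["stages"]["prediction"] = {
                "r_predicted_actual": cv_result.r_predicted_actual,
                "p_permutation": cv_result.p_permutation,
            }
            summary.append(
                f"Prediction: r(predicted, actual) = "
                f"{cv_result.r_predicted_actual:.3f}"
                + (
                    f", permutation p = {cv_result.p_permutation:.4g}"
                    if cv_result.p_permutation is not None
                    else ""
                )
            )

            # --- mediation ----------------------------------------------
            stage = "mediation"
            med_kwargs = dict(config.mediation)
            med_kwargs.setdefault("seed", seeds["mediation"])
            med = mediate(
                feature,
                cohort.phenotype["cpts"].to_numpy(dtype=float),
                outcome,
                covariates,
                **med_kwargs,
            )
            with open(out / "mediation.json", "w") as fh:
                json.dump(
                    {
                        "a": med.a,
                        "b": med.b,
                        "c": med.c,
                        "c_prime": med.c_prime,
                        "indirect": med.indirect,
                        "ci": [med.ci_low, med.ci_high],
                        "significant": med.significant,
                        "n_boot": med.n_boot,
                    },
                    fh,
                    indent=1,
                )
            manifest["stages"]["mediation"] = {
                "indirect": med.indirect,
                "ci": [med.ci_low, med.ci_high],
                "significant": med.significant,
            }
            summary.append(
                f"Mediation: indirect = {med.indirect:.3f} "
                f"(95% CI {med.ci_low:.3f} to {med.ci_high:.3f}; "
                f"{'significant' if med.significant else 'not significant'})."
            )
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("pipeline failed at stage %s: %s", stage, exc)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    for line in summary:
        log.info(line)
    return out
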