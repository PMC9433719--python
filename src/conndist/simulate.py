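"""Synthetic cohorts with a planted outcome-associated subnetwork.

The generator emulates the statistical structure the downstream analysis
assumes: ``n_subjects`` participants, each with a region x region Fisher-z
connectivity matrix over ``n_regions`` regions partitioned into canonical
resting-state networks, a phenotype table (baseline and follow-up distress,
a posttraumatic-stress mediator, age, sex, mean framewise displacement),
and a sparse *effect subnetwork* whose edge strengths correlate with the
distress-change outcome at a controlled level.

Generative model (standardized latent chain)
--------------------------------------------
Per subject, a latent brain factor ``g ~ N(0, 1)`` drives everything:

* mediator       ``m = a*g + sqrt(1 - a^2) * e_m``            (Var m = 1)
* outcome        ``y = c'*g + b*m + sum_k gamma_k z_k + s_y e_y``  (Var y = 1)
* planted edge   ``w_e = beta*g + noise_sd * e_e``
* other edges    ``w_e = noise_sd * e_e``

with ``s_y`` solved so the outcome has unit variance.  Because the chain is
standardized, OLS on (g, m, y) recovers the path coefficients ``a``, ``b``,
``c'`` directly as standardized coefficients, and the population indirect
effect is exactly ``a*b``.

``beta`` is solved in closed form so that the planted edge-outcome
correlation converges to ``effect_rho``: with ``rho_gy = c' + a*b`` the
correlation of an edge with the outcome factors as
``corr(w, y) = corr(w, g) * rho_gy``, hence

    q    = effect_rho / rho_gy                  (requires |q| < 1)
    beta = noise_sd * q / sqrt(1 - q^2)

Phenotype scores are affine maps of the latents (no truncation, so affine
invariance and the calibration above hold exactly): distress change
``T1 - T3 = 8*y`` distress points and mediator score ``40 + 15*m``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import EdgeIndex, RegionSet, devectorize, edge_count

# Default region partition: 136 regions over the 7 canonical networks.
DEFAULT_PARTITION = (24, 22, 20, 18, 18, 17, 17)

# Affine maps from unit-variance latents to questionnaire-like scores.
DISTRESS_T1_MEAN = 28.0
DISTRESS_T1_SD = 9.0
DELTA_SCALE = 8.0
CPTS_LOC = 40.0
CPTS_SCALE = 15.0

# Sample demographics echoing a young-adult cohort (58% female, ~22 y).
AGE_MEAN, AGE_SD = 22.43, 2.12
FEMALE_PROB = 0.58
FD_MEAN, FD_SD = 0.12, 0.04


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Attributes
    ----------
    n_subjects, n_regions : int
        Cohort and parcellation size.
    partition_sizes : tuple of int
        Regions per network; must sum to ``n_regions``.
    effect_edges : int
        Number of planted edges; they form one connected subnetwork.
    effect_rho : float
        Target population correlation between each planted edge weight and
        the outcome, in (-1, 1).  Negative by default: weaker connectivity
        predicts worse distress change.
    path_a, path_b, path_c_prime : float
        Standardized mediation path coefficients (brain -> mediator,
        mediator -> outcome, direct brain -> outcome).
    covariate_effects : tuple of float
        Loadings of (age, sex, mean FD) on the outcome; zero by default
        (the covariates are still drawn and adjusted for downstream).
    noise_sd : float
        Edge noise standard deviation (Fisher-z units).
    n_timepoints : int
        0 = direct-matrix mode (default); > 0 = time-series mode, emitting
        per-subject multivariate-normal series whose population correlation
        matches the subject's target matrix after positive-definite repair.
    seed : int
        Generator seed; identical configs produce identical cohorts.
    """

    n_subjects: int = 100
    n_regions: int = 136
    partition_sizes: tuple = DEFAULT_PARTITION
    effect_edges: int = 70
    effect_rho: float = -0.3
    path_a: float = 0.5
    path_b: float = 0.4
    path_c_prime: float = 0.6
    covariate_effects: tuple = (0.0, 0.0, 0.0)
    noise_sd: float = 1.0
    n_timepoints: int = 0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "partition_sizes", tuple(self.partition_sizes))
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if sum(self.partition_sizes) != self.n_regions:
            raise ValueError(
                f"partition_sizes sum {sum(self.partition_sizes)} != "
                f"n_regions {self.n_regions}"
            )
        if any(s <= 0 for s in self.partition_sizes):
            raise ValueError("partition sizes must be positive")
        if not abs(self.effect_rho) < 1:
            raise ValueError("effect_rho must lie in (-1, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.effect_edges <= edge_count(self.n_regions):
            raise ValueError("effect_edges out of range for n_regions")
        if abs(self.path_a) >= 1:
            raise ValueError("path_a must lie in (-1, 1) (standardized chain)")
        if len(self.covariate_effects) != 3:
            raise ValueError("covariate_effects must have 3 entries (age, sex, fd)")
        if self.outcome_noise_var() <= 0:
            raise ValueError(
                "path and covariate loadings leave no residual outcome "
                "variance; shrink them"
            )
        if self.effect_rho != 0:
            rho_gy = self.brain_outcome_corr()
            if rho_gy == 0 or abs(self.effect_rho / rho_gy) >= 1:
                raise ValueError(
                    f"effect_rho={self.effect_rho} unattainable: |effect_rho| "
                    f"must be < |corr(g, y)| = {abs(rho_gy):.4f} implied by the "
                    "path coefficients"
                )

    def brain_outcome_corr(self) -> float:
        """Population correlation of the latent brain factor with the outcome."""
        return self.path_c_prime + self.path_a * self.path_b

    def outcome_noise_var(self) -> float:
        """Residual outcome variance under the unit-variance constraint."""
        a, b, c = self.path_a, self.path_b, self.path_c_prime
        return 1.0 - (c * c + b * b + 2 * a * b * c) - sum(
            g * g for g in self.covariate_effects
        )

    def edge_loading(self) -> float:
        """Closed-form beta: planted-edge loading on the brain factor."""
        if self.effect_rho == 0:
            return 0.0
        q = self.effect_rho / self.brain_outcome_corr()
        return self.noise_sd * q / np.sqrt(1.0 - q * q)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for recovery tests."""

    effect_edge_list: list  # (i, j) region pairs, i < j
    subject_factor: np.ndarray = field(repr=False)  # latent g per subject
    mediator_true: np.ndarray = field(repr=False)   # latent m per subject
    outcome_true: np.ndarray = field(repr=False)    # latent y per subject
    edge_loading: float = 0.0                        # beta actually used

    def __post_init__(self):
        pairs = [tuple(int(v) for v in e) for e in self.effect_edge_list]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate planted edges")
        if any(i == j for i, j in pairs):
            raise ValueError("self-pair in planted edges")
        if any(i < 0 or j < 0 for i, j in pairs):
            raise ValueError("negative region index in planted edges")
        self.effect_edge_list = [(min(i, j), max(i, j)) for i, j in pairs]


@dataclass
class Cohort:
    """Phenotypes plus per-subject connectomes, the unit all stages share."""

    phenotype: pd.DataFrame
    edge_table: np.ndarray = field(repr=False)  # subjects x edges, Fisher z
    edge_index: EdgeIndex
    regions: RegionSet
    timeseries: list | None = field(default=None, repr=False)

    @property
    def n_subjects(self) -> int:
        return self.edge_table.shape[0]

    def outcome(self, convention: str = "t1_minus_t3") -> np.ndarray:
        """Distress change per subject.

        ``"t1_minus_t3"`` (default) follows the pre-minus-during definition;
        ``"t3_minus_t1"`` flips the sign (increase in distress positive).
        """
        delta = (self.phenotype["distress_t1"] - self.phenotype["distress_t3"]).to_numpy()
        if convention == "t1_minus_t3":
            return delta
        if convention == "t3_minus_t1":
            return -delta
        raise ValueError(f"unknown convention {convention!r}")

    def covariates(self, names: Sequence[str] = ("age", "sex", "mean_fd")) -> np.ndarray:
        return self.phenotype[list(names)].to_numpy(dtype=float)

    def matrix(self, subject: int):
        """Connectivity matrix of one subject (rebuilt from the edge table)."""
        return devectorize(
            self.edge_table[subject],
            self.edge_index,
            subject_id=str(self.phenotype["subject_id"].iloc[subject]),
        )


def _connected_edge_sample(
    rng: np.random.Generator, n_regions: int, n_edges: int
) -> list:
    """Sample ``n_edges`` distinct edges forming one connected subgraph."""
    if n_edges == 0:
        return []
    # smallest node count h with h*(h-1)/2 >= n_edges (then h-1 <= n_edges)
    h = 2
    while h * (h - 1) // 2 < n_edges:
        h += 1
    nodes = rng.choice(n_regions, size=h, replace=False)
    edges = set()
    # random recursive tree guarantees connectivity
    for k in range(1, h):
        j = rng.integers(0, k)
        a, b = int(nodes[k]), int(nodes[j])
        edges.add((min(a, b), max(a, b)))
    while len(edges) < n_edges:
        a, b = rng.choice(h, size=2, replace=False)
        a, b = int(nodes[a]), int(nodes[b])
        edges.add((min(a, b), max(a, b)))
    return sorted(edges)


def _repair_positive_definite(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Nearest-PD-style repair: clip eigenvalues at ``floor``, renormalize diag."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    return (fixed + fixed.T) / 2.0


def simulate_cohort(config: SimConfig) -> tuple:
    """Generate a synthetic cohort and its ground truth.

    Returns
    -------
    (Cohort, GroundTruth)
        Deterministic given ``config`` (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n, R = config.n_subjects, config.n_regions
    index = EdgeIndex(R)
    regions = RegionSet.from_partition_sizes(config.partition_sizes)

    g = rng.standard_normal(n)
    m = config.path_a * g + np.sqrt(1.0 - config.path_a**2) * rng.standard_normal(n)

    age = AGE_MEAN + AGE_SD * rng.standard_normal(n)
    sex = (rng.random(n) < FEMALE_PROB).astype(int)
    mean_fd = np.abs(FD_MEAN + FD_SD * rng.standard_normal(n))
    z_age = (age - AGE_MEAN) / AGE_SD
    z_sex = (sex - FEMALE_PROB) / np.sqrt(FEMALE_PROB * (1 - FEMALE_PROB))
    z_fd = (mean_fd - np.mean(mean_fd)) / (np.std(mean_fd) or 1.0)

    g_age, g_sex, g_fd = config.covariate_effects
    s_y = np.sqrt(config.outcome_noise_var())
    y = (
        config.path_c_prime * g
        + config.path_b * m
        + g_age * z_age
        + g_sex * z_sex
        + g_fd * z_fd
        + s_y * rng.standard_normal(n)
    )

    beta = config.edge_loading()
    effect_pairs = _connected_edge_sample(rng, R, config.effect_edges)
    edge_table = config.noise_sd * rng.standard_normal((n, len(index)))
    if effect_pairs:
        flat = index.to_flat(
            np.array([p[0] for p in effect_pairs]),
            np.array([p[1] for p in effect_pairs]),
        )
        edge_table[:, flat] += beta * g[:, None]

    distress_t1 = DISTRESS_T1_MEAN + DISTRESS_T1_SD * rng.standard_normal(n)
    delta = DELTA_SCALE * y
    phenotype = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "distress_t1": distress_t1,
            "distress_t3": distress_t1 - delta,
            "cpts": CPTS_LOC + CPTS_SCALE * m,
            "age": age,
            "sex": sex,
            "mean_fd": mean_fd,
        }
    )

    timeseries = None
    if config.n_timepoints > 0:
        if config.n_timepoints < 3:
            raise ValueError("time-series mode needs >= 3 timepoints")
        timeseries = []
        for s in range(n):
            target = np.tanh(devectorize(edge_table[s], index).values)
            np.fill_diagonal(target, 1.0)
            repaired = _repair_positive_definite(target)
            try:
                chol = np.linalg.cholesky(repaired)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ValueError(
                    f"subject {phenotype['subject_id'][s]}: target correlation "
                    "matrix not repairable to positive definite"
                ) from exc
            ts = rng.standard_normal((config.n_timepoints, R)) @ chol.T
            timeseries.append(ts)

    cohort = Cohort(
        phenotype=phenotype,
        edge_table=edge_table,
        edge_index=index,
        regions=regions,
        timeseries=timeseries,
    )
    truth = GroundTruth(
        effect_edge_list=effect_pairs,
        subject_factor=g,
        mediator_true=m,
        outcome_true=y,
        edge_loading=beta,
    )
    return cohort, truth


def write_cohort(cohort: Cohort, truth: GroundTruth, outdir) -> None:
    """Write a cohort to disk: phenotype CSV, membership CSV, per-subject
    matrix (or time-series) files, and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.phenotype.to_csv(outdir / "phenotype.csv", index=False)
    cohort.regions.to_frame().to_csv(outdir / "membership.csv", index=False)
    subj_dir = outdir / ("timeseries" if cohort.timeseries is not None else "matrices")
    subj_dir.mkdir(exist_ok=True)
    for s, sid in enumerate(cohort.phenotype["subject_id"]):
        if cohort.timeseries is not None:
            np.savetxt(subj_dir / f"{sid}.tsv", cohort.timeseries[s], delimiter="\t")
        else:
            np.savetxt(subj_dir / f"{sid}.tsv", cohort.matrix(s).values, delimiter="\t")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "effect_edge_list": [list(e) for e in truth.effect_edge_list],
                "edge_loading": truth.edge_loading,
                "subject_factor": truth.subject_factor.tolist(),
                "mediator_true": truth.mediator_true.tolist(),
                "outcome_true": truth.outcome_true.tolist(),
            },
            fh,
            indent=1,
        )
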