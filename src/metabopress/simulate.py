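"""Synthetic two-cohort CKD metabolomics data with planted blood-pressure effects.

The generator emulates the statistical structure the association pipeline
assumes, so every downstream stage is testable without access to patient
data:

* two independent cohorts (discovery / validation) with per-CKD-stage sample
  counts and clinical covariate means/SDs defaulting to the published cohort
  summaries (824 and 552 subjects across control + CKD stages 1-5);
  covariates are truncated normals within physiologic bounds;
* a block-collinear LC-MS feature matrix: features are partitioned into
  clusters, each cluster driven by one latent Gaussian factor, and
  intensities are log-normal (positive, right-skewed). The factor loading is
  calibrated so that the expected pairwise |Pearson r| between raw
  intensities inside a block matches ``within_cluster_r``;
* blood pressure from a latent linear score over centered covariates plus a
  small set of causal features (one per distinct cluster) plus Gaussian
  noise; the score is discretized to stages 1-5 by within-cohort quantile
  thresholds, and a (systolic, diastolic) pair is then sampled uniformly
  inside that stage's band so that re-staging the readings reproduces the
  latent stage exactly.

Planted effect sizes are expressed per 1 SD of log-intensity (the latent
Gaussian scale); the truth record also carries the equivalent slope per
log-intensity unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import STRATA, covariate_reference, stratum_sizes

__all__ = ["SimConfig", "CohortBundle", "simulate_cohorts", "write_bundle", "read_bundle"]

# physiologic truncation bounds for covariate draws
_BOUNDS = {"age": (18.0, 95.0), "egfr": (1.0, 160.0), "weight": (35.0, 150.0), "bmi": (14.0, 45.0)}

# covariate slopes on the latent blood-pressure score (signs follow the
# published clinical model: pressure rises with age/weight/BMI/CKD severity
# and falls with eGFR), applied to covariates centered at reference values
_DEFAULT_COVARIATE_EFFECTS = {
    "ckd_stage": 0.08,
    "egfr": -0.005,
    "age": 0.004,
    "weight": 0.009,
    "bmi": 0.032,
}
_COVARIATE_CENTERS = {"ckd_stage": 2.5, "egfr": 60.0, "age": 57.0, "weight": 72.0, "bmi": 24.6}

# (systolic, diastolic) sampling bands per stage, chosen strictly inside each
# stage's defining region so staging the sampled pair returns the stage
_STAGE_BANDS = {
    1: ((95.0, 119.0), (60.0, 79.0)),
    2: ((120.0, 129.0), (62.0, 79.0)),
    3: ((130.0, 139.0), (80.0, 89.0)),
    4: ((140.0, 180.0), (90.0, 120.0)),
    5: ((181.0, 230.0), (121.0, 140.0)),
}


@dataclass
class SimConfig:
    """Generator configuration; defaults are the study conditions."""

    n_discovery: tuple[int, ...] = stratum_sizes("discovery")
    n_validation: tuple[int, ...] = stratum_sizes("validation")
    n_features: int = 200
    n_clusters: int = 60
    cluster_size_dist: str = "equal"  # "equal" | "geometric"
    within_cluster_r: float = 0.7
    n_causal: int = 10
    effect_sizes: float | Sequence[float] = 0.35
    covariate_effects: dict = field(default_factory=lambda: dict(_DEFAULT_COVARIATE_EFFECTS))
    noise_sd: float = 0.6
    stage_probs: tuple[float, ...] = (0.25, 0.15, 0.25, 0.30, 0.05)
    log_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_discovery) != 6 or len(self.n_validation) != 6:
            raise ValueError("stratum sizes must have 6 entries (control + CKD1-5)")
        if any(n <= 0 for n in (*self.n_discovery, *self.n_validation)):
            raise ValueError("all stratum sizes must be positive")
        if not 0 < self.within_cluster_r < 1:
            raise ValueError("within_cluster_r must lie in (0, 1)")
        if self.n_features <= 0 or self.n_clusters <= 0:
            raise ValueError("n_features and n_clusters must be positive")
        if self.n_clusters > self.n_features:
            raise ValueError("n_clusters cannot exceed n_features")
        if self.n_causal > self.n_clusters:
            raise ValueError("n_causal exceeds n_clusters (one causal feature per cluster)")
        if self.n_causal > self.n_features:
            raise ValueError("n_causal cannot exceed n_features")
        if self.noise_sd <= 0 or self.log_sigma <= 0:
            raise ValueError("noise_sd and log_sigma must be positive")
        if len(self.stage_probs) != 5 or not np.isclose(sum(self.stage_probs), 1.0):
            raise ValueError("stage_probs must be 5 probabilities summing to 1")

    @property
    def effect_vector(self) -> np.ndarray:
        beta = np.asarray(self.effect_sizes, dtype=float)
        if beta.ndim == 0:
            beta = np.full(self.n_causal, float(beta))
        if beta.size != self.n_causal:
            raise ValueError("effect_sizes length must equal n_causal")
        return beta


@dataclass
class CohortBundle:
    """One cohort: intensity matrix, feature metadata, clinical table, truth."""

    features: pd.DataFrame
    features_meta: pd.DataFrame
    clinical: pd.DataFrame
    truth: list[dict]

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.clinical.index):
            raise ValueError("feature and clinical tables must share sample IDs in order")
        known = set(self.features.columns)
        for rec in self.truth:
            if rec["feature"] not in known:
                raise ValueError(f"truth references unknown feature {rec['feature']!r}")

    @property
    def causal_features(self) -> list[str]:
        return [rec["feature"] for rec in self.truth]


def _cluster_assignment(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Cluster index per feature; every cluster gets at least one feature."""
    if config.cluster_size_dist == "equal":
        sizes = np.full(config.n_clusters, config.n_features // config.n_clusters)
        sizes[: config.n_features % config.n_clusters] += 1
    elif config.cluster_size_dist == "geometric":
        raw = rng.geometric(p=0.35, size=config.n_clusters).astype(float)
        extra = config.n_features - config.n_clusters
        sizes = 1 + np.floor(extra * raw / raw.sum()).astype(int)
        # distribute rounding remainder to the largest blocks
        for k in np.argsort(-raw)[: config.n_features - int(sizes.sum())]:
            sizes[k] += 1
    else:
        raise ValueError(f"unknown cluster_size_dist {config.cluster_size_dist!r}")
    return np.repeat(np.arange(config.n_clusters), sizes)


def _gaussian_block_corr(target_r: float, sigma: float) -> float:
    """Latent-Gaussian correlation giving |Pearson r| = target on the
    log-normal intensity scale: inverts corr(e^X, e^Y) for bivariate normals."""
    s2 = sigma * sigma
    r = np.log1p(target_r * np.expm1(s2)) / s2
    return float(np.clip(r, 0.0, 0.999))


def _draw_covariates(cohort: str, sizes: Sequence[int], rng: np.random.Generator) -> pd.DataFrame:
    ref = covariate_reference(cohort)
    frames = []
    for stage_idx, (stratum, n) in enumerate(zip(STRATA, sizes)):
        cols = {"ckd_stage": np.full(n, stage_idx, dtype=float)}
        cols["sex"] = (rng.random(n) < ref["men_frac"][stage_idx]).astype(float)
        for name in ("age", "egfr", "weight", "bmi"):
            mean, sd = ref[name][stage_idx]
            lo, hi = _BOUNDS[name]
            a, b = (lo - mean) / sd, (hi - mean) / sd
            cols[name] = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
        frames.append(pd.DataFrame(cols))
    out = pd.concat(frames, ignore_index=True)
    out.index = pd.Index([f"{cohort[0].upper()}{k:04d}" for k in range(len(out))], name="sample_id")
    return out


def _sample_bp(stages: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    systolic = np.empty(stages.size)
    diastolic = np.empty(stages.size)
    for stage, ((slo, shi), (dlo, dhi)) in _STAGE_BANDS.items():
        mask = stages == stage
        k = int(mask.sum())
        systolic[mask] = rng.uniform(slo, shi, size=k)
        diastolic[mask] = rng.uniform(dlo, dhi, size=k)
    return np.round(systolic, 1), np.round(diastolic, 1)


def _simulate_cohort(
    cohort: str,
    sizes: Sequence[int],
    config: SimConfig,
    structure: dict,
    rng: np.random.Generator,
) -> CohortBundle:
    clinical = _draw_covariates(cohort, sizes, rng)
    n = len(clinical)
    assign = structure["assign"]
    r_gauss = structure["r_gauss"]

    factors = rng.standard_normal((n, config.n_clusters))
    noise = rng.standard_normal((n, config.n_features))
    z = np.sqrt(r_gauss) * factors[:, assign] + np.sqrt(1.0 - r_gauss) * noise
    log_x = structure["mu"][None, :] + config.log_sigma * z
    features = pd.DataFrame(
        np.exp(log_x), index=clinical.index, columns=structure["ids"]
    )

    score = np.zeros(n)
    for cov, slope in config.covariate_effects.items():
        score += slope * (clinical[cov].to_numpy() - _COVARIATE_CENTERS[cov])
    causal_idx = structure["causal_idx"]
    beta = config.effect_vector
    for b, fi in zip(beta, causal_idx):
        score += b * z[:, fi]
    score += rng.normal(0.0, config.noise_sd, size=n)

    edges = np.quantile(score, np.cumsum(config.stage_probs)[:-1])
    stages = 1 + np.searchsorted(edges, score, side="left")
    systolic, diastolic = _sample_bp(stages, rng)
    clinical["systolic"] = systolic
    clinical["diastolic"] = diastolic
    clinical["bp_stage_latent"] = stages
    clinical["cohort"] = cohort

    truth = [
        {
            "feature": structure["ids"][fi],
            "cluster": int(assign[fi]),
            "effect_per_sd": float(b),
            "effect_per_log_unit": float(b / config.log_sigma),
        }
        for b, fi in zip(beta, causal_idx)
    ]
    return CohortBundle(
        features=features,
        features_meta=structure["meta"],
        clinical=clinical,
        truth=truth,
    )


def simulate_cohorts(config: SimConfig) -> tuple[CohortBundle, CohortBundle]:
    """Generate the discovery and validation bundles from one configuration.

    The feature panel (IDs, m/z, retention time, cluster structure, causal
    placement) is shared; samples are drawn independently per cohort. Output
    is fully determined by the configuration, including its seed.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    struct_rng = np.random.default_rng(seeds[0])

    assign = _cluster_assignment(config, struct_rng)
    ids = [f"F{k:05d}" for k in range(config.n_features)]
    meta = pd.DataFrame(
        {
            "feature": ids,
            "mz": np.round(struct_rng.uniform(60.0, 1200.0, config.n_features), 4),
            "rt": np.round(struct_rng.uniform(0.3, 16.0, config.n_features), 2),
        }
    ).set_index("feature")
    # one causal feature per distinct cluster: the first member of a random
    # draw of n_causal clusters
    causal_clusters = struct_rng.choice(config.n_clusters, size=config.n_causal, replace=False)
    first_member = {c: int(np.argmax(assign == c)) for c in causal_clusters}
    causal_idx = np.array([first_member[c] for c in causal_clusters], dtype=int)

    structure = {
        "assign": assign,
        "ids": ids,
        "meta": meta,
        "mu": struct_rng.uniform(8.0, 12.0, config.n_features),
        "r_gauss": _gaussian_block_corr(config.within_cluster_r, config.log_sigma),
        "causal_idx": causal_idx,
    }
    discovery = _simulate_cohort(
        "discovery", config.n_discovery, config, structure, np.random.default_rng(seeds[1])
    )
    validation = _simulate_cohort(
        "validation", config.n_validation, config, structure, np.random.default_rng(seeds[2])
    )
    return discovery, validation


def write_bundle(bundle: CohortBundle, directory: str | Path) -> dict:
    """Serialize a bundle to TSV/JSON files; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle.features.to_csv(directory / "features.tsv", sep="\t")
    bundle.features_meta.to_csv(directory / "features_meta.tsv", sep="\t")
    bundle.clinical.to_csv(directory / "clinical.tsv", sep="\t")
    (directory / "truth.json").write_text(json.dumps(bundle.truth, indent=1))
    manifest = {
        "files": ["features.tsv", "features_meta.tsv", "clinical.tsv", "truth.json"],
        "n_samples": int(len(bundle.features)),
        "n_features": int(bundle.features.shape[1]),
        "n_causal": len(bundle.truth),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_bundle(directory: str | Path) -> CohortBundle:
    """Load a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    features = pd.read_csv(directory / "features.tsv", sep="\t", index_col=0)
    meta = pd.read_csv(directory / "features_meta.tsv", sep="\t", index_col=0)
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t", index_col=0)
    truth = json.loads((directory / "truth.json").read_text())
    return CohortBundle(features=features, features_meta=meta, clinical=clinical, truth=truth)
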