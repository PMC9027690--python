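"""End-to-end orchestration: simulate -> stage -> reduce -> associate -> importance.

``run_pipeline`` executes the full analysis on synthetic (or previously
written) two-cohort bundles and leaves every stage output plus a provenance
record in the run directory, so a run can be audited stage by stage
(feature and sample counts at each checkpoint) and re-executed
bit-identically from its configuration.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (
    COMBINED_COVARIATES,
    combined_fit,
    cumulative_r2,
    evaluate_recovery,
    roc_auc,
    screen_features,
)
from .importance import NetSpec, ablation_importance, accuracy_curve
from .reduction import correlation_cluster, select_representatives
from .simulate import CohortBundle, SimConfig, read_bundle, simulate_cohorts, write_bundle
from .staging import stage_table

__all__ = ["RunConfig", "run_pipeline"]

_BASE_COVARIATES = ("age", "weight", "bmi", "egfr")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    sim: SimConfig = field(default_factory=SimConfig)
    load_dir: str | None = None  # read bundles instead of simulating
    t: float = 0.45
    alpha: float = 0.05
    outcome: str = "bp_code5"
    reduce_seed: int = 0
    run_importance: bool = False
    importance_seeds: int = 5
    net: dict = field(default_factory=dict)  # NetSpec overrides

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _join(bundle: CohortBundle, reduced: pd.DataFrame) -> pd.DataFrame:
    staged = stage_table(bundle.clinical)
    return staged.join(reduced)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write outputs + provenance under ``out_dir``.

    Returns a summary dict (counts, recovery metrics, headline tables'
    paths). On a stage failure, partial outputs are kept and a FAILED marker
    naming the stage is written before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_name = "setup"
    log: dict = {"config_digest": config.digest(), "version": __version__, "stages": {}}
    try:
        stage_name = "simulate"
        if config.load_dir:
            base = Path(config.load_dir)
            discovery = read_bundle(base / "discovery")
            validation = read_bundle(base / "validation")
        else:
            discovery, validation = simulate_cohorts(config.sim)
        write_bundle(discovery, out / "discovery")
        write_bundle(validation, out / "validation")
        log["stages"]["simulate"] = {
            "n_discovery": len(discovery.features),
            "n_validation": len(validation.features),
            "n_features": discovery.features.shape[1],
        }

        stage_name = "stage"
        disc_staged = stage_table(discovery.clinical)
        val_staged = stage_table(validation.clinical)
        disc_staged.to_csv(out / "discovery_staged.tsv", sep="\t")
        val_staged.to_csv(out / "validation_staged.tsv", sep="\t")
        log["stages"]["stage"] = {
            "discovery_code5_counts": disc_staged["bp_code5"].value_counts().sort_index().to_dict(),
        }

        stage_name = "reduce"
        clusters = correlation_cluster(discovery.features, t=config.t, seed=config.reduce_seed)
        clusters.to_json(out / "clusters.json")
        reduced_disc = select_representatives(discovery.features, clusters)
        reduced_val = select_representatives(validation.features, clusters)
        log["stages"]["reduce"] = {
            "n_features_in": discovery.features.shape[1],
            "n_clusters": len(clusters),
            "t": config.t,
        }

        stage_name = "associate"
        disc_joined = disc_staged.join(reduced_disc)
        val_joined = val_staged.join(reduced_val)
        assoc = screen_features(
            disc_joined, val_joined, list(reduced_disc.columns),
            outcome=config.outcome, alpha=config.alpha,
        )
        pooled = pd.concat([disc_joined, val_joined])
        assoc = combined_fit(assoc, pooled, outcome=config.outcome, alpha=config.alpha)
        assoc.to_csv(out / "assoc.tsv", sep="\t", index=False)
        recovery = evaluate_recovery(assoc, discovery.causal_features, clusters.cluster_of())
        replicated = (
            assoc.loc[assoc["replicated"]]
            .sort_values("p_combined")
            .reset_index(drop=True)
        )
        ranked = list(replicated["feature"])
        r2 = cumulative_r2(pooled, ranked, outcome=config.outcome)
        pd.DataFrame({"n_features": range(len(r2)), "adj_r2": r2}).to_csv(
            out / "r2_curve.tsv", sep="\t", index=False
        )
        roc_rows = [
            {"feature": f, "auc": roc_auc(pooled[f].to_numpy(), pooled["bp_binary"].to_numpy())}
            for f in ranked
        ]
        pd.DataFrame(roc_rows, columns=["feature", "auc"]).to_csv(
            out / "roc.tsv", sep="\t", index=False
        )
        log["stages"]["associate"] = {
            "n_screened": len(assoc),
            "n_replicated": int(assoc["replicated"].sum()),
            "n_combined_sig_raw": int(assoc["sig_combined_raw"].sum()),
            "n_combined_sig_adj": int(assoc["sig_combined_adj"].sum()),
            **recovery,
        }

        importance_path = None
        if config.run_importance and ranked:
            stage_name = "importance"
            spec = NetSpec(
                features=tuple(_BASE_COVARIATES) + tuple(ranked),
                **config.net,
            )
            report = ablation_importance(
                pooled, spec, features_to_test=ranked, n_seeds=config.importance_seeds
            )
            report.deltas.to_csv(out / "importance.tsv", sep="\t", index=False)
            curve = accuracy_curve(
                pooled,
                NetSpec(features=tuple(_BASE_COVARIATES), **config.net),
                ranked,
                n_seeds=config.importance_seeds,
            )
            curve.to_csv(out / "accuracy_curve.tsv", sep="\t", index=False)
            importance_path = str(out / "importance.tsv")
            log["stages"]["importance"] = {
                "baseline_accuracy": report.baseline_accuracy,
                "final_accuracy": float(curve["accuracy_mean"].iloc[-1]),
            }

        stage_name = "report"
        (out / "provenance.json").write_text(json.dumps(log, indent=1, default=str))
        return {
            "assoc": str(out / "assoc.tsv"),
            "clusters": str(out / "clusters.json"),
            "importance": importance_path,
            **log["stages"]["associate"],
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage_name}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc
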