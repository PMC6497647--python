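"""End-to-end orchestration: simulate -> score -> validate -> localize.

The pipeline is deterministic under the config seed: per-subject bootstrap
seeds are derived from (seed, subject index), so subject-level parallelism
cannot change results.  Every artifact directory receives a provenance block
with the full config, its hash and the package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from neuroscore.dissim import ExpertModel
from neuroscore.firstlevel import ItemBetaMaps, zmap_from_betas
from neuroscore.localize import group_localization
from neuroscore.scoring import (
    InfonetConfig,
    NeuralScoreRecord,
    infonet_score,
    rsa_score,
    univariate_score,
)
from neuroscore.searchlight import searchlight_dms, sphere_neighborhoods
from neuroscore.synthdata import SyntheticCohort, SyntheticCohortSpec, generate_cohort
from neuroscore.validation import fit_score_model, lrt_compare, scores_to_long, welch_t

__all__ = ["PipelineConfig", "run_pipeline", "score_cohort", "validate_scores"]

log = logging.getLogger(__name__)

METHODS = ("infonet", "rsa", "univariate")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the end-to-end pipeline, JSON-serializable.

    Unknown keys are rejected on load; the serialized config is stamped into
    every output's provenance block.
    """

    seed: int = 0
    methods: tuple[str, ...] = METHODS
    runs: tuple[int, ...] | None = (1,)
    # simulation
    n_subjects_per_group: int = 10
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_items: int = 24
    n_runs: int = 4
    a_task: float = 1.0
    w_cat: float = 1.0
    w_vis: float = 0.5
    noise_sd: float = 0.5
    n_task_blobs: int = 4
    n_info_blobs: int = 3
    blob_radius: float = 2.0
    # scoring
    top_fraction: float = 0.02
    radius_voxels: float = 3.0
    min_voxels: int = 10
    z_threshold: float = 2.0
    au_threshold: float = 0.95
    min_network_size: int = 2
    scales: tuple[float, ...] = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))
    n_boot_per_scale: int = 100
    svm_cost: float = 1.0
    svm_kernel_width: float = 0.5
    svm_eval_mode: str = "resubstitution"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.runs is not None and any(r < 1 or r > self.n_runs for r in self.runs):
            raise ValueError("runs must lie in [1, n_runs]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw = dict(raw)
        for key in ("methods", "runs", "grid_dims", "scales"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def cohort_spec(self) -> SyntheticCohortSpec:
        return SyntheticCohortSpec(
            n_subjects_per_group=self.n_subjects_per_group,
            grid_dims=self.grid_dims, n_items=self.n_items, n_runs=self.n_runs,
            a_task=self.a_task, w_cat=self.w_cat, w_vis=self.w_vis,
            noise_sd=self.noise_sd, n_task_blobs=self.n_task_blobs,
            n_info_blobs=self.n_info_blobs, blob_radius=self.blob_radius,
            seed=self.seed,
        )

    def infonet_config(self, subject_index: int = 0) -> InfonetConfig:
        return InfonetConfig(
            top_fraction=self.top_fraction, radius_voxels=self.radius_voxels,
            min_voxels=self.min_voxels, scales=self.scales,
            n_boot_per_scale=self.n_boot_per_scale,
            au_threshold=self.au_threshold, min_network_size=self.min_network_size,
            svm_cost=self.svm_cost, svm_kernel_width=self.svm_kernel_width,
            svm_eval_mode=self.svm_eval_mode,
            seed=_subject_seed(self.seed, subject_index),
        )


def _subject_seed(master_seed: int, subject_index: int) -> int:
    return int(
        np.random.SeedSequence([master_seed, subject_index]).generate_state(1)[0]
    )


def score_cohort(
    cohort: SyntheticCohort, config: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, NeuralScoreRecord]]:
    """Score every subject-run with the configured methods.

    Returns a tidy frame (subject_id, run_id, method, score, n_contributing,
    flags) and a record map keyed by "subject/run/method" holding the full
    :class:`NeuralScoreRecord` objects (contributing voxels included).
    """
    runs = tuple(config.runs) if config.runs is not None else tuple(
        range(1, cohort.spec.n_runs + 1)
    )
    need_rsa = "rsa" in config.methods
    if need_rsa:
        wb_centers, wb_hoods = sphere_neighborhoods(
            cohort.mask, config.radius_voxels, config.min_voxels
        )
    rows, records = [], {}
    subject_ids = cohort.subject_ids
    for s_i, sid in enumerate(subject_ids):
        icfg = config.infonet_config(s_i)
        for run in runs:
            betas = cohort.betas[(sid, run)]
            zmap = zmap_from_betas(betas)
            produced: list[NeuralScoreRecord] = []
            if "univariate" in config.methods:
                rec = univariate_score(zmap, config.top_fraction)
                rec.subject_id, rec.run_id = sid, run
                produced.append(rec)
            if need_rsa:
                slr = searchlight_dms(
                    betas, wb_centers, wb_hoods,
                    config.radius_voxels, config.min_voxels,
                )
                rec = rsa_score(slr, cohort.expert_model, config.z_threshold)
                rec.subject_id, rec.run_id = sid, run
                produced.append(rec)
            if "infonet" in config.methods:
                rec, _ = infonet_score(
                    betas, cohort.expert_model.categories, icfg,
                    zmap=zmap, brain_mask=cohort.mask,
                )
                produced.append(rec)
            for rec in produced:
                records[f"{sid}/{run}/{rec.method}"] = rec
                rows.append({
                    "subject_id": sid, "run_id": run, "method": rec.method,
                    "score": rec.score,
                    "n_contributing": int(rec.contributing_voxels.size),
                    "flags": ";".join(rec.flags),
                })
    return pd.DataFrame(rows), records


def validate_scores(
    scores: pd.DataFrame, behavior: pd.DataFrame, run: int = 1
) -> dict:
    """Group t-tests, per-method mixed models and infonet-vs-others LRTs."""
    out: dict = {"run": run, "methods": {}, "model_comparisons": []}
    long_all = scores_to_long(scores, behavior, run=run)
    for method in sorted(scores["method"].unique()):
        entry: dict = {}
        sub = scores[(scores["method"] == method) & (scores["run_id"] == run)]
        sub = sub[np.isfinite(sub["score"])]
        merged = sub.merge(behavior[["subject_id", "group"]], on="subject_id")
        a = merged.loc[merged["group"] == "expert", "score"]
        b = merged.loc[merged["group"] == "novice", "score"]
        if len(a) >= 2 and len(b) >= 2:
            t, df, p = welch_t(a, b)
            entry["group_test"] = {
                "mean_expert": float(a.mean()), "mean_novice": float(b.mean()),
                "t": t, "df": df, "p": p,
            }
        long_m = long_all[long_all["method"] == method]
        if long_m["subject_id"].nunique() >= 3 and long_m["score"].nunique() > 1:
            mm = fit_score_model(long_m)
            entry["mixed_model"] = {
                "beta": mm.beta, "beta_std": mm.beta_std, "p": mm.p,
                "loglik": mm.loglik, "n_obs": mm.n_obs,
                "converged": mm.converged, "flags": mm.flags,
            }
        entry["n_valid"] = int(len(sub))
        entry["n_dropped"] = int((scores["method"] == method).sum() - len(scores[(scores["method"] == method) & np.isfinite(scores["score"])]))
        out["methods"][method] = entry

    # stepwise comparisons against the infonet score, when available
    if "infonet" in scores["method"].unique():
        wide = long_all.pivot_table(
            index=["subject_id", "test_type", "accuracy"],
            columns="method", values="score",
        ).reset_index()
        for other in ("rsa", "univariate"):
            if other not in wide.columns or "infonet" not in wide.columns:
                continue
            both = wide.dropna(subset=["infonet", other])
            if both["subject_id"].nunique() < 3:
                continue
            for base, comp in (
                (["infonet"], ["infonet", other]),
                ([other], ["infonet", other]),
            ):
                try:
                    res = lrt_compare(base, comp, both)
                except ValueError as exc:
                    log.warning("LRT %s vs %s failed: %s", base, comp, exc)
                    continue
                out["model_comparisons"].append({
                    "base": "+".join(base), "composite": "+".join(comp),
                    "chi2": res.chi2, "p": res.p, "df": res.df_diff,
                })
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run simulate -> score -> validate -> localize; returns the result bundle.

    Artifacts written under ``out_dir``: scores.tsv, validation.json,
    localization NIfTIs per method, provenance.json.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from neuroscore import __version__

    cohort = generate_cohort(config.cohort_spec())
    log.info("simulated %d subjects on %s grid (%d in-mask voxels)",
             len(cohort.subject_ids), config.grid_dims, int(cohort.mask.sum()))
    scores, records = score_cohort(cohort, config)
    scores.to_csv(out_dir / "scores.tsv", sep="\t", index=False)

    run1 = min(config.runs) if config.runs else 1
    validation = validate_scores(scores, cohort.behavior, run=run1)
    (out_dir / "validation.json").write_text(json.dumps(validation, indent=2))

    voxel_coords = np.argwhere(cohort.mask)
    groups = cohort.ground_truth.groups
    for method in config.methods:
        contributing = {
            sid: records[f"{sid}/{run1}/{method}"].contributing_voxels
            for sid in cohort.subject_ids
            if f"{sid}/{run1}/{method}" in records
        }
        if not contributing:
            continue
        locmap = group_localization(
            contributing, groups, cohort.mask.shape, voxel_coords, cohort.affine
        )
        locmap.write(out_dir, prefix=f"localization_{method}")

    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_subjects": len(cohort.subject_ids),
        "n_mask_voxels": int(cohort.mask.sum()),
        "n_scores": int(len(scores)),
        "n_missing_scores": int((~np.isfinite(scores["score"])).sum()),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {
        "cohort": cohort, "scores": scores, "records": records,
        "validation": validation, "provenance": provenance,
    }
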