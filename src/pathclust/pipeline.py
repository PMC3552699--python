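"""End-to-end orchestration of the pathway-assisted subtype analysis.

Stages, in order: simulate (or load) a cohort, quantile-normalize, derive
subtype labels from receptor status, run the three-step differential
screen per subtype, build merged pathway-protein matrices, compute the
four distance matrices, cluster them into dendrograms, predict patient
subtypes by nearest neighbor, and export the pathway association network.
Every artifact is plain text and every random stage is seeded, so a rerun
of the same configuration reproduces byte-identical outputs (recorded as
checksums in the run manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cluster import evaluate, hierarchical_cluster, nn_predict, to_newick
from .diffstats import SignificanceCutoffs, declare_significant, differential_test
from .distances import (
    build_distance_matrix,
    DistanceMatrix,
    patient_intensity_profile,
    patient_qvalue_profile,
)
from .network import build_network, select_top_pathways, write_edge_list, write_graphml
from .pathways import build_pathway_protein_matrix, read_gmt, write_gmt
from .quantify import fit_subtype_effects, quantile_normalize
from .simulate import CohortDesign, generate_cohort, generate_pathway_db, make_block_plan
from .subtypes import SUBTYPE_ORDER

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "METRICS"]

METRICS = ("protein_intensity", "q_value", "pathway_profile", "distance_score")


@dataclass
class PipelineConfig:
    """Flat, YAML-serializable pipeline configuration."""

    outdir: str = "pathclust_run"
    # inputs; empty paths mean "simulate"
    intensities: str = ""
    annotation: str = ""
    gmt: str = ""
    # simulation design
    seed: int | None = 0
    n_proteins: int = 616
    n_healthy: int = 80
    n_replicates: int = 2
    n_pathways: int = 20
    pathway_size_min: int = 10
    pathway_size_max: int = 30
    pathway_overlap: float = 0.1
    effect_size: float = 1.0
    n_diff_per_subtype: int = 40
    sigma_individual: float = 0.4
    sigma_replicate: float = 0.1
    sigma_residual: float = 0.3
    # testing
    permutations: int = 1000
    f_alpha: float = 0.05
    p_estimator: str = "plain"
    cutoffs: tuple[float, float, float] = (0.2, 0.1, 0.05)
    # downstream
    score_mode: str = "mean"
    linkage: str = "average"
    prediction: str = "resubstitution"  # or "loo"
    run_prediction: bool = True
    min_avg_count: float = 5.0
    min_similarity: float = 0.0

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducible runs")
        if self.p_estimator not in ("plain", "plus-one"):
            raise ValueError("p_estimator must be 'plain' or 'plus-one'")
        if self.score_mode not in ("mean", "sum"):
            raise ValueError("score_mode must be 'mean' or 'sum'")
        if self.prediction not in ("resubstitution", "loo"):
            raise ValueError("prediction must be 'resubstitution' or 'loo'")
        SignificanceCutoffs(tuple(self.cutoffs))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.cutoffs, list):
            cfg.cutoffs = tuple(cfg.cutoffs)
        return cfg

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["cutoffs"] = list(self.cutoffs)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def analyze_cohort(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    db,
    config: PipelineConfig,
) -> dict:
    """Normalize, screen, and build every subtype-level artifact in memory.

    Returns a dict with the normalized matrix, per-subtype differential
    tables, merged pathway-protein matrices, the effects table, the four
    distance matrices with their merge trees, and the common indices.
    """
    norm = quantile_normalize(matrix)
    subtypes_present = [
        s.value
        for s in SUBTYPE_ORDER
        if s.value in set(annotation.loc[annotation["group"] == "cancer", "subtype"])
    ]
    cutoffs = SignificanceCutoffs(tuple(config.cutoffs))
    results: dict[str, pd.DataFrame] = {}
    sig_sets: dict[str, dict[int, dict]] = {}
    for i, subtype in enumerate(subtypes_present):
        table = differential_test(
            norm,
            annotation,
            subtype,
            B=config.permutations,
            seed=config.seed + 100 + i,
            f_alpha=config.f_alpha,
            estimator=config.p_estimator,
        )
        results[subtype] = table
        sig_sets[subtype] = declare_significant(table, cutoffs)

    all_sig: set[str] = set()
    for subtype in subtypes_present:
        for k in (1, 2, 3):
            all_sig |= sig_sets[subtype][k]["proteins"]
    union_pathways = [pw for pw in db.names if db[pw] & all_sig] or db.names
    union_proteins = sorted(all_sig & set(db.proteins()))
    matrices = {}
    for subtype in subtypes_present:
        directions = results[subtype].set_index("protein_id")["direction"].to_dict()
        matrices[subtype] = build_pathway_protein_matrix(
            {k: sig_sets[subtype][k]["proteins"] for k in (1, 2, 3)},
            db,
            pathways=union_pathways,
            proteins=union_proteins,
            directions=directions,
            subtype=subtype,
        )

    effects = fit_subtype_effects(norm, annotation)
    profiles: dict[str, Mapping] = {
        "protein_intensity": {s: effects[f"S_{s}"] for s in subtypes_present},
        "q_value": {
            s: results[s].set_index("protein_id")["q"] for s in subtypes_present
        },
        "pathway_profile": {s: matrices[s].profile(1) for s in subtypes_present},
        "distance_score": {s: matrices[s] for s in subtypes_present},
    }
    dist_matrices: dict[str, DistanceMatrix] = {}
    trees = {}
    for metric in METRICS:
        D = build_distance_matrix(
            profiles[metric], metric, mode=config.score_mode, on_constant="one"
        )
        dist_matrices[metric] = D
        trees[metric] = hierarchical_cluster(D, method=config.linkage)
    return {
        "normalized": norm,
        "difftests": results,
        "significant": sig_sets,
        "pathway_matrices": matrices,
        "effects": effects,
        "profiles": profiles,
        "distances": dist_matrices,
        "trees": trees,
        "union_pathways": union_pathways,
        "union_proteins": union_proteins,
        "subtypes": subtypes_present,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the manifest (also written to the outdir)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "outputs": {}, "seed": config.seed}
    written: list[Path] = []

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)
        written.append(path)

    # --- stage: inputs -----------------------------------------------------
    if config.intensities and config.annotation and config.gmt:
        matrix = pio.read_intensity_tsv(config.intensities)
        annotation = pio.read_annotation_tsv(config.annotation)
        db = read_gmt(config.gmt)
        truth = None
        manifest["stages"].append({"stage": "load", "inputs": [config.intensities, config.annotation, config.gmt]})
    else:
        db = generate_pathway_db(
            n_pathways=config.n_pathways,
            size_range=(config.pathway_size_min, config.pathway_size_max),
            overlap_fraction=config.pathway_overlap,
            seed=config.seed,
        )
        plan = make_block_plan(
            db,
            seed=config.seed + 1,
            n_diff_per_subtype=config.n_diff_per_subtype,
            effect_size=config.effect_size,
            sigma_individual=config.sigma_individual,
            sigma_replicate=config.sigma_replicate,
            sigma_residual=config.sigma_residual,
        )
        design = CohortDesign(
            n_healthy=config.n_healthy,
            n_proteins=config.n_proteins,
            n_replicates_per_sample=config.n_replicates,
            seed=config.seed + 2,
        )
        matrix, annotation, truth = generate_cohort(design, plan)
        write_gmt(db, out / "pathways.gmt")
        pio.write_intensity_tsv(matrix, out / "intensities.tsv")
        pio.write_annotation_tsv(annotation, out / "annotation.tsv")
        truth.to_json(out / "ground_truth.json")
        for name in ("pathways.gmt", "intensities.tsv", "annotation.tsv", "ground_truth.json"):
            emit(name, out / name)
        manifest["stages"].append({"stage": "simulate", "seed": config.seed})

    # --- stages: normalize .. distances (in-memory core) --------------------
    art = analyze_cohort(matrix, annotation, db, config)
    norm = art["normalized"]
    results = art["difftests"]
    matrices = art["pathway_matrices"]
    effects = art["effects"]
    dist_matrices = art["distances"]
    trees = art["trees"]
    union_pathways = art["union_pathways"]
    union_proteins = art["union_proteins"]
    subtypes_present = art["subtypes"]

    pio.write_intensity_tsv(norm, out / "normalized.tsv")
    emit("normalized.tsv", out / "normalized.tsv")
    manifest["stages"].append({"stage": "normalize"})
    for subtype in subtypes_present:
        path = out / f"difftest_{subtype}.tsv"
        results[subtype].to_csv(path, sep="\t", index=False)
        emit(path.name, path)
    manifest["stages"].append(
        {"stage": "test", "B": config.permutations, "subtypes": subtypes_present}
    )
    for subtype in subtypes_present:
        ppm = matrices[subtype]
        path = out / f"pathway_matrix_{subtype}.tsv"
        ppm.values.to_csv(path, sep="\t")
        emit(path.name, path)
        if ppm.direction is not None:
            dpath = out / f"pathway_matrix_{subtype}_direction.tsv"
            ppm.direction.to_csv(dpath, sep="\t")
            emit(dpath.name, dpath)
    manifest["stages"].append({"stage": "pathways", "n_pathways": len(union_pathways)})
    effects.to_csv(out / "subtype_effects.tsv", sep="\t")
    emit("subtype_effects.tsv", out / "subtype_effects.tsv")
    for metric in METRICS:
        path = out / f"distance_{metric}.tsv"
        pio.write_distance_tsv(dist_matrices[metric], path)
        emit(path.name, path)
        npath = out / f"dendrogram_{metric}.nwk"
        npath.write_text(to_newick(trees[metric]) + "\n")
        emit(npath.name, npath)
    manifest["stages"].append({"stage": "distances", "metrics": list(METRICS)})

    # --- stage: prediction ---------------------------------------------------
    if config.run_prediction:
        prediction = predict_cohort(
            norm,
            annotation,
            db,
            results,
            matrices,
            effects,
            config,
            union_pathways,
            union_proteins,
        )
        for metric, report in prediction.items():
            path = out / f"prediction_{metric}.tsv"
            report.table.to_csv(path, sep="\t")
            emit(path.name, path)
        summary = {m: r.summary() for m, r in prediction.items()}
        (out / "prediction_summary.json").write_text(json.dumps(summary, indent=1))
        emit("prediction_summary.json", out / "prediction_summary.json")
        manifest["stages"].append({"stage": "predict", "mode": config.prediction})

    # --- stage: network -------------------------------------------------------
    changed = pd.DataFrame({s: matrices[s].changed_counts() for s in subtypes_present})
    selected = select_top_pathways(changed, min_avg_count=config.min_avg_count)
    if len(selected) >= 2:
        for subtype in subtypes_present:
            g = build_network(
                db,
                selected,
                changed_counts=changed[subtype],
                min_similarity=config.min_similarity,
            )
            gpath = out / f"network_{subtype}.graphml"
            write_graphml(g, gpath)
            emit(gpath.name, gpath)
            epath = out / f"network_{subtype}_edges.tsv"
            write_edge_list(g, epath)
            emit(epath.name, epath)
        manifest["stages"].append({"stage": "network", "n_selected": len(selected)})
    else:
        logger.warning("fewer than two pathways pass the selection rule; network skipped")
        manifest["stages"].append({"stage": "network", "n_selected": len(selected)})

    config.to_yaml(out / "config.yaml")
    emit("config.yaml", out / "config.yaml")
    manifest["checksums"] = {p.name: _sha256(p) for p in written}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def predict_cohort(
    norm: pd.DataFrame,
    annotation: pd.DataFrame,
    db,
    results: Mapping[str, pd.DataFrame],
    matrices: Mapping,
    effects: pd.DataFrame,
    config: PipelineConfig,
    union_pathways,
    union_proteins,
) -> dict:
    """Nearest-neighbor prediction of every patient under all four metrics.

    Exemplars are the subtype-level profiles (resubstitution by default).
    Patient profiles: replicate-mean intensity vector, per-patient q-value
    vector against the healthy cohort, and the pathway profile / merged
    matrix derived from the patient's own three-cutoff screen.
    """
    cancer = annotation[annotation["group"] == "cancer"]
    patients = list(dict.fromkeys(cancer["individual_id"]))
    truth = dict(zip(cancer["individual_id"], cancer["subtype"]))
    subtypes_present = list(results)
    cutoffs = SignificanceCutoffs(tuple(config.cutoffs))

    exemplars = {
        "protein_intensity": {s: effects[f"S_{s}"] for s in subtypes_present},
        "q_value": {s: results[s].set_index("protein_id")["q"] for s in subtypes_present},
        "pathway_profile": {s: matrices[s].profile(1) for s in subtypes_present},
        "distance_score": {s: matrices[s] for s in subtypes_present},
    }

    healthy_cols = annotation.loc[
        annotation["group"] == "healthy", "sample_id"
    ].tolist()
    healthy_mean = norm[healthy_cols].mean(axis=1)

    predictions: dict[str, dict[str, str]] = {m: {} for m in METRICS}
    for idx, patient in enumerate(patients):
        # per-protein intensity change of this patient relative to healthy plasma,
        # on the same (centered) scale as the subtype fixed-effect exemplars
        intensity = patient_intensity_profile(norm, annotation, patient) - healthy_mean
        q = patient_qvalue_profile(
            norm,
            annotation,
            patient,
            B=config.permutations,
            seed=(config.seed or 0) + 5000 + idx,
            f_alpha=config.f_alpha,
            estimator=config.p_estimator,
        )
        sig = declare_significant(
            pd.DataFrame({"protein_id": q.index, "q": q.to_numpy()}), cutoffs
        )
        ppm = build_pathway_protein_matrix(
            {k: sig[k]["proteins"] for k in (1, 2, 3)},
            db,
            pathways=union_pathways,
            proteins=union_proteins,
            subtype=str(patient),
        )
        profile_by_metric = {
            "protein_intensity": intensity,
            "q_value": q,
            "pathway_profile": ppm.profile(1),
            "distance_score": ppm,
        }
        metric_exemplars = exemplars
        if config.prediction == "loo":
            metric_exemplars = _loo_exemplars(
                exemplars,
                truth[patient],
                patient,
                norm,
                annotation,
                db,
                config,
                union_pathways,
                union_proteins,
            )
        for metric in METRICS:
            label, _, _ = nn_predict(
                profile_by_metric[metric],
                metric_exemplars[metric],
                metric,
                mode=config.score_mode,
                **({"on_constant": "one"} if metric != "distance_score" else {}),
            )
            predictions[metric][patient] = label

    return {m: evaluate(predictions[m], truth) for m in METRICS}


def _loo_exemplars(
    exemplars,
    subtype: str,
    patient: str,
    norm: pd.DataFrame,
    annotation: pd.DataFrame,
    db,
    config: PipelineConfig,
    union_pathways,
    union_proteins,
) -> dict:
    """Recompute the held-out patient's subtype exemplars without the patient.

    Only the patient's own subtype changes; the other exemplars are reused.
    """
    ann = annotation[
        ~(
            (annotation["individual_id"] == patient)
            & (annotation["group"] == "cancer")
        )
    ]
    cols = [c for c in norm.columns if c in set(ann["sample_id"])]
    sub = norm[cols]
    sub.attrs = dict(norm.attrs)
    if (ann["subtype"] == subtype).sum() == 0:
        return exemplars  # held-out patient was the subtype's only member
    table = differential_test(
        sub,
        ann,
        subtype,
        B=config.permutations,
        seed=(config.seed or 0) + 9000,
        f_alpha=config.f_alpha,
        estimator=config.p_estimator,
    )
    cutoffs = SignificanceCutoffs(tuple(config.cutoffs))
    sig = declare_significant(table, cutoffs)
    ppm = build_pathway_protein_matrix(
        {k: sig[k]["proteins"] for k in (1, 2, 3)},
        db,
        pathways=union_pathways,
        proteins=union_proteins,
        subtype=subtype,
    )
    effects = fit_subtype_effects(sub, ann)
    out = {m: dict(exemplars[m]) for m in exemplars}
    out["protein_intensity"][subtype] = effects[f"S_{subtype}"]
    out["q_value"][subtype] = table.set_index("protein_id")["q"]
    out["pathway_profile"][subtype] = ppm.profile(1)
    out["distance_score"][subtype] = ppm
    return out
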