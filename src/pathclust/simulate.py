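"""Synthetic plasma-proteomics cohorts with planted subtype structure.

The generator emulates the study conditions of a label-free plasma
proteomics comparison of breast cancer patients and healthy controls: a
default cohort of 80 patients (subtype counts 24 luminal A, 15 luminal B,
10 HER2+, 19 basal-like, 12 unknown) and 80 healthy women, each plasma
sample injected in replicate.  Log2 intensities follow the additive ANOVA
structure

    y = baseline_p + subtype_effect_p (cancer only) + individual + replicate + residual

with a per-(protein, individual) Gaussian biological effect, a per-column
Gaussian injection shift shared by all proteins of a replicate, and a
per-cell Gaussian residual.  Differential proteins are planted inside
designated "active" pathways of a synthetic GMT database so that
pathway-level metrics see concentrated signal, and receptor statuses are
derived from each patient's true subtype (the inverse of the assignment
rules), making the true labels exactly recoverable.  Patients of the
Unknown subtype get missing receptor status.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pathways import PathwayDB
from .quantify import SCALE_LOG2
from .subtypes import SUBTYPE_ORDER, Subtype, receptor_status_for_subtype

__all__ = [
    "CohortDesign",
    "EffectPlan",
    "GroundTruth",
    "generate_pathway_db",
    "generate_cohort",
    "make_block_plan",
    "DEFAULT_SUBTYPE_COUNTS",
]

#: study-condition cohort composition (patients per receptor-defined subtype)
DEFAULT_SUBTYPE_COUNTS: dict[str, int] = {
    "LuminalA": 24,
    "LuminalB": 15,
    "HER2Plus": 10,
    "BasalLike": 19,
    "Unknown": 12,
}

_VALID_SUBTYPES = {s.value for s in SUBTYPE_ORDER}


@dataclass(frozen=True)
class CohortDesign:
    """Cohort composition and measurement layout."""

    n_healthy: int = 80
    subtype_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS)
    )
    n_proteins: int = 616
    n_replicates_per_sample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy <= 0 or self.n_proteins <= 0 or self.n_replicates_per_sample <= 0:
            raise ValueError("all design counts must be positive")
        bad = set(self.subtype_counts) - _VALID_SUBTYPES
        if bad:
            raise ValueError(f"unknown subtypes in design: {sorted(bad)}")
        if any(c <= 0 for c in self.subtype_counts.values()):
            raise ValueError("subtype counts must be positive")


@dataclass(frozen=True)
class EffectPlan:
    """Planted differential effects and noise magnitudes (log2 units)."""

    effects: Mapping[str, Mapping[str, float]]  # subtype -> protein -> log2 shift
    active_pathways: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    sigma_individual: float = 0.4
    sigma_replicate: float = 0.1
    sigma_residual: float = 0.3

    def __post_init__(self) -> None:
        for s in (self.sigma_individual, self.sigma_replicate, self.sigma_residual):
            if s < 0:
                raise ValueError("variance components must be nonnegative")
        for subtype, eff in self.effects.items():
            if subtype not in _VALID_SUBTYPES:
                raise ValueError(f"unknown subtype in plan: {subtype!r}")
            if not all(np.isfinite(list(eff.values()) or [0.0])):
                raise ValueError(f"non-finite effect size for subtype {subtype!r}")


@dataclass
class GroundTruth:
    """What was planted: labels, differential sets, active pathways."""

    labels: dict[str, str]  # individual_id -> true subtype
    differential: dict[str, set[str]]  # subtype -> differential protein ids
    active_pathways: dict[str, tuple[str, ...]]
    plan: EffectPlan

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels,
            "differential": {s: sorted(p) for s, p in self.differential.items()},
            "active_pathways": {s: list(p) for s, p in self.active_pathways.items()},
            "sigma": {
                "individual": self.plan.sigma_individual,
                "replicate": self.plan.sigma_replicate,
                "residual": self.plan.sigma_residual,
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _accession(i: int) -> str:
    return f"P{i:06d}"


def generate_pathway_db(
    n_pathways: int = 20,
    size_range: tuple[int, int] = (5, 40),
    overlap_fraction: float = 0.2,
    seed: int = 0,
) -> PathwayDB:
    """Synthetic pathway database with controlled pairwise overlap.

    Each pathway draws ``round(size * overlap_fraction)`` members from a
    shared core pool and the remainder from its own private accessions, so
    ``overlap_fraction = 0`` yields pairwise-disjoint pathways and larger
    fractions increase the expected Jaccard similarity.  Deterministic for
    a fixed seed.
    """
    if n_pathways < 2:
        raise ValueError("need at least two pathways")
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid size range")
    if not 0.0 <= overlap_fraction < 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    core_size = max(hi, 1)
    core = [_accession(i + 1) for i in range(core_size)]
    next_id = core_size + 1
    pathways: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        n_core = int(round(size * overlap_fraction))
        n_core = min(n_core, core_size)
        members = list(rng.choice(core, size=n_core, replace=False)) if n_core else []
        n_private = size - n_core
        members += [_accession(next_id + k) for k in range(n_private)]
        next_id += n_private
        name = f"pw{i + 1:03d}"
        pathways[name] = frozenset(members)
        descriptions[name] = f"synthetic pathway {i + 1}"
    return PathwayDB(pathways=pathways, descriptions=descriptions)


def generate_cohort(
    design: CohortDesign,
    plan: EffectPlan,
    protein_ids: Sequence[str] | None = None,
    dropout_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate a cohort: (intensity matrix, annotation table, ground truth).

    The intensity matrix is proteins x sample-replicate columns on the log2
    scale (column ids ``<individual>_r<k>``).  The annotation table has one
    row per column: sample_id, individual_id, group, replicate, ER, PR,
    HER2, subtype.  Receptor statuses are the canonical inverse of each
    patient's true subtype; Unknown patients get missing statuses.
    ``dropout_rate`` blanks that fraction of cells completely at random
    (the only missingness mechanism modelled).
    """
    if not 0.0 <= dropout_rate < 1.0:
        raise ValueError("dropout_rate must lie in [0, 1)")
    bad = set(plan.effects) - set(design.subtype_counts)
    if bad:
        raise ValueError(f"plan subtypes absent from design: {sorted(bad)}")

    planted = sorted({p for eff in plan.effects.values() for p in eff})
    if protein_ids is None:
        filler_needed = design.n_proteins - len(planted)
        if filler_needed < 0:
            raise ValueError(
                f"design.n_proteins={design.n_proteins} smaller than number of "
                f"planted proteins ({len(planted)})"
            )
        existing = set(planted)
        fillers = []
        i = 1
        while len(fillers) < filler_needed:
            acc = f"F{i:06d}"
            if acc not in existing:
                fillers.append(acc)
            i += 1
        protein_ids = planted + fillers
    else:
        missing = set(planted) - set(protein_ids)
        if missing:
            raise ValueError(f"planted proteins outside universe: {sorted(missing)}")
        if len(protein_ids) != design.n_proteins:
            raise ValueError("protein_ids length must equal design.n_proteins")
    protein_ids = list(protein_ids)
    n_prot = len(protein_ids)
    prot_index = {p: i for i, p in enumerate(protein_ids)}

    rng = np.random.default_rng(design.seed)
    baseline = rng.normal(25.0, 2.0, size=n_prot)

    individuals: list[tuple[str, str, str]] = []  # (id, group, subtype)
    for h in range(design.n_healthy):
        individuals.append((f"H{h + 1:04d}", "healthy", ""))
    counter = 1
    for subtype in [s.value for s in SUBTYPE_ORDER if s.value in design.subtype_counts]:
        for _ in range(design.subtype_counts[subtype]):
            individuals.append((f"C{counter:04d}", "cancer", subtype))
            counter += 1

    columns = []
    ann_rows = []
    data = np.empty((n_prot, len(individuals) * design.n_replicates_per_sample))
    col = 0
    for ind_id, group, subtype in individuals:
        effect = np.zeros(n_prot)
        if group == "cancer" and subtype in plan.effects:
            for p, e in plan.effects[subtype].items():
                effect[prot_index[p]] += e
        ind_effect = (
            rng.normal(0.0, plan.sigma_individual, size=n_prot)
            if plan.sigma_individual > 0
            else np.zeros(n_prot)
        )
        status = receptor_status_for_subtype(subtype or Subtype.UNKNOWN) if group == "cancer" else None
        for rep in range(1, design.n_replicates_per_sample + 1):
            rep_shift = rng.normal(0.0, plan.sigma_replicate) if plan.sigma_replicate > 0 else 0.0
            resid = (
                rng.normal(0.0, plan.sigma_residual, size=n_prot)
                if plan.sigma_residual > 0
                else np.zeros(n_prot)
            )
            sample_id = f"{ind_id}_r{rep}"
            columns.append(sample_id)
            data[:, col] = baseline + effect + ind_effect + rep_shift + resid
            col += 1
            ann_rows.append(
                {
                    "sample_id": sample_id,
                    "individual_id": ind_id,
                    "group": group,
                    "replicate": rep,
                    "ER": status.er.value if status else "NA",
                    "PR": status.pr.value if status else "NA",
                    "HER2": status.her2.value if status else "NA",
                    "subtype": subtype,
                }
            )

    if dropout_rate > 0.0:
        mask = rng.random(data.shape) < dropout_rate
        data = np.where(mask, np.nan, data)

    matrix = pd.DataFrame(data, index=protein_ids, columns=columns)
    matrix.index.name = "protein_id"
    matrix.attrs["scale"] = SCALE_LOG2
    annotation = pd.DataFrame(ann_rows)
    truth = GroundTruth(
        labels={ind: (sub if group == "cancer" else "healthy") for ind, group, sub in individuals},
        differential={s: set(eff) for s, eff in plan.effects.items()},
        active_pathways=dict(plan.active_pathways),
        plan=plan,
    )
    return matrix, annotation, truth


def make_block_plan(
    db: PathwayDB,
    seed: int = 0,
    n_diff_per_subtype: int = 40,
    effect_size: float = 1.0,
    shared_within_pair: float = 0.9,
    shared_across_pairs: float = 0.1,
    pathways_per_group: int = 4,
    sigma_individual: float = 0.4,
    sigma_replicate: float = 0.1,
    sigma_residual: float = 0.3,
) -> EffectPlan:
    """Default planted block structure for recovery experiments.

    The luminal pair (LuminalA, LuminalB) shares ``shared_within_pair`` of
    its differential proteins, the basal pair (HER2Plus, BasalLike)
    likewise, the two pairs overlap by ``shared_across_pairs``, and the
    Unknown subtype gets its own differential set.  Differential proteins
    are drawn from designated active pathways of *db*, signs are random but
    consistent across subtypes sharing a protein, and the log2 effect
    magnitude is ``effect_size`` (a two-fold change at the default 1.0).
    """
    rng = np.random.default_rng(seed)
    names = db.names
    if len(names) < 3 * pathways_per_group:
        raise ValueError("pathway database too small for three active groups")
    groups = {
        "luminal": tuple(names[:pathways_per_group]),
        "basal": tuple(names[pathways_per_group : 2 * pathways_per_group]),
        "unknown": tuple(names[2 * pathways_per_group : 3 * pathways_per_group]),
    }

    def pool(group: str) -> list[str]:
        members: set[str] = set()
        for pw in groups[group]:
            members |= db[pw]
        return sorted(members)

    n = n_diff_per_subtype
    n_shared = int(round(shared_within_pair * n))
    n_own = n - n_shared
    n_cross = int(round(shared_across_pairs * n))

    lum_pool, bas_pool, unk_pool = pool("luminal"), pool("basal"), pool("unknown")

    def draw(source: list[str], k: int, taken: set[str]) -> list[str]:
        avail = [p for p in source if p not in taken]
        if len(avail) < k:
            raise ValueError("active pathways too small for requested differential sets")
        picked = list(rng.choice(avail, size=k, replace=False))
        taken.update(picked)
        return picked

    taken: set[str] = set()
    inter = sorted(set(lum_pool) & set(bas_pool))
    cross_source = inter if len(inter) >= n_cross else lum_pool
    cross = draw(cross_source, n_cross, taken)
    lum_core = cross + draw(lum_pool, n_shared - n_cross, taken)
    bas_core = cross + draw(bas_pool, n_shared - n_cross, taken)
    sets = {
        "LuminalA": lum_core + draw(lum_pool, n_own, taken),
        "LuminalB": lum_core + draw(lum_pool, n_own, taken),
        "HER2Plus": bas_core + draw(bas_pool, n_own, taken),
        "BasalLike": bas_core + draw(bas_pool, n_own, taken),
        "Unknown": draw(unk_pool, n, taken),
    }

    sign: dict[str, float] = {}
    effects: dict[str, dict[str, float]] = {}
    for subtype, proteins in sets.items():
        eff = {}
        for p in proteins:
            if p not in sign:
                sign[p] = float(rng.choice([-1.0, 1.0]))
            eff[p] = sign[p] * effect_size
        effects[subtype] = eff

    active = {
        "LuminalA": groups["luminal"],
        "LuminalB": groups["luminal"],
        "HER2Plus": groups["basal"],
        "BasalLike": groups["basal"],
        "Unknown": groups["unknown"],
    }
    return EffectPlan(
        effects=effects,
        active_pathways=active,
        sigma_individual=sigma_individual,
        sigma_replicate=sigma_replicate,
        sigma_residual=sigma_residual,
    )
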