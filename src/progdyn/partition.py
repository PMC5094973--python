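"""Stage-wise fold-changes and the dynamic gene-set partition.

Differential expression is defined purely by fold-change: a gene belongs to
the tumor gene set (TGS) when its tumor-vs-normal |log2 FC| exceeds a
threshold (default 1.0 log2 units). The TGS is then divided into four
non-overlapping subsets by the FIRST progression step whose |log2 FC|
exceeds the same threshold — step 1 (hyperplasia vs normal) → EGS,
step 2 (dysplasia vs hyperplasia) → IGS, step 3 (tumor vs dysplasia) → LGS —
and genes that never cross the threshold at a single step form the
progressive subset (PGS). Up/down direction follows the tumor-vs-normal
sign, so subset UP/DN lists are sub-lists of the TGS ones.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (
    DirectionalSet,
    DynamicPartition,
    ExpressionMatrix,
    OrthologMap,
    StageDesign,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Column name of the overall (last stage vs reference) fold-change.
OVERALL = "tumor_vs_normal"


def step_column(design: StageDesign, k: int) -> str:
    later, earlier = design.steps[k]
    return f"{later}_vs_{earlier}"


def compute_fold_changes(expr: ExpressionMatrix, design: StageDesign) -> pd.DataFrame:
    """Per-gene log2 fold-changes for each consecutive step and overall.

    Because expression is on the log2 scale, the log2 FC between two stages
    is the difference of their per-stage mean log2 values. Columns are one
    per consecutive step (``later_vs_earlier``) plus ``tumor_vs_normal``
    (last stage vs reference stage, whatever their labels).
    """
    stage_means = {}
    for stage in design.stages:
        samples = design.samples_for(stage)
        samples = [s for s in samples if s in expr.sample_ids]
        if not samples:
            raise ValidationError(f"stage {stage!r} has no measured samples")
        stage_means[stage] = expr.values[samples].mean(axis=1)
    fc = pd.DataFrame(index=expr.gene_ids)
    for later, earlier in design.steps:
        fc[f"{later}_vs_{earlier}"] = stage_means[later] - stage_means[earlier]
    fc[OVERALL] = stage_means[design.stages[-1]] - stage_means[design.stages[0]]
    if not np.isfinite(fc.to_numpy()).all():
        raise ValidationError("fold-change table contains non-finite values")
    return fc


_SUBSET_BY_STEP = {0: "EGS", 1: "IGS", 2: "LGS"}


def partition_dynamics(fc: pd.DataFrame, design: StageDesign,
                       threshold: float = 1.0) -> DynamicPartition:
    """Partition the TGS into EGS/IGS/LGS/PGS from a fold-change table.

    The threshold is strict (|FC| > threshold). A gene enters a step subset
    at the first step whose |FC| exceeds the threshold; a TGS gene with no
    such step is progressive. Direction (up/dn) is the tumor-vs-normal sign;
    genes whose defining-step sign disagrees with the overall sign are
    recorded in ``sign_conflicts``.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    if design.n_steps != 3:
        raise ValidationError(
            "the dynamic partition is defined for a 4-stage design "
            f"(3 steps); got {design.n_steps} steps"
        )
    step_cols = [step_column(design, k) for k in range(design.n_steps)]
    missing = [c for c in step_cols + [OVERALL] if c not in fc.columns]
    if missing:
        raise ValidationError(f"fold-change table missing column(s): {missing}")

    overall = fc[OVERALL]
    in_tgs = overall.abs() > threshold
    members: dict = {name: {"up": set(), "dn": set()} for name in
                     ("TGS", "EGS", "IGS", "LGS", "PGS")}
    conflicts = []
    for gene in fc.index[in_tgs]:
        direction = "up" if overall[gene] > 0 else "dn"
        members["TGS"][direction].add(gene)
        subset = "PGS"
        for k, col in enumerate(step_cols):
            if abs(fc.at[gene, col]) > threshold:
                subset = _SUBSET_BY_STEP[k]
                if np.sign(fc.at[gene, col]) != np.sign(overall[gene]):
                    conflicts.append(gene)
                break
        members[subset][direction].add(gene)
    if conflicts:
        logger.warning(
            "%d gene(s) have a defining-step FC sign opposite to their "
            "tumor-vs-normal sign: %s", len(conflicts), sorted(conflicts)[:10],
        )

    return DynamicPartition(
        tgs=DirectionalSet(**{k: frozenset(v) for k, v in members["TGS"].items()}),
        egs=DirectionalSet(**{k: frozenset(v) for k, v in members["EGS"].items()}),
        igs=DirectionalSet(**{k: frozenset(v) for k, v in members["IGS"].items()}),
        lgs=DirectionalSet(**{k: frozenset(v) for k, v in members["LGS"].items()}),
        pgs=DirectionalSet(**{k: frozenset(v) for k, v in members["PGS"].items()}),
        sign_conflicts=tuple(sorted(conflicts)),
    )


_SUBSET_ORDER = ("EGS", "IGS", "LGS", "PGS")


def project_orthologs(partition: DynamicPartition,
                      omap: OrthologMap) -> tuple[DynamicPartition, dict]:
    """Project every partition member through an ortholog map.

    One-to-many mappings expand, duplicate targets collapse, and unmapped
    members are dropped. The second return value is a report with drop
    counts per (subset, direction), plus counts of the two collision kinds a
    many-to-many map can create, both resolved deterministically:

    * a target claimed by several subsets is kept in the earliest one
      (EGS < IGS < LGS < PGS);
    * a target claimed with both directions within its winning subset is
      genuinely ambiguous and dropped from the projection entirely.

    The projected TGS is rebuilt as the union of the projected subsets, so
    partition invariants hold by construction.
    """
    if not omap.pairs:
        raise ValidationError("ortholog map is empty")
    drops: dict = {}
    # target -> set of (subset_rank, direction) claims
    claims: dict = {}
    for rank, name in enumerate(_SUBSET_ORDER):
        ds = partition.as_dict()[name]
        for direction, sources in (("up", ds.up), ("dn", ds.dn)):
            n_dropped = 0
            for gene in sources:
                targets = omap.pairs.get(gene)
                if targets is None:
                    n_dropped += 1
                    continue
                for t in targets:
                    claims.setdefault(t, set()).add((rank, direction))
            drops.setdefault(name, {})[direction] = n_dropped
            if n_dropped:
                logger.info("ortholog projection of %s dropped %d %s member(s)",
                            name, n_dropped, direction)

    resolved: dict = {name: {"up": set(), "dn": set()} for name in _SUBSET_ORDER}
    n_cross, n_ambiguous = 0, 0
    for target, claimed in claims.items():
        best_rank = min(rank for rank, _ in claimed)
        if any(rank != best_rank for rank, _ in claimed):
            n_cross += 1
        directions = {d for rank, d in claimed if rank == best_rank}
        if len(directions) > 1:
            n_ambiguous += 1
            continue
        resolved[_SUBSET_ORDER[best_rank]][directions.pop()].add(target)
    if n_cross:
        logger.warning("%d projected gene(s) claimed by several subsets; "
                       "kept in the earliest", n_cross)
    if n_ambiguous:
        logger.warning("%d projected gene(s) had conflicting up/dn direction "
                       "and were dropped", n_ambiguous)
    drops["cross_subset_collisions"] = n_cross
    drops["ambiguous_direction_dropped"] = n_ambiguous

    subsets = {name: DirectionalSet(up=frozenset(v["up"]), dn=frozenset(v["dn"]))
               for name, v in resolved.items()}
    tgs = DirectionalSet(
        up=frozenset().union(*(subsets[n].up for n in _SUBSET_ORDER)),
        dn=frozenset().union(*(subsets[n].dn for n in _SUBSET_ORDER)),
    )
    return (
        DynamicPartition(
            tgs=tgs, egs=subsets["EGS"], igs=subsets["IGS"],
            lgs=subsets["LGS"], pgs=subsets["PGS"],
            sign_conflicts=partition.sign_conflicts,
        ),
        drops,
    )
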