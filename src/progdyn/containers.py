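"""Core data containers shared across the pipeline.

The pipeline operates on log2-scale gene × sample expression matrices with a
per-sample histological stage or class annotation, gene sets with an optional
up/down direction, a source→target ortholog map, and an ordered stage design
(reference stage first, tumor last).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VALID_DIRECTIONS = ("up", "dn", "none")


class ValidationError(ValueError):
    """An input violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values (genes × samples) plus sample annotation.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, one column per sample id, float values
        on the log2 scale. No missing entries are allowed; missing-value
        handling is an explicit option of the loaders.
    annotation
        Series mapping every sample id to a stage or class label.
    """

    values: pd.DataFrame
    annotation: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene id(s): {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample id(s): {dups}")
        missing = [s for s in self.values.columns if s not in self.annotation.index]
        if missing:
            raise ValidationError(f"annotation missing sample(s): {missing}")
        if self.annotation.index.duplicated().any():
            raise ValidationError("a sample has more than one annotation label")
        if self.values.isna().any().any():
            raise ValidationError(
                "expression matrix contains missing values; "
                "load with an explicit missing policy"
            )
        # keep annotation aligned and restricted to the measured samples
        self.annotation = self.annotation.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = self.values.index.intersection(pd.Index(list(genes)))
        return ExpressionMatrix(self.values.loc[keep], self.annotation.copy())


def direction_from_name(name: str) -> str:
    """Infer a gene set's direction from the MSigDB-style _UP/_DN suffix."""
    if name.endswith("_UP"):
        return "up"
    if name.endswith("_DN"):
        return "dn"
    return "none"


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with an optional up/down direction."""

    name: str
    direction: str
    members: frozenset

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ValidationError(
                f"direction must be one of {VALID_DIRECTIONS}, got {self.direction!r}"
            )
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def from_members(cls, name: str, members: Iterable[str]) -> "GeneSet":
        return cls(name, direction_from_name(name), frozenset(members))

    @property
    def base_name(self) -> str:
        """Set-family name with any _UP/_DN suffix stripped."""
        if self.direction in ("up", "dn"):
            return self.name[:-3]
        return self.name


@dataclass
class OrthologMap:
    """One-to-many source-gene → target-genes mapping (e.g. mouse → human)."""

    pairs: Mapping[str, frozenset]

    def __post_init__(self) -> None:
        clean = {}
        for src, targets in self.pairs.items():
            targets = frozenset(targets)
            if not targets:
                raise ValidationError(f"empty target set for source gene {src!r}")
            clean[src] = targets
        self.pairs = clean

    def project(self, genes: Iterable[str]) -> tuple[frozenset, int]:
        """Map a gene collection, collapsing duplicates.

        Returns the union of target genes and the count of source genes with
        no map entry (dropped).
        """
        mapped: set = set()
        dropped = 0
        for g in genes:
            targets = self.pairs.get(g)
            if targets is None:
                dropped += 1
            else:
                mapped.update(targets)
        return frozenset(mapped), dropped


@dataclass
class StageDesign:
    """Ordered histological stages and the sample → stage assignment.

    Stage 0 is the reference (normal) stage; the last stage is the tumor
    stage. Consecutive pairs define the progression steps.
    """

    stages: tuple
    assignment: pd.Series

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        if len(self.stages) < 2:
            raise ValidationError("a stage design needs at least 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise ValidationError("stage labels must be unique")
        unknown = set(self.assignment.unique()) - set(self.stages)
        if unknown:
            raise ValidationError(f"assignment uses unknown stage label(s): {sorted(unknown)}")
        for stage in self.stages:
            if not (self.assignment == stage).any():
                raise ValidationError(f"stage {stage!r} has no samples")

    @classmethod
    def from_annotation(cls, annotation: pd.Series, stages: Iterable[str]) -> "StageDesign":
        return cls(tuple(stages), annotation.copy())

    def samples_for(self, stage: str) -> pd.Index:
        return self.assignment.index[self.assignment == stage]

    @property
    def steps(self) -> list[tuple[str, str]]:
        """Consecutive (later, earlier) stage pairs, in progression order."""
        return [(self.stages[k], self.stages[k - 1]) for k in range(1, len(self.stages))]

    @property
    def n_steps(self) -> int:
        return len(self.stages) - 1


@dataclass
class DirectionalSet:
    """Up- and down-regulated member lists of one dynamic gene set."""

    up: frozenset = frozenset()
    dn: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.up = frozenset(self.up)
        self.dn = frozenset(self.dn)
        overlap = self.up & self.dn
        if overlap:
            raise ValidationError(f"genes in both up and dn lists: {sorted(overlap)}")

    @property
    def all(self) -> frozenset:
        return self.up | self.dn

    def __len__(self) -> int:
        return len(self.up) + len(self.dn)


PARTITION_SET_NAMES = ("TGS", "EGS", "IGS", "LGS", "PGS")


@dataclass
class DynamicPartition:
    """The tumor gene set (TGS) and its four non-overlapping dynamic subsets.

    EGS/IGS/LGS hold genes first crossing the fold-change threshold at the
    hyperplasia, dysplasia, or tumor step; PGS holds genes that cross the
    tumor-vs-normal threshold without crossing it at any single step.
    ``sign_conflicts`` lists TGS genes whose defining-step fold-change sign
    disagrees with their tumor-vs-normal sign (direction follows the overall
    sign; conflicts are surfaced, not silently resolved).
    """

    tgs: DirectionalSet
    egs: DirectionalSet
    igs: DirectionalSet
    lgs: DirectionalSet
    pgs: DirectionalSet
    sign_conflicts: tuple = ()

    def __post_init__(self) -> None:
        subsets = [self.egs.all, self.igs.all, self.lgs.all, self.pgs.all]
        for i in range(len(subsets)):
            for j in range(i + 1, len(subsets)):
                overlap = subsets[i] & subsets[j]
                if overlap:
                    raise ValidationError(
                        f"dynamic subsets overlap: {sorted(overlap)}"
                    )
        union = frozenset().union(*subsets)
        if union != self.tgs.all:
            raise ValidationError("union of EGS/IGS/LGS/PGS must equal TGS")

    def as_dict(self) -> dict:
        return {
            "TGS": self.tgs,
            "EGS": self.egs,
            "IGS": self.igs,
            "LGS": self.lgs,
            "PGS": self.pgs,
        }

    def to_gene_sets(self) -> list[GeneSet]:
        """The ten directional gene sets (X_UP / X_DN), skipping empty lists."""
        out = []
        for name, ds in self.as_dict().items():
            if ds.up:
                out.append(GeneSet(f"{name}_UP", "up", ds.up))
            if ds.dn:
                out.append(GeneSet(f"{name}_DN", "dn", ds.dn))
        return out
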