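"""Taxonomic delineation from gene-content dissimilarity.

Calibration against complete-genome collections places conspecific strain
pairs mostly below Bray-Curtis 0.2 and pairs from different families
mostly above 0.4, so 0.2 and 0.4 serve as species and family cutoffs.
This module applies those cutoffs to strain pairs, summarises
dissimilarity distributions by the pair's lowest shared taxonomic rank,
and scores true/false positive rates of any index at a cutoff.

Cutoff comparisons are strict: a pair is called "same group" when its
dissimilarity is strictly below the cutoff, so boundary ties are
"different". Pairs are unordered and self-pairs are excluded throughout.
Blank taxonomy fields make a pair's relation undecidable; such pairs are
excluded from rank statistics rather than guessed.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix

#: Calibrated Bray-Curtis cutoffs for species and family membership.
DEFAULT_SPECIES_CUTOFF = 0.2
DEFAULT_FAMILY_CUTOFF = 0.4

#: Default bin boundaries for rank-level distribution summaries.
DEFAULT_BINS = (0.0, 0.2, 0.4, 0.5, 0.8, 1.0)

RANKS = ("species", "genus", "family", "order")


class RankRelation(enum.Enum):
    """Lowest shared taxonomic rank of an unordered strain pair."""

    INTRA_SPECIES = "intra_species"
    INTRA_GENUS_INTER_SPECIES = "intra_genus_inter_species"
    INTRA_FAMILY_INTER_GENUS = "intra_family_inter_genus"
    INTRA_ORDER_INTER_FAMILY = "intra_order_inter_family"
    INTER_ORDER = "inter_order"


@dataclass(frozen=True)
class TaxonomyRecord:
    species: str
    genus: str
    family: str
    order: str


@dataclass
class TaxonomyTable:
    """Strain → (species, genus, family, order) assignments."""

    records: dict[str, TaxonomyRecord]

    def __contains__(self, strain_id: str) -> bool:
        return strain_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def rank(self, strain_id: str, rank: str) -> str:
        return getattr(self.records[strain_id], rank)

    def same_rank(self, a: str, b: str, rank: str) -> bool | None:
        """True/False if decidable, None when either label is blank."""
        va, vb = self.rank(a, rank), self.rank(b, rank)
        if not va or not vb:
            return None
        return va == vb

    def relation(self, a: str, b: str) -> RankRelation | None:
        """Relation of the pair's lowest shared rank; None if undecidable."""
        for rank, rel in zip(
            RANKS,
            (
                RankRelation.INTRA_SPECIES,
                RankRelation.INTRA_GENUS_INTER_SPECIES,
                RankRelation.INTRA_FAMILY_INTER_GENUS,
                RankRelation.INTRA_ORDER_INTER_FAMILY,
            ),
        ):
            same = self.same_rank(a, b, rank)
            if same is None:
                return None
            if same:
                return rel
        return RankRelation.INTER_ORDER

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (s, r.species, r.genus, r.family, r.order)
                for s, r in self.records.items()
            ],
            columns=["strain_id", *RANKS],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        expected = ["strain_id", *RANKS]
        if list(df.columns[:5]) != expected:
            raise ValueError(f"taxonomy TSV must have columns {expected}")
        if df["strain_id"].duplicated().any():
            dups = df.loc[df["strain_id"].duplicated(), "strain_id"].tolist()
            raise ValueError(f"duplicate strain ids in taxonomy: {dups}")
        return cls(
            {
                row.strain_id: TaxonomyRecord(row.species, row.genus, row.family, row.order)
                for row in df.itertuples()
            }
        )


@dataclass(frozen=True)
class CutoffConfig:
    """Species/family Bray-Curtis cutoffs; 0 < species < family < 1."""

    species_cutoff: float = DEFAULT_SPECIES_CUTOFF
    family_cutoff: float = DEFAULT_FAMILY_CUTOFF

    def __post_init__(self) -> None:
        if not 0.0 < self.species_cutoff < self.family_cutoff < 1.0:
            raise ValueError(
                "require 0 < species_cutoff < family_cutoff < 1, got "
                f"({self.species_cutoff}, {self.family_cutoff})"
            )


@dataclass(frozen=True)
class DelineationCall:
    """Cutoff-based membership call for one unordered strain pair."""

    pair: tuple[str, str]
    bc: float
    same_species_predicted: bool
    same_family_predicted: bool


def classify_pair(
    bc: float, cfg: CutoffConfig = CutoffConfig(), pair: tuple[str, str] = ("", "")
) -> DelineationCall:
    """Call same-species / same-family membership from a BC value.

    Strict comparisons: ``bc < cutoff`` predicts membership, so a same-
    species call always implies a same-family call.
    """
    if not 0.0 <= bc <= 1.0:
        raise ValueError(f"Bray-Curtis value outside [0, 1]: {bc}")
    return DelineationCall(
        pair=pair,
        bc=bc,
        same_species_predicted=bc < cfg.species_cutoff,
        same_family_predicted=bc < cfg.family_cutoff,
    )


def classify_matrix(
    dm: DistanceMatrix, cfg: CutoffConfig = CutoffConfig()
) -> list[DelineationCall]:
    """Classify every unordered strain pair of a dissimilarity matrix."""
    return [
        classify_pair(float(dm.values[i, j]), cfg, (dm.labels[i], dm.labels[j]))
        for i, j in itertools.combinations(range(len(dm.labels)), 2)
    ]


def _check_labels(dm: DistanceMatrix, tax: TaxonomyTable) -> None:
    missing = [s for s in dm.labels if s not in tax]
    if missing:
        raise KeyError(f"strains missing from taxonomy: {missing}")


def rank_relations(
    dm: DistanceMatrix, tax: TaxonomyTable
) -> dict[tuple[str, str], RankRelation | None]:
    """Relation of every unordered pair in the matrix (None = undecidable)."""
    _check_labels(dm, tax)
    return {
        (a, b): tax.relation(a, b)
        for a, b in itertools.combinations(dm.labels, 2)
    }


@dataclass
class BinnedDistribution:
    """Histogram of pair dissimilarities for one rank relation.

    ``empty`` flags a relation class with no pairs (fractions are then an
    empty array, never NaN). Bins are left-closed; the last is closed on
    both sides so the boundary value 1.0 is counted.
    """

    relation: RankRelation
    bin_edges: tuple[float, ...]
    counts: np.ndarray
    fractions: np.ndarray
    empty: bool


def binned_distribution(
    dm: DistanceMatrix,
    tax: TaxonomyTable,
    relation: RankRelation,
    bins: Sequence[float] = DEFAULT_BINS,
) -> BinnedDistribution:
    """Fraction of a relation class's pair values falling in each bin."""
    edges = tuple(float(b) for b in bins)
    if list(edges) != sorted(set(edges)):
        raise ValueError("bins must be strictly increasing")
    if edges[0] > 0.0 or edges[-1] < 1.0:
        raise ValueError("bins must cover [0, 1]")
    rels = rank_relations(dm, tax)
    vals = np.array(
        [dm.get(a, b) for (a, b), rel in rels.items() if rel == relation]
    )
    if vals.size == 0:
        k = len(edges) - 1
        return BinnedDistribution(relation, edges, np.zeros(k, int), np.zeros(k), True)
    counts, _ = np.histogram(vals, bins=np.array(edges))
    return BinnedDistribution(
        relation, edges, counts, counts / counts.sum(), False
    )


@dataclass(frozen=True)
class ConfusionAtCutoff:
    tpr: float
    fpr: float
    n_true_pairs: int
    n_false_pairs: int


def confusion_at_cutoff(
    dm: DistanceMatrix,
    tax: TaxonomyTable,
    cutoff: float,
    rank: str = "species",
) -> ConfusionAtCutoff:
    """TPR/FPR of the "value < cutoff ⇒ same rank" call, per pair.

    TPR is the fraction of same-``rank`` pairs called same; FPR the
    fraction of different-rank pairs called same. Rates are per pair, not
    per strain. Pairs whose rank label is blank are excluded.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    _check_labels(dm, tax)
    same_vals, diff_vals = [], []
    for a, b in itertools.combinations(dm.labels, 2):
        same = tax.same_rank(a, b, rank)
        if same is None:
            continue
        (same_vals if same else diff_vals).append(dm.get(a, b))
    if not same_vals:
        raise ValueError(f"no same-{rank} pairs: TPR undefined")
    same_arr, diff_arr = np.array(same_vals), np.array(diff_vals)
    tpr = float((same_arr < cutoff).mean())
    fpr = float((diff_arr < cutoff).mean()) if diff_arr.size else 0.0
    return ConfusionAtCutoff(tpr, fpr, len(same_vals), len(diff_vals))


def index_agreement(
    truth: Mapping[tuple[str, str], bool],
    *calls: Mapping[tuple[str, str], bool],
) -> float:
    """Fraction of pairs on which every index predicts the true relation.

    All call maps must cover exactly the pairs of ``truth``.
    """
    if not calls:
        raise ValueError("need at least one call set")
    pairs = set(truth)
    for c in calls:
        if set(c) != pairs:
            raise ValueError("call sets cover different pairs than the truth set")
    n_ok = sum(all(c[p] == truth[p] for c in calls) for p in pairs)
    return n_ok / len(pairs)
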