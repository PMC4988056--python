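"""Ortholog-count profiles from tabular protein search hits.

A genome's gene content is summarised as an *orthologous gene profile*: for
every orthologous group (OG, e.g. an eggNOG COG/NOG cluster) the number of
its genes whose best database hit falls in that group. Profiles are built
from 12-column tabular search output (BLAST/USEARCH ``outfmt 6`` dialect:
query, target, %identity, alignment length, mismatches, gap opens, qstart,
qend, sstart, send, e-value, bit score), filtered at an e-value ceiling and
a global-identity floor, with each gene assigned to the OG of its single
best surviving hit.

Genomes with too few mapped genes (default < 1000) carry too little signal
for gene-content comparison and are excluded from the profile table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Hit-retention defaults: e-value ceiling and global-identity floor (%).
DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_IDENTITY_MIN = 30.0
#: Genomes mapping fewer genes than this are excluded from profile tables.
DEFAULT_MIN_MAPPED = 1000


@dataclass(frozen=True)
class GeneHit:
    """One filtered-format search hit of a gene against an ortholog database.

    ``og_id`` is the orthologous group the target sequence belongs to (the
    target id itself when no target→OG map is supplied). Coordinates follow
    the 1-based BLAST tabular convention; they are carried but unused.
    """

    gene_id: str
    og_id: str
    identity_pct: float
    evalue: float
    bitscore: float
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(
                f"identity_pct must be in [0, 100], got {self.identity_pct!r}"
            )
        if self.evalue < 0:
            raise ValueError(f"evalue must be non-negative, got {self.evalue!r}")


@dataclass
class HitParseReport:
    """Per-file accounting emitted alongside parsed hits."""

    n_lines: int = 0
    malformed: list[tuple[int, str]] = field(default_factory=list)
    n_unmapped_targets: int = 0

    @property
    def n_parsed(self) -> int:
        return self.n_lines - len(self.malformed) - self.n_unmapped_targets


@dataclass
class OrthologProfile:
    """Counts of genes per orthologous group for one strain.

    ``counts`` never stores zero values: absence of an OG means the key is
    absent. ``total_mapped`` is the row total S_i used by the Bray-Curtis
    dissimilarity.
    """

    strain_id: str
    counts: dict[str, int]
    total_mapped: int = -1

    def __post_init__(self) -> None:
        bad = {og: c for og, c in self.counts.items() if c <= 0}
        if bad:
            raise ValueError(f"non-positive counts not allowed: {bad}")
        total = sum(self.counts.values())
        if self.total_mapped == -1:
            self.total_mapped = total
        elif self.total_mapped != total:
            raise ValueError(
                f"total_mapped={self.total_mapped} but counts sum to {total}"
            )


@dataclass
class ProfileTable:
    """Strains × orthologous-groups integer count matrix with QC metadata."""

    strains: list[str]
    og_ids: list[str]
    counts: np.ndarray  # shape (n_strains, n_ogs), non-negative integers
    excluded_strains: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.strains), len(self.og_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.strains)} strains x {len(self.og_ids)} OGs"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_mapped(self) -> np.ndarray:
        """Per-strain row totals (S_i)."""
        return self.counts.sum(axis=1)

    def profile(self, strain_id: str) -> OrthologProfile:
        """Extract one strain as an :class:`OrthologProfile` (zeros dropped)."""
        i = self.strains.index(strain_id)
        row = self.counts[i]
        nz = row > 0
        counts = {og: int(c) for og, c in zip(np.array(self.og_ids)[nz], row[nz])}
        return OrthologProfile(strain_id, counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.strains, columns=self.og_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("strain_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            strains=[str(s) for s in df.index],
            og_ids=[str(c) for c in df.columns],
            counts=df.to_numpy(dtype=np.int64),
        )

    def write_exclusions_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.excluded_strains, columns=["strain_id", "total_mapped"]
        ).to_csv(path, sep="\t", index=False)


def parse_hits(
    stream: IO[str] | Iterable[str],
    og_map: Mapping[str, str] | None = None,
) -> tuple[list[GeneHit], HitParseReport]:
    """Parse 12-column tabular hit lines into :class:`GeneHit` records.

    Parameters
    ----------
    stream
        An iterable of lines (an open text file works). Blank lines and
        ``#`` comment lines are ignored.
    og_map
        Optional map from target sequence id to orthologous-group id. When
        given, hits whose target is absent from the map are dropped and
        tallied in the report; when absent, the target id is used as OG id.

    Returns
    -------
    (hits, report)
        Parsed hits in input order, and a :class:`HitParseReport` listing
        malformed lines by line number and the count of unmapped targets.
    """
    hits: list[GeneHit] = []
    report = HitParseReport()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        report.n_lines += 1
        cols = line.split("\t")
        if len(cols) < 12:
            report.malformed.append((lineno, f"expected >=12 columns, got {len(cols)}"))
            continue
        try:
            gene_id, target_id = cols[0], cols[1]
            identity = float(cols[2])
            qs, qe, ss, se = (int(c) for c in cols[6:10])
            evalue = float(cols[10])
            bitscore = float(cols[11])
        except ValueError as exc:
            report.malformed.append((lineno, str(exc)))
            continue
        if og_map is not None:
            og_id = og_map.get(target_id)
            if og_id is None:
                report.n_unmapped_targets += 1
                continue
        else:
            og_id = target_id
        try:
            hits.append(
                GeneHit(gene_id, og_id, identity, evalue, bitscore, qs, qe, ss, se)
            )
        except ValueError as exc:
            report.malformed.append((lineno, str(exc)))
    if report.malformed:
        logger.warning("parse_hits: %d malformed lines", len(report.malformed))
    if report.n_unmapped_targets:
        logger.warning(
            "parse_hits: %d hits dropped (target not in OG map)",
            report.n_unmapped_targets,
        )
    return hits, report


def read_og_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping target sequence id → OG id."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["target_id", "og_id"], dtype=str
    )
    return dict(zip(df["target_id"], df["og_id"]))


def filter_hits(
    hits: Sequence[GeneHit],
    evalue_max: float = DEFAULT_EVALUE_MAX,
    identity_min: float = DEFAULT_IDENTITY_MIN,
) -> list[GeneHit]:
    """Retain hits passing both thresholds, preserving order.

    Boundaries are inclusive: ``evalue <= evalue_max`` and
    ``identity_pct >= identity_min`` are kept.
    """
    return [
        h for h in hits if h.evalue <= evalue_max and h.identity_pct >= identity_min
    ]


def _best_hit_key(h: GeneHit) -> tuple:
    # Total order: highest bitscore, then lowest e-value, then highest
    # identity, then lexicographically smallest og_id.
    return (-h.bitscore, h.evalue, -h.identity_pct, h.og_id)


def assign_best_hits(hits: Sequence[GeneHit]) -> dict[str, str]:
    """Assign each gene to the OG of its best hit.

    Expects already-filtered hits. The tie-break key (bitscore desc,
    e-value asc, identity desc, og_id asc) is total, so the assignment is
    independent of input order. Genes with no hits are absent from the
    result; a gene never contributes fractionally to several OGs.
    """
    best: dict[str, GeneHit] = {}
    for h in hits:
        cur = best.get(h.gene_id)
        if cur is None or _best_hit_key(h) < _best_hit_key(cur):
            best[h.gene_id] = h
    return {g: h.og_id for g, h in best.items()}


def build_profile(assignments: Mapping[str, str], strain_id: str) -> OrthologProfile:
    """Count genes per OG from a gene→OG assignment."""
    counts: dict[str, int] = {}
    for og in assignments.values():
        counts[og] = counts.get(og, 0) + 1
    return OrthologProfile(strain_id=strain_id, counts=counts)


def build_profile_table(
    profiles: Sequence[OrthologProfile],
    min_mapped: int = DEFAULT_MIN_MAPPED,
) -> ProfileTable:
    """Assemble profiles into a count matrix, excluding low-mapping strains.

    Strains with ``total_mapped < min_mapped`` go to ``excluded_strains``;
    columns are the union of OGs over retained strains, in first-appearance
    order; missing cells are 0.
    """
    seen: set[str] = set()
    for p in profiles:
        if p.strain_id in seen:
            raise ValueError(f"duplicate strain_id: {p.strain_id!r}")
        seen.add(p.strain_id)

    retained = [p for p in profiles if p.total_mapped >= min_mapped]
    excluded = [
        (p.strain_id, p.total_mapped) for p in profiles if p.total_mapped < min_mapped
    ]
    if excluded:
        logger.info(
            "build_profile_table: excluded %d strains with < %d mapped genes",
            len(excluded),
            min_mapped,
        )

    og_ids: list[str] = []
    og_index: dict[str, int] = {}
    for p in retained:
        for og in p.counts:
            if og not in og_index:
                og_index[og] = len(og_ids)
                og_ids.append(og)

    counts = np.zeros((len(retained), len(og_ids)), dtype=np.int64)
    for i, p in enumerate(retained):
        for og, c in p.counts.items():
            counts[i, og_index[og]] = c

    return ProfileTable(
        strains=[p.strain_id for p in retained],
        og_ids=og_ids,
        counts=counts,
        excluded_strains=excluded,
    )
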