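"""16S rRNA gene identity and fragment-based average nucleotide identity.

These are the two sequence-identity indices gene-content dissimilarity is
benchmarked against. 16S identity is the mean end-to-end (global)
identity over all cross pairs of 16S copies from the two strains; ANI
follows the ANIb/JSpecies recipe: chop the query genome into consecutive
1020-nt fragments, find each fragment's best local alignment on the
subject, keep fragments aligning at >= 30 % identity over >= 70 % of
their length, and average the retained identities. ANI is directional by
default; :func:`symmetric_ani` averages both directions.

Identity denominators always count gap columns (global-identity
convention). The built-in aligner (see :mod:`gcdiss.align`) targets
desk-scale sequences, not multi-megabase production genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .align import global_align, local_align

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")

#: ANIb convention: fragment length and hit-retention filters.
DEFAULT_FRAGMENT_LEN = 1020
DEFAULT_ANI_IDENTITY_MIN = 30.0
DEFAULT_ANI_COVERAGE_MIN = 0.7


@dataclass(frozen=True)
class AlignmentIdentity:
    """Match/column bookkeeping of one global alignment."""

    matches: int
    columns: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * self.matches / self.columns


@dataclass(frozen=True)
class ANIResult:
    """One-way ANI of a (query, subject) genome pair.

    ``ani_pct`` is None when no fragment passed the identity/coverage
    filters (a defined failure, distinct from an error).
    """

    ani_pct: float | None
    n_fragments_total: int
    n_fragments_used: int
    query_id: str = "query"
    subject_id: str = "subject"

    @property
    def defined(self) -> bool:
        return self.ani_pct is not None


def _check_dna(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = sorted(set(seq) - DNA_ALPHABET)
    if bad:
        raise ValueError(f"{name}: non-DNA characters {bad}")
    return seq


def global_identity(a: str, b: str) -> AlignmentIdentity:
    """Global (end-to-end) identity of two DNA sequences.

    Identity = matches / alignment columns, gap columns included.
    """
    a = _check_dna(a, "sequence a")
    b = _check_dna(b, "sequence b")
    aln = global_align(a, b)
    return AlignmentIdentity(matches=aln.matches, columns=aln.columns)


def rrna_identity(copies_a: list[str], copies_b: list[str]) -> float:
    """Mean global identity (%) over all cross pairs of 16S copies.

    When a genome carries several 16S copies, every copy of one strain is
    compared with every copy of the other (|A| x |B| alignments) and the
    identities are averaged.
    """
    if not copies_a or not copies_b:
        raise ValueError("rrna_identity requires non-empty copy lists")
    idents = [
        global_identity(x, y).identity_pct for x in copies_a for y in copies_b
    ]
    return sum(idents) / len(idents)


def fragment_genome(genome: str, fragment_len: int = DEFAULT_FRAGMENT_LEN) -> list[str]:
    """Consecutive non-overlapping fragments of exactly ``fragment_len``.

    A trailing remainder shorter than ``fragment_len`` is discarded (and
    logged); a genome shorter than one fragment yields an empty list.
    """
    if fragment_len < 1:
        raise ValueError("fragment_len must be >= 1")
    n_full = len(genome) // fragment_len
    remainder = len(genome) - n_full * fragment_len
    if n_full == 0:
        logger.warning(
            "fragment_genome: genome length %d < fragment length %d",
            len(genome),
            fragment_len,
        )
    elif remainder:
        logger.debug("fragment_genome: %d trailing nt discarded", remainder)
    return [
        genome[i * fragment_len : (i + 1) * fragment_len] for i in range(n_full)
    ]


def ani(
    query: str,
    subject: str,
    identity_min: float = DEFAULT_ANI_IDENTITY_MIN,
    coverage_min: float = DEFAULT_ANI_COVERAGE_MIN,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    query_id: str = "query",
    subject_id: str = "subject",
) -> ANIResult:
    """One-way average nucleotide identity, query fragments vs subject.

    Each query fragment is locally aligned to its best location on the
    subject; fragments whose alignment reaches ``identity_min`` percent
    identity over at least ``coverage_min`` of the fragment length are
    retained, and their mean identity is the ANI. Zero retained fragments
    is a defined failure (``ani_pct`` None), not an exception.
    """
    query = _check_dna(query, "query")
    subject = _check_dna(subject, "subject")
    fragments = fragment_genome(query, fragment_len)
    idents = []
    for frag in fragments:
        aln = local_align(frag, subject)
        if aln is None:
            continue
        covered = aln.a_span[1] - aln.a_span[0]
        if covered / len(frag) >= coverage_min and aln.identity_pct >= identity_min:
            idents.append(aln.identity_pct)
    ani_pct = sum(idents) / len(idents) if idents else None
    if ani_pct is None:
        logger.warning(
            "ani: no fragment of %s passed filters against %s", query_id, subject_id
        )
    return ANIResult(
        ani_pct=ani_pct,
        n_fragments_total=len(fragments),
        n_fragments_used=len(idents),
        query_id=query_id,
        subject_id=subject_id,
    )


def symmetric_ani(a: str, b: str, **kwargs) -> float:
    """Mean of the two directional ANI values; error if either undefined."""
    fwd = ani(a, b, query_id="a", subject_id="b", **kwargs)
    rev = ani(b, a, query_id="b", subject_id="a", **kwargs)
    if not fwd.defined or not rev.defined:
        raise ValueError("symmetric ANI undefined: a direction retained no fragments")
    return (fwd.ani_pct + rev.ani_pct) / 2.0


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file as (id, uppercase sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_single_fasta(path: str | Path) -> tuple[str, str]:
    """Read a FASTA expected to hold one record (e.g. a genome)."""
    records = read_fasta(path)
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly 1 record, found {len(records)}")
    return records[0]
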