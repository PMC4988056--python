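"""Seeded synthetic cohorts for exercising the whole pipeline offline.

Real calibrations of gene-content dissimilarity run on thousands of
downloaded complete genomes; these generators stand in for that data at
desk scale. A cohort is built from nested orthologous-group cores: a
universal core shared by every strain, plus order-, family-, genus- and
species-level cores (disjoint OG blocks), plus per-strain private
accessory genes. Because a pair's shared gene mass is then exactly the
mass of the cores its lowest common rank implies, the pairwise
Bray-Curtis dissimilarity of every generated pair falls inside the
designed per-relation ranges by construction — the generator recomputes
the realized matrix and refuses to return one outside its design.

``make_proteomes`` closes the loop at sequence level: every designed gene
count becomes a mutated copy of its OG's reference protein, so running
the toy search + profile builder over the emitted FASTA files must
recover the designed count table. All generators are pure functions of
(design, seed).

The mutation model (uniform substitutions over a 20-letter alphabet,
no indels in proteomes) is deliberately non-biological; it exists to
exercise identity filters and best-hit assignment, not to emulate
evolution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .align import global_align
from .delineation import TaxonomyRecord, TaxonomyTable
from .dissimilarity import DistanceMatrix, pairwise_matrix
from .profiles import OrthologProfile, ProfileTable, build_profile_table

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"


@dataclass(frozen=True)
class CohortDesign:
    """Shape and target dissimilarity structure of a synthetic cohort.

    The five BC ranges give, per rank relation of a strain pair, the
    interval its realized Bray-Curtis dissimilarity must fall in. Their
    midpoints must increase with rank distance (nested cores shrink as
    relatedness drops). ``genes_per_strain`` is the nominal number of
    mapped genes per strain (S_i); the default keeps strains above the
    1000-gene QC threshold. A fraction of core OGs carries two gene
    copies so the index's weighting on duplications is exercised.
    """

    n_orders: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    strains_per_species: int = 3
    genes_per_strain: int = 1200
    intra_species_bc_range: tuple[float, float] = (0.05, 0.18)
    inter_species_bc_range: tuple[float, float] = (0.22, 0.38)
    inter_genus_bc_range: tuple[float, float] = (0.28, 0.42)
    inter_family_bc_range: tuple[float, float] = (0.45, 0.70)
    inter_order_bc_range: tuple[float, float] = (0.75, 0.90)
    duplicated_og_fraction: float = 0.2
    seed: int = 0

    @property
    def n_strains(self) -> int:
        return (
            self.n_orders
            * self.families_per_order
            * self.genera_per_family
            * self.species_per_genus
            * self.strains_per_species
        )

    def validate(self) -> None:
        if self.n_strains <= 0:
            raise ValueError("cohort design has zero strains")
        ranges = [
            self.intra_species_bc_range,
            self.inter_species_bc_range,
            self.inter_genus_bc_range,
            self.inter_family_bc_range,
            self.inter_order_bc_range,
        ]
        for lo, hi in ranges:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"BC range outside [0,1] or inverted: ({lo}, {hi})")
        mids = [(lo + hi) / 2 for lo, hi in ranges]
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise ValueError(
                "per-relation BC range midpoints must increase with rank "
                f"distance, got {mids}"
            )


@dataclass
class SyntheticCohort:
    """A generated cohort: taxonomy, count table and realized BC matrix."""

    design: CohortDesign
    taxonomy: TaxonomyTable
    table: ProfileTable
    realized_bc: DistanceMatrix


def _strain_layout(design: CohortDesign):
    """Yield (strain_id, order, family, genus, species) tuples."""
    for o, f, g, s, t in itertools.product(
        range(design.n_orders),
        range(design.families_per_order),
        range(design.genera_per_family),
        range(design.species_per_genus),
        range(design.strains_per_species),
    ):
        order = f"o{o + 1}"
        family = f"{order}.f{f + 1}"
        genus = f"{family}.g{g + 1}"
        species = f"{genus}.s{s + 1}"
        strain = f"{species}.t{t + 1}"
        yield strain, order, family, genus, species


def make_taxonomy(design: CohortDesign) -> TaxonomyTable:
    """Balanced multi-rank taxonomy with unique, nested strain ids."""
    design.validate()
    return TaxonomyTable(
        {
            strain: TaxonomyRecord(species, genus, family, order)
            for strain, order, family, genus, species in _strain_layout(design)
        }
    )


class _OGAllocator:
    """Hands out disjoint blocks of OG ids with per-OG copy numbers.

    Every ``1/duplicated_og_fraction``-th OG carries two gene copies; a
    block of target gene *mass* therefore uses fewer OGs than genes.
    """

    def __init__(self, dup_fraction: float):
        self._next = 0
        self._period = round(1 / dup_fraction) if dup_fraction > 0 else 0

    def block(self, mass: int) -> dict[str, int]:
        counts: dict[str, int] = {}
        remaining = mass
        while remaining > 0:
            self._next += 1
            c = 2 if self._period and self._next % self._period == 0 else 1
            c = min(c, remaining)
            counts[f"OG{self._next:06d}"] = c
            remaining -= c
        return counts

    def singletons(self, n: int, prefix: str = "OG") -> dict[str, int]:
        counts = {}
        for _ in range(n):
            self._next += 1
            counts[f"{prefix}{self._next:06d}"] = 1
        return counts


def _core_masses(design: CohortDesign) -> tuple[dict[str, int], tuple[int, int]]:
    """Solve nested core gene masses and the private-size jitter interval."""
    s = design.genes_per_strain

    def mid(r):
        return (r[0] + r[1]) / 2

    k_root = round(s * (1 - mid(design.inter_order_bc_range)))
    k_order = round(s * (1 - mid(design.inter_family_bc_range)))
    k_family = round(s * (1 - mid(design.inter_genus_bc_range)))
    k_genus = round(s * (1 - mid(design.inter_species_bc_range)))
    a_mid = round(s * mid(design.intra_species_bc_range))
    k_species = s - a_mid
    if not 0 <= k_root <= k_order <= k_family <= k_genus <= k_species:
        raise ValueError("infeasible BC ranges: nested core masses not monotone")

    lo, hi = design.intra_species_bc_range
    if hi >= 1.0:
        raise ValueError("intra-species BC range must stay below 1")
    a_min = lo * k_species / (1 - lo)
    a_max = hi * k_species / (1 - hi)
    if a_max < a_min:
        raise ValueError("infeasible intra-species BC range")
    # jitter over the middle half of the feasible interval, so realized
    # values sit safely inside the designed range
    quarter = (a_max - a_min) / 4
    a_lo = math.ceil(a_min + quarter)
    a_hi = math.floor(a_max - quarter)
    if a_hi < a_lo:
        a_lo = a_hi = round((a_min + a_max) / 2)
    masses = {
        "root": k_root,
        "order": k_order - k_root,
        "family": k_family - k_order,
        "genus": k_genus - k_family,
        "species": k_species - k_genus,
    }
    return masses, (a_lo, a_hi)


def _relation_range(design: CohortDesign, rel_value: str) -> tuple[float, float]:
    return {
        "intra_species": design.intra_species_bc_range,
        "intra_genus_inter_species": design.inter_species_bc_range,
        "intra_family_inter_genus": design.inter_genus_bc_range,
        "intra_order_inter_family": design.inter_family_bc_range,
        "inter_order": design.inter_order_bc_range,
    }[rel_value]


def make_cohort(design: CohortDesign | None = None) -> SyntheticCohort:
    """Generate taxonomy + profiles and verify the realized BC structure."""
    design = design or CohortDesign()
    design.validate()
    masses, (a_lo, a_hi) = _core_masses(design)
    rng = np.random.default_rng(design.seed)
    alloc = _OGAllocator(design.duplicated_og_fraction)

    root_core = alloc.block(masses["root"])
    cores: dict[str, dict[str, int]] = {}  # taxon name -> its own block

    profiles: list[OrthologProfile] = []
    taxonomy = make_taxonomy(design)
    for strain, order, family, genus, species in _strain_layout(design):
        for taxon, level in ((order, "order"), (family, "family"), (genus, "genus"), (species, "species")):
            if taxon not in cores:
                cores[taxon] = alloc.block(masses[level])
        counts: dict[str, int] = dict(root_core)
        for taxon in (order, family, genus, species):
            counts.update(cores[taxon])
        n_private = int(rng.integers(a_lo, a_hi + 1)) if a_hi > 0 else 0
        counts.update(alloc.singletons(n_private))
        profiles.append(OrthologProfile(strain, {k: v for k, v in counts.items() if v > 0}))

    table = build_profile_table(profiles, min_mapped=0)
    realized = pairwise_matrix(table)

    # By-construction guarantee, re-checked: every pair inside its range.
    for i, j in itertools.combinations(range(len(table.strains)), 2):
        a, b = table.strains[i], table.strains[j]
        rel = taxonomy.relation(a, b)
        lo, hi = _relation_range(design, rel.value)
        bc = realized.values[i, j]
        if not lo - 1e-12 <= bc <= hi + 1e-12:
            raise ValueError(
                f"realized BC {bc:.4f} for pair ({a}, {b}) outside designed "
                f"range ({lo}, {hi}) for {rel.value}; infeasible design"
            )
    return SyntheticCohort(design, taxonomy, table, realized)


def make_profiles(design: CohortDesign | None = None) -> tuple[ProfileTable, DistanceMatrix]:
    """Profile table + realized BC matrix (see :func:`make_cohort`)."""
    cohort = make_cohort(design)
    return cohort.table, cohort.realized_bc


# ---------------------------------------------------------------------------
# Sequence-level fixtures


@dataclass
class ProteomeSet:
    """Toy ortholog database + per-strain proteomes + gene→OG truth map."""

    db: list[tuple[str, str]]  # (og_id, reference protein)
    proteomes: dict[str, list[tuple[str, str]]]  # strain -> [(gene_id, seq)]
    truth: dict[str, str]  # gene_id -> og_id
    mutation_rate: float

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "og_db.faa", "w") as fh:
            for og, seq in self.db:
                fh.write(f">{og}\n{seq}\n")
        for strain, genes in self.proteomes.items():
            safe = strain.replace("/", "_")
            with open(outdir / f"{safe}.faa", "w") as fh:
                for gid, seq in genes:
                    fh.write(f">{gid}\n{seq}\n")
        with open(outdir / "truth_map.tsv", "w") as fh:
            for gid, og in self.truth.items():
                fh.write(f"{gid}\t{og}\n")


def _mutate(seq: str, rate: float, rng: np.random.Generator, alphabet: str) -> str:
    if rate == 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [c for c in alphabet if c != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def make_proteomes(
    table: ProfileTable,
    db_size: int | None = None,
    mutation_rate: float = 0.05,
    seed: int = 0,
    protein_len_range: tuple[int, int] = (80, 160),
) -> ProteomeSet:
    """Emit sequence-level inputs whose designed recovery is the table.

    Each OG gets one random reference protein; each designed gene copy is
    an independently mutated variant of its OG's reference (per-residue
    substitution probability ``mutation_rate``, no indels). ``db_size``
    larger than the table's OG count adds decoy references that no gene
    derives from. Searching the proteomes against the database and
    applying the best-hit assignment rules recovers the designed counts.
    """
    if not 0.0 <= mutation_rate <= 0.5:
        raise ValueError(
            "mutation_rate must be in [0, 0.5] so hit identities stay above "
            "the 30 % retention filter"
        )
    rng = np.random.default_rng(seed)
    og_ids = list(table.og_ids)
    if db_size is None:
        db_size = len(og_ids)
    if db_size < len(og_ids):
        raise ValueError("db_size smaller than the number of designed OGs")

    def random_protein() -> str:
        ln = int(rng.integers(protein_len_range[0], protein_len_range[1] + 1))
        return "".join(
            AA_ALPHABET[i] for i in rng.integers(len(AA_ALPHABET), size=ln)
        )

    db = [(og, random_protein()) for og in og_ids]
    db += [(f"DECOY{i:05d}", random_protein()) for i in range(db_size - len(og_ids))]
    refs = dict(db)

    proteomes: dict[str, list[tuple[str, str]]] = {}
    truth: dict[str, str] = {}
    for si, strain in enumerate(table.strains):
        genes: list[tuple[str, str]] = []
        k = 0
        for oi, og in enumerate(og_ids):
            for _ in range(int(table.counts[si, oi])):
                k += 1
                gid = f"{strain}|g{k:05d}"
                genes.append((gid, _mutate(refs[og], mutation_rate, rng, AA_ALPHABET)))
                truth[gid] = og
        proteomes[strain] = genes
    return ProteomeSet(db=db, proteomes=proteomes, truth=truth, mutation_rate=mutation_rate)


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def toy_search(
    genes: list[tuple[str, str]],
    db: list[tuple[str, str]],
    kmer_prescreen: int = 4,
) -> list[str]:
    """Align genes against a toy ortholog database; emit 12-column hit lines.

    A shared-k-mer prescreen (like the word heuristics of real search
    tools) limits full global alignments to plausible pairs. Identity is
    matches over alignment columns; the e-value is a Karlin-Altschul-style
    plausibility score derived from the alignment score and database size,
    adequate for threshold plumbing, not a real statistic.
    """
    db_letters = sum(len(s) for _, s in db)
    db_kmers = [(og, seq, _kmers(seq, kmer_prescreen)) for og, seq in db]
    lines = []
    for gid, gseq in genes:
        gk = _kmers(gseq, kmer_prescreen)
        for og, tseq, tk in db_kmers:
            if gk.isdisjoint(tk):
                continue
            aln = global_align(gseq, tseq)
            bitscore = max(aln.score, 0.0)
            evalue = min(db_letters * len(gseq) * 2.0 ** (-bitscore), 10.0)
            lines.append(
                "\t".join(
                    [
                        gid,
                        og,
                        f"{aln.identity_pct:.2f}",
                        str(aln.columns),
                        str(aln.columns - aln.matches),
                        "0",
                        "1",
                        str(len(gseq)),
                        "1",
                        str(len(tseq)),
                        f"{evalue:.3g}",
                        f"{bitscore:.1f}",
                    ]
                )
            )
    return lines


def make_genome_pair(
    length: int, substitution_rate: float, seed: int = 0
) -> tuple[str, str]:
    """A random genome and a copy with independent per-site substitutions."""
    if not 0.0 <= substitution_rate < 0.75:
        raise ValueError("substitution_rate must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    a = "".join(DNA[i] for i in rng.integers(4, size=length))
    b = _mutate(a, substitution_rate, rng, DNA)
    return a, b


def make_rrna_copies(
    n_copies: int, length: int = 1500, divergence: float = 0.0, seed: int = 0,
    template: str | None = None,
) -> list[str]:
    """Mutated copies of a (possibly supplied) 16S-like template sequence."""
    rng = np.random.default_rng(seed)
    if template is None:
        template = "".join(DNA[i] for i in rng.integers(4, size=length))
    return [_mutate(template, divergence, rng, DNA) for _ in range(n_copies)]
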