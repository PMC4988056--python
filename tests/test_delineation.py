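import itertools
import math

import numpy as np
import pytest

from gcdiss.delineation import (
    CutoffConfig,
    RankRelation,
    TaxonomyRecord,
    TaxonomyTable,
    binned_distribution,
    classify_matrix,
    classify_pair,
    confusion_at_cutoff,
    index_agreement,
    rank_relations,
)
from gcdiss.dissimilarity import DistanceMatrix
from gcdiss.synth import CohortDesign, make_cohort, make_taxonomy


def dm_from_upper(labels, entries):
    """Build a DistanceMatrix from a dict of unordered-pair values."""
    n = len(labels)
    d = np.zeros((n, n))
    for (a, b), v in entries.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(labels, d)


class TestClassifyPair:
    def test_below_species_cutoff(self):
        call = classify_pair(0.15)
        assert call.same_species_predicted and call.same_family_predicted

    def test_between_cutoffs(self):
        call = classify_pair(0.35)
        assert not call.same_species_predicted and call.same_family_predicted

    def test_boundary_is_strict(self):
        call = classify_pair(0.2)
        assert not call.same_species_predicted
        assert classify_pair(0.4).same_family_predicted is False

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(1.2)

    def test_species_implies_family(self):
        for bc in np.linspace(0, 1, 21):
            call = classify_pair(float(bc))
            assert (not call.same_species_predicted) or call.same_family_predicted

    def test_invalid_cutoff_config(self):
        with pytest.raises(ValueError):
            CutoffConfig(species_cutoff=0.5, family_cutoff=0.4)


class TestRankRelations:
    def test_basic_relations(self, two_species_taxonomy):
        tax = two_species_taxonomy
        assert tax.relation("s1", "s2") is RankRelation.INTRA_SPECIES
        assert tax.relation("s1", "s3") is RankRelation.INTRA_GENUS_INTER_SPECIES

    def test_blank_rank_is_undecidable(self):
        tax = TaxonomyTable(
            {
                "a": TaxonomyRecord("", "g", "f", "o"),
                "b": TaxonomyRecord("sp", "g", "f", "o"),
            }
        )
        assert tax.relation("a", "b") is None

    def test_missing_strain_named_in_error(self, two_species_taxonomy):
        dm = dm_from_upper(["s1", "zz"], {("s1", "zz"): 0.5})
        with pytest.raises(KeyError, match="zz"):
            rank_relations(dm, two_species_taxonomy)

    def test_counts_match_design_combinatorics(self):
        design = CohortDesign(
            n_orders=2,
            families_per_order=1,
            genera_per_family=2,
            species_per_genus=2,
            strains_per_species=2,
            genes_per_strain=300,
            seed=3,
        )
        cohort = make_cohort(design)
        rels = rank_relations(cohort.realized_bc, cohort.taxonomy)
        counts = {rel: 0 for rel in RankRelation}
        for rel in rels.values():
            counts[rel] += 1
        n_strains = design.n_strains  # 16
        per_species = design.strains_per_species
        n_species = n_strains // per_species
        # hand combinatorics for the balanced layout
        intra_sp = n_species * math.comb(per_species, 2)
        per_genus = per_species * design.species_per_genus
        intra_genus = (n_strains // per_genus) * math.comb(per_genus, 2) - intra_sp
        per_family = per_genus * design.genera_per_family
        intra_family = (n_strains // per_family) * math.comb(per_family, 2) - intra_sp - intra_genus
        inter_order = math.comb(n_strains, 2) - intra_sp - intra_genus - intra_family
        assert counts[RankRelation.INTRA_SPECIES] == intra_sp
        assert counts[RankRelation.INTRA_GENUS_INTER_SPECIES] == intra_genus
        assert counts[RankRelation.INTRA_FAMILY_INTER_GENUS] == intra_family
        assert counts[RankRelation.INTRA_ORDER_INTER_FAMILY] == 0  # one family/order
        assert counts[RankRelation.INTER_ORDER] == inter_order


class TestBinnedDistribution:
    def test_all_intra_in_first_bin(self, two_species_taxonomy):
        labels = ["s1", "s2", "s3", "s4"]
        entries = {p: 0.1 for p in itertools.combinations(labels, 2)}
        dm = dm_from_upper(labels, entries)
        d = binned_distribution(dm, two_species_taxonomy, RankRelation.INTRA_SPECIES,
                                bins=(0, 0.2, 0.4, 1.0))
        np.testing.assert_allclose(d.fractions, [1, 0, 0])

    def test_fractions_sum_to_one_and_match_counting(self, default_cohort):
        c = default_cohort
        rels = rank_relations(c.realized_bc, c.taxonomy)
        for rel in RankRelation:
            d = binned_distribution(c.realized_bc, c.taxonomy, rel)
            if d.empty:
                continue
            assert d.fractions.sum() == pytest.approx(1.0, abs=1e-12)
            vals = [c.realized_bc.get(a, b) for (a, b), r in rels.items() if r == rel]
            # direct counting per bin (left-closed, last bin closed)
            edges = d.bin_edges
            for k in range(len(edges) - 1):
                if k < len(edges) - 2:
                    expect = sum(edges[k] <= v < edges[k + 1] for v in vals)
                else:
                    expect = sum(edges[k] <= v <= edges[k + 1] for v in vals)
                assert d.counts[k] == expect

    def test_empty_relation_flagged(self, two_species_taxonomy):
        labels = ["s1", "s2", "s3", "s4"]
        dm = dm_from_upper(labels, {p: 0.1 for p in itertools.combinations(labels, 2)})
        d = binned_distribution(dm, two_species_taxonomy, RankRelation.INTER_ORDER)
        assert d.empty and d.fractions.size == len(d.bin_edges) - 1

    def test_bad_bins_rejected(self, two_species_taxonomy):
        labels = ["s1", "s2", "s3", "s4"]
        dm = dm_from_upper(labels, {p: 0.1 for p in itertools.combinations(labels, 2)})
        with pytest.raises(ValueError):
            binned_distribution(dm, two_species_taxonomy, RankRelation.INTRA_SPECIES,
                                bins=(0, 0.5, 0.4, 1))


class TestConfusionAtCutoff:
    def test_perfectly_separated(self, default_cohort):
        c = default_cohort
        conf = confusion_at_cutoff(c.realized_bc, c.taxonomy, 0.2, "species")
        assert conf.tpr == 1.0 and conf.fpr == 0.0

    def test_cutoff_one_calls_everything_same(self, default_cohort):
        c = default_cohort
        conf = confusion_at_cutoff(c.realized_bc, c.taxonomy, 1.0, "species")
        assert conf.tpr == 1.0 and conf.fpr == 1.0

    def test_designed_false_positive_fraction(self, two_species_taxonomy):
        # 4 inter-species pairs; exactly one placed below the cutoff
        labels = ["s1", "s2", "s3", "s4"]
        entries = {
            ("s1", "s2"): 0.05,
            ("s3", "s4"): 0.05,
            ("s1", "s3"): 0.10,  # the designed false positive
            ("s1", "s4"): 0.50,
            ("s2", "s3"): 0.50,
            ("s2", "s4"): 0.50,
        }
        dm = dm_from_upper(labels, entries)
        conf = confusion_at_cutoff(dm, two_species_taxonomy, 0.2, "species")
        assert conf.fpr == pytest.approx(1 / 4)
        assert conf.tpr == 1.0
        assert (conf.n_true_pairs, conf.n_false_pairs) == (2, 4)

    def test_no_true_pairs_is_an_error(self):
        tax = TaxonomyTable(
            {
                "a": TaxonomyRecord("spA", "g", "f", "o"),
                "b": TaxonomyRecord("spB", "g", "f", "o"),
            }
        )
        dm = dm_from_upper(["a", "b"], {("a", "b"): 0.5})
        with pytest.raises(ValueError, match="TPR undefined"):
            confusion_at_cutoff(dm, tax, 0.2, "species")

    def test_monotone_in_cutoff(self, default_cohort):
        c = default_cohort
        prev = (0.0, 0.0)
        for cutoff in (0.1, 0.2, 0.3, 0.5, 0.8, 1.0):
            conf = confusion_at_cutoff(c.realized_bc, c.taxonomy, cutoff, "family")
            assert conf.tpr >= prev[0] and conf.fpr >= prev[1]
            prev = (conf.tpr, conf.fpr)

    def test_consistent_with_classify_matrix(self, default_cohort):
        c = default_cohort
        calls = classify_matrix(c.realized_bc)
        same_sp = {
            frozenset(call.pair): call.same_species_predicted for call in calls
        }
        n_called_same = 0
        n_true = 0
        for (a, b), rel in rank_relations(c.realized_bc, c.taxonomy).items():
            if rel is RankRelation.INTRA_SPECIES:
                n_true += 1
                n_called_same += same_sp[frozenset((a, b))]
        conf = confusion_at_cutoff(c.realized_bc, c.taxonomy, 0.2, "species")
        assert conf.n_true_pairs == n_true
        assert conf.tpr == pytest.approx(n_called_same / n_true)


class TestIndexAgreement:
    def test_identical_perfect_predictors(self):
        truth = {("a", "b"): True, ("a", "c"): False}
        assert index_agreement(truth, dict(truth), dict(truth), dict(truth)) == 1.0

    def test_inverted_index_fails_positive_pairs(self):
        truth = {("a", "b"): True, ("a", "c"): True}
        inverted = {p: not v for p, v in truth.items()}
        assert index_agreement(truth, dict(truth), inverted) == 0.0

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(5)
        pairs = [(f"s{i}", f"s{j}") for i, j in itertools.combinations(range(8), 2)]
        truth = {p: bool(rng.integers(2)) for p in pairs}
        calls = [
            {p: bool(rng.integers(2)) for p in pairs} for _ in range(3)
        ]
        expected = sum(
            all(c[p] == truth[p] for c in calls) for p in pairs
        ) / len(pairs)
        assert index_agreement(truth, *calls) == pytest.approx(expected)

    def test_mismatched_pair_sets_rejected(self):
        truth = {("a", "b"): True}
        with pytest.raises(ValueError):
            index_agreement(truth, {("a", "c"): True})


def test_make_taxonomy_roundtrip_tsv(tmp_path):
    tax = make_taxonomy(CohortDesign(seed=0))
    path = tmp_path / "tax.tsv"
    tax.to_tsv(path)
    back = TaxonomyTable.from_tsv(path)
    assert back.records == tax.records
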