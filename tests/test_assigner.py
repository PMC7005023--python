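"""Barcode distillation, K2P distances, threshold assignment, NJ trees."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligocoi.assigner import (
    InsufficientOverlap,
    Otu,
    apply_morphology_overrides,
    assign_lineage,
    cluster_new_lineages,
    cluster_otus,
    dereplicate,
    dominant_otu,
    k2p_distance,
    nj_tree,
    nj_with_bootstrap,
    place_new_lineage,
    remove_chimeras,
    SpecimenAssignment,
)
from oligocoi.refdb import ReferenceDatabase, ReferenceRecord

from _oracles import (
    k2p_brute_force,
    nj_bipartitions,
    random_additive_tree,
    topology_bipartitions,
)
from conftest import make_record


def _mutate(seq, positions, transition=True):
    trans = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv = {"A": "C", "C": "A", "G": "T", "T": "G"}
    out = list(seq)
    for p in positions:
        out[p] = (trans if transition else tv)[out[p]]
    return "".join(out)


class TestDereplicate:
    def test_counting_and_order(self):
        assert dereplicate(["ACGT", "ACGA", "ACGT", "ACGT"]) == [("ACGT", 3), ("ACGA", 1)]

    def test_empty(self):
        assert dereplicate([]) == []

    @given(st.lists(st.sampled_from(["AAAA", "ACGT", "TTTT"]), max_size=200))
    @settings(deadline=None, max_examples=25)
    def test_counts_conserved(self, seqs):
        assert sum(c for _, c in dereplicate(seqs)) == len(seqs)


class TestChimeras:
    def test_perfect_splice_removed(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), 200))
        b = _mutate(a, range(0, 200, 8))  # 25 diffs from a
        chimera = a[:100] + b[100:]
        uniques = [(a, 50), (b, 50), (chimera, 5)]
        assert remove_chimeras(uniques) == [(a, 50), (b, 50)]

    def test_clean_data_untouched(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 200))
        b = _mutate(a, range(0, 200, 5))
        uniques = [(a, 40), (b, 20)]
        assert remove_chimeras(uniques) == uniques

    def test_low_abundance_parent_not_eligible(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), 200))
        b = _mutate(a, range(0, 200, 8))
        chimera = a[:100] + b[100:]
        # parents are NOT 2x more abundant: query must be retained
        uniques = [(a, 8), (b, 8), (chimera, 5)]
        assert (chimera, 5) in remove_chimeras(uniques)

    def test_simulated_chimeras_detected_without_parent_loss(self, small_db):
        # library-wide dereplication so both chimera parents are abundant
        from oligocoi.readproc import demultiplex, merge_pairs
        from oligocoi.synthetic_data import (
            CommunityProfile,
            SimulationConfig,
            generate_reads,
            make_tag_scheme,
            simulate_site_community,
        )

        profile = CommunityProfile("S1", {r.lineage_id: 1.0 for r in small_db}, "stream")
        truth = simulate_site_community(profile, 10, seed=5, db=small_db)
        scheme = make_tag_scheme("S1", [s for s, _ in truth.specimens], seed=5)
        config = SimulationConfig(reads_per_specimen=60, per_base_error=0.0, chimera_rate=0.05)
        pairs, read_truth = generate_reads(truth, scheme, config, seed=5)
        demux = demultiplex(pairs, scheme)
        merged_all = []
        for sid, reads in demux.assigned.items():
            merged, _ = merge_pairs(reads, specimen_id=sid)
            merged_all.extend(m.sequence for m in merged)
        templates = set(truth.amplicons.values())
        uniques = dereplicate(merged_all)
        chimeric_uniques = {s for s, _ in uniques if s not in templates}
        assert chimeric_uniques
        retained = {s for s, _ in remove_chimeras(uniques)}
        # no true template lost, >= 90% of chimeric uniques removed
        assert templates <= retained
        removed = chimeric_uniques - retained
        assert len(removed) / len(chimeric_uniques) >= 0.90


class TestOtus:
    def test_one_mismatch_joins(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 313))
        b = _mutate(a, [7])
        otus = cluster_otus([(a, 30), (b, 5)])
        assert len(otus) == 1
        assert otus[0].member_count == 35
        assert otus[0].representative == a

    def test_ten_percent_divergence_splits(self):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 313))
        b = _mutate(a, range(0, 310, 10))  # 31 diffs -> identity ~0.901
        otus = cluster_otus([(a, 30), (b, 5)])
        assert len(otus) == 2

    def test_singleton(self):
        otus = cluster_otus([("ACGT" * 30, 7)])
        assert len(otus) == 1 and otus[0].representative == "ACGT" * 30


class TestDominantOtu:
    def test_highest_count_wins(self):
        otus = [Otu("CCCC", 120), Otu("AAAA", 3)]
        assert dominant_otu(otus) == "CCCC"

    def test_min_reads_failure(self):
        assert dominant_otu([Otu("AAAA", 5)], min_reads=10) is None

    def test_tie_breaks_lexicographically(self):
        assert dominant_otu([Otu("TTTT", 50), Otu("AAAA", 50)]) == "AAAA"


class TestK2P:
    def test_identical_sequences(self):
        d = k2p_distance("ACGT" * 50, "ACGT" * 50)
        assert d.p_transitions == 0 and d.q_transversions == 0 and d.k2p == 0

    def test_known_value(self):
        # 300 sites, 30 transitions, 15 transversions: P=0.1, Q=0.05
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), 300))
        b = _mutate(_mutate(a, range(0, 300, 10), transition=True),
                    range(5, 300, 20), transition=False)
        d = k2p_distance(a, b)
        assert d.p_transitions == pytest.approx(0.1)
        assert d.q_transversions == pytest.approx(0.05)
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert d.k2p == pytest.approx(expected, abs=1e-12)
        assert d.k2p == pytest.approx(0.1701812, abs=1e-6)

    def test_symmetry_random_pairs(self, rng):
        for _ in range(50):
            a = "".join(rng.choice(list("ACGT"), 200))
            b = _mutate(a, rng.choice(200, size=rng.integers(0, 60), replace=False))
            assert k2p_distance(a, b).k2p == k2p_distance(b, a).k2p

    def test_saturation_is_infinite(self):
        a = "A" * 150
        b = "C" * 150  # all transversions: Q = 1
        assert math.isinf(k2p_distance(a, b).k2p)

    def test_insufficient_overlap_raises(self):
        with pytest.raises(InsufficientOverlap):
            k2p_distance("ACGT" * 10, "ACGT" * 10)

    def test_n_positions_excluded(self):
        a = "ACGT" * 50
        b = "N" * 4 + a[4:]
        assert k2p_distance(a, b).compared_sites == 196

    def test_unequal_lengths_end_trimmed(self):
        a = "ACGTTGCA" * 40  # 320
        b = a[5:315]  # 310, offset 5
        d = k2p_distance(a, b)
        assert d.k2p == 0.0

    def test_monotone_in_transition_count(self):
        rng = np.random.default_rng(6)
        a = "".join(rng.choice(list("ACGT"), 313))
        last = -1.0
        for k in range(0, 100, 10):
            d = k2p_distance(a, _mutate(a, range(k))).k2p
            assert d > last
            last = d

    def test_exceeds_p_distance(self, rng):
        # the correction can only stretch the observed proportion of diffs
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 250))
            k = int(rng.integers(1, 70))
            b = _mutate(a, rng.choice(250, size=k, replace=False))
            assert k2p_distance(a, b).k2p >= k / 250 - 1e-12


def _db_with(*records):
    return ReferenceDatabase(records=list(records))


class TestAssignLineage:
    def test_within_default_threshold_assigned(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 313))
        db = _db_with(make_record("L1", genus="Tubifex", seq=seq))
        barcode = _mutate(seq, range(26))  # 26 transitions: K2P ~ 0.0908
        a = assign_lineage(barcode, db)
        assert a.route == "local_db" and a.lineage_id == "L1"
        assert 0.08 < a.distance < 0.10

    def test_nais_override_blocks_marginal_match(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 313))
        db = _db_with(
            make_record("L1", genus="Nais", group="naidinae", sensitive=True,
                        taxon_name="Nais sp1", seq=seq)
        )
        barcode = _mutate(seq, range(26))  # 0.0908 >= 0.08 -> no match
        a = assign_lineage(barcode, db)
        assert a.route == "unassigned" and a.lineage_id is None

    def test_identical_barcode_distance_zero(self, small_db):
        rec = small_db.records[0]
        a = assign_lineage(rec.sequence, small_db)
        assert a.lineage_id == rec.lineage_id and a.distance == 0.0

    def test_secondary_database_fallback(self, rng):
        seq_a = "".join(rng.choice(list("ACGT"), 313))
        seq_b = _mutate(seq_a, range(0, 313, 2), transition=False)  # far away
        local = _db_with(make_record("L1", seq=seq_a))
        secondary = _db_with(make_record("G1", seq=seq_b))
        a = assign_lineage(_mutate(seq_b, [0]), local, secondary=secondary)
        assert a.route == "secondary_db" and a.lineage_id == "G1"

    def test_morphology_override(self):
        a = SpecimenAssignment("SP1", "ACGT" * 79, None, None, "unassigned")
        (out,) = apply_morphology_overrides([a], {"SP1": "Tubifex tubifex"})
        assert out.route == "morphology" and out.lineage_id == "Tubifex tubifex"


class TestNewLineages:
    def _unassigned(self, sid, barcode):
        return SpecimenAssignment(sid, barcode, None, None, "unassigned")

    def test_close_barcodes_share_label(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 313))
        pair = [self._unassigned("a", seq), self._unassigned("b", _mutate(seq, range(6)))]
        out = cluster_new_lineages(pair, _db_with(make_record("L1")))
        assert out[0].lineage_id == out[1].lineage_id == "NEW_01"

    def test_distant_barcodes_get_distinct_labels(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 313))
        far = _mutate(seq, range(0, 313, 4), transition=False)
        out = cluster_new_lineages(
            [self._unassigned("a", seq), self._unassigned("b", far)],
            _db_with(make_record("L1")),
        )
        assert {o.lineage_id for o in out} == {"NEW_01", "NEW_02"}

    def test_labels_stable_across_reruns(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 313)) for _ in range(4)]
        items = [self._unassigned(f"s{i}", s) for i, s in enumerate(seqs)]
        db = _db_with(make_record("L1"))
        first = [(o.specimen_id, o.lineage_id) for o in cluster_new_lineages(items, db)]
        second = [(o.specimen_id, o.lineage_id) for o in cluster_new_lineages(items, db)]
        assert first == second

    def test_assigned_input_rejected(self):
        good = SpecimenAssignment("a", "ACGT" * 79, "L1", 0.01, "local_db")
        with pytest.raises(ValueError):
            cluster_new_lineages([good], _db_with(make_record("L1")))


class TestNeighbourJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(d, ["a", "b", "c"])
        lengths = {child.name: length for child, length in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    @pytest.mark.parametrize("n_taxa", [4, 5, 6])
    def test_additive_matrices_recover_topology(self, n_taxa):
        rng = np.random.default_rng(n_taxa)
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(15):
            topo, dist = random_additive_tree(labels, rng)
            tree = nj_tree(dist, labels)
            assert nj_bipartitions(tree, labels) == topology_bipartitions(topo, labels)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(8)
        labels = [f"t{i}" for i in range(6)]
        _, dist = random_additive_tree(labels, rng)
        ours = nj_bipartitions(nj_tree(dist, labels), labels)
        sk_tree = skbio_nj(DistanceMatrix(dist, labels))
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if labels[0] in side:
                side = frozenset(labels) - side
            if 1 < len(side) < len(labels) - 1:
                theirs.add(side)
        assert ours == theirs

    def test_invalid_matrix_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="invalid distance matrix"):
            nj_tree(bad, ["a", "b"])
        asym = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="invalid distance matrix"):
            nj_tree(asym, ["a", "b", "c"])

    def test_bootstrap_on_invariant_alignment_gives_full_support(self):
        # every column identical: every replicate rebuilds the same tree
        seqs = {
            "t1": "A" * 120, "t2": "G" * 120, "t3": "C" * 120,
            "t4": "T" * 120, "t5": "A" * 120,
        }
        tree = nj_with_bootstrap(seqs, n_replicates=50, seed=0)
        supports = [node.support for node in tree.bipartitions().values()]
        assert supports and all(s == 1.0 for s in supports)

    def test_newick_output_parses(self):
        dendropy = pytest.importorskip("dendropy")
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        newick = nj_tree(d, ["a", "b", "c"]).to_newick()
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {leaf.taxon.label for leaf in tree.leaf_node_iter()} == {"a", "b", "c"}


class TestPlacement:
    def _placement_db(self, rng):
        # three family clusters: tight Enchytraeidae near the root, Tubificinae
        # and Naidinae ~20% away on disjoint mutation sets
        root = "".join(rng.choice(list("ACGT"), 313))
        positions = rng.permutation(313)
        t_anchor = _mutate(root, positions[:60], transition=False)
        n_anchor = _mutate(root, positions[60:120], transition=False)
        e_anchor = _mutate(root, positions[120:160], transition=False)
        records = [
            make_record("E1", genus="Cognettia", group="enchytraeidae", sensitive=True,
                        taxon_name="Cognettia sp1", seq=_mutate(e_anchor, range(0, 313, 100))),
            make_record("E2", genus="Cognettia", group="enchytraeidae", sensitive=True,
                        taxon_name="Cognettia sp2", seq=_mutate(e_anchor, range(1, 313, 90))),
            make_record("E3", genus="Cognettia", group="enchytraeidae", sensitive=True,
                        taxon_name="Cognettia sp3", seq=_mutate(e_anchor, range(2, 313, 80))),
            make_record("T1", genus="Tubifex", seq=t_anchor),
            make_record("T2", genus="Limnodrilus", group="tubificinae_nohair",
                        taxon_name="Limnodrilus sp1", seq=_mutate(t_anchor, range(4, 313, 25))),
            make_record("N1", genus="Nais", group="naidinae", sensitive=True,
                        taxon_name="Nais sp1", seq=n_anchor),
            make_record("N2", genus="Nais", group="naidinae", sensitive=True,
                        taxon_name="Nais sp2", seq=_mutate(n_anchor, range(5, 313, 25))),
        ]
        return _db_with(*records), root, e_anchor, positions

    def test_query_near_enchytraeids_placed_in_family(self, rng):
        db, _, e_anchor, _ = self._placement_db(rng)
        query = _mutate(e_anchor, range(3, 313, 35))  # ~3% inside the E clade
        family = place_new_lineage(query, db, n_replicates=100, seed=1)
        assert family == "Enchytraeidae"

    def test_rootward_query_incertae_sedis(self, rng):
        # query ~20% from the root on its own mutation set: roughly equidistant
        # from all three family clusters, so no attachment is well supported
        db, root, _, positions = self._placement_db(rng)
        query = _mutate(root, positions[180:240], transition=False)
        family = place_new_lineage(query, db, support_min=0.999, n_replicates=100, seed=1)
        assert family == "incertae sedis"

    def test_placement_deterministic(self, rng):
        db, _, e_anchor, _ = self._placement_db(rng)
        query = _mutate(e_anchor, range(3, 313, 35))
        a = place_new_lineage(query, db, n_replicates=60, seed=9)
        b = place_new_lineage(query, db, n_replicates=60, seed=9)
        assert a == b

    def test_small_database_rejected(self):
        db = _db_with(make_record("L1"), make_record("L2"))
        with pytest.raises(ValueError, match="too small"):
            place_new_lineage("ACGT" * 79, db)


class TestK2POracle:
    def test_brute_force_equivalence(self, rng):
        for _ in range(200):
            a = "".join(rng.choice(list("ACGT"), 250))
            k = int(rng.integers(0, 80))
            b = _mutate(a, rng.choice(250, size=k, replace=False))
            ours = k2p_distance(a, b).k2p
            theirs = k2p_brute_force(a, b)
            if math.isinf(theirs):
                assert math.isinf(ours)
            else:
                assert ours == pytest.approx(theirs, abs=1e-12)
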