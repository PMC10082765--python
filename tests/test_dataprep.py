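"""Kinetic labelling, shortest-path negatives, and node filtering."""

import math

import numpy as np
import pytest

import duplexbind as db
from duplexbind.dataprep import (
    InteractionRecord,
    LabeledPair,
    read_records_tsv,
    write_labeled_pairs_tsv,
    read_labeled_pairs_tsv,
)

from conftest import random_duplex
from oracles import all_pairs_distances


def rec(lig, prot, value, ctype="Kd", temp=25.0):
    return InteractionRecord(lig, prot, ctype, value, temp)


def chain_network() -> db.DuplexNetwork:
    """Path l1-p1-l2-p2-l3-p3-l4-p4: distance(l1, p4) = 7."""
    pos = [("l1", "p1"), ("l2", "p1"), ("l2", "p2"), ("l3", "p2"),
           ("l3", "p3"), ("l4", "p3"), ("l4", "p4")]
    return db.DuplexNetwork.from_edges(pos, [])


class TestFilterTemperature:
    def test_in_range_kept_and_out_of_range_removed(self):
        records = [rec("l", "p", 1.0, temp=37.0), rec("l", "q", 1.0, temp=4.0)]
        kept = db.filter_temperature(records)
        assert [r.protein_id for r in kept] == ["p"]

    @pytest.mark.parametrize("keep_missing,expected", [(True, 1), (False, 0)])
    def test_missing_temperature_flag(self, keep_missing, expected):
        records = [rec("l", "p", 1.0, temp=None)]
        assert len(db.filter_temperature(records, keep_missing=keep_missing)) == expected


class TestLabelFromKinetics:
    @pytest.mark.parametrize(
        "value,expected_label",
        [(500.0, "positive"), (1e3, "positive"), (1e6, "negative"), (5e7, "negative")],
    )
    def test_threshold_labelling_boundaries_inclusive(self, value, expected_label):
        labeled, dropped = db.label_from_kinetics([rec("l", "p", value)])
        assert not dropped
        assert labeled[0].label == expected_label

    def test_intermediate_value_dropped_as_ambiguous(self):
        labeled, dropped = db.label_from_kinetics([rec("l", "p", 1e4)])
        assert not labeled
        assert dropped[0][1].startswith("only intermediate")

    def test_conflicting_evidence_dropped(self):
        records = [rec("l", "p", 10.0, ctype="Kd"), rec("l", "p", 1e7, ctype="Ki")]
        labeled, dropped = db.label_from_kinetics(records)
        assert not labeled
        assert "conflicting" in dropped[0][1]

    def test_median_aggregation_within_constant_type(self):
        # median of {10, 20, 1e9} nM Kd is 20 -> positive despite the outlier
        records = [rec("l", "p", v, ctype="Kd") for v in (10.0, 20.0, 1e9)]
        labeled, dropped = db.label_from_kinetics(records)
        assert labeled[0].label == "positive"

    def test_labelling_monotone_in_positive_threshold(self):
        rng = np.random.default_rng(0)
        records = [
            rec(f"l{i}", f"p{i}", float(10 ** rng.uniform(0, 9))) for i in range(60)
        ]
        pos_strict = {
            p.pair
            for p in db.label_from_kinetics(records, pos_max_nM=1e2)[0]
            if p.label == "positive"
        }
        pos_loose = {
            p.pair
            for p in db.label_from_kinetics(records, pos_max_nM=1e3)[0]
            if p.label == "positive"
        }
        assert pos_strict <= pos_loose

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            rec("l", "p", 0.0)


class TestMergeCuratedPositives:
    def test_curated_pair_without_experimental_record_retained(self):
        merged = db.merge_curated_positives([("l", "p")], [])
        assert merged[0].provenance == "curated_positive"
        assert merged[0].label == "positive"

    def test_curated_pair_with_experimental_negative_excluded(self):
        exp = [LabeledPair("l", "p", "negative")]
        merged = db.merge_curated_positives([("l", "p")], exp)
        assert all(p.pair != ("l", "p") or p.label == "negative" for p in merged)
        assert len(merged) == 1  # the negative stays, the curated entry is gone

    def test_curated_also_experimental_positive_single_entry(self):
        exp = [LabeledPair("l", "p", "positive")]
        merged = db.merge_curated_positives([("l", "p")], exp)
        assert len(merged) == 1
        assert merged[0].provenance == "experimental"


class TestShortestPathDistances:
    def test_directly_linked_pair_is_one(self):
        net = chain_network()
        dist = db.shortest_path_distances(net)
        assert dist[("l1", "p1")] == 1

    def test_chain_reaches_seven_hops(self):
        dist = db.shortest_path_distances(chain_network())
        assert dist[("l1", "p4")] == 7

    def test_distances_are_odd(self):
        net = random_duplex(15, 15, 40, seed=0, pos_fraction=1.0)
        for d in db.shortest_path_distances(net).values():
            assert d % 2 == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_floyd_warshall_oracle(self, seed):
        net = random_duplex(20, 20, 45, seed=seed, pos_fraction=1.0)
        dist = db.shortest_path_distances(net)
        oracle = all_pairs_distances(net)
        for pair, d_oracle in oracle.items():
            if math.isinf(d_oracle):
                assert pair not in dist
            else:
                assert dist[pair] == int(d_oracle)


class TestSampleNetworkNegatives:
    def test_unique_seven_hop_pair_found(self):
        out = db.sample_network_negatives(chain_network(), distance=7, n_samples=1)
        assert [p.pair for p in out] == [("l1", "p4")]
        assert out[0].provenance == "network_derived" and out[0].distance == 7

    def test_request_exceeding_pool_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="returning all"):
            out = db.sample_network_negatives(chain_network(), distance=7, n_samples=5)
        assert len(out) == 1

    def test_seeding_reproducible(self):
        net = random_duplex(25, 25, 60, seed=4, pos_fraction=1.0)
        a = db.sample_network_negatives(net, distance=3, n_samples=10, seed=1)
        b = db.sample_network_negatives(net, distance=3, n_samples=10, seed=1)
        c = db.sample_network_negatives(net, distance=3, n_samples=10, seed=2)
        assert [p.pair for p in a] == [p.pair for p in b]
        assert [p.pair for p in a] != [p.pair for p in c]

    def test_sampled_pairs_reverify_to_distance(self):
        net = random_duplex(30, 30, 70, seed=7, pos_fraction=1.0)
        oracle = all_pairs_distances(net)
        for p in db.sample_network_negatives(net, distance=5, n_samples=8, seed=0):
            assert oracle[p.pair] == 5

    def test_min_only_accepts_larger_distances(self):
        net = random_duplex(30, 30, 70, seed=7, pos_fraction=1.0)
        out = db.sample_network_negatives(
            net, distance=5, n_samples=10, seed=0, min_only=True
        )
        assert all(p.distance >= 5 for p in out)


class TestBuildEvalNegatives:
    def test_distance_thresholds(self):
        # long chain: l1..l7 / p1..p7 path gives distances 1..13
        pos = []
        for i in range(1, 8):
            pos.append((f"l{i}", f"p{i}"))
            if i < 7:
                pos.append((f"l{i+1}", f"p{i}"))
        net = db.DuplexNetwork.from_edges(pos, [])
        out = db.build_eval_negatives(net, min_distance=11)
        pairs = {p.pair for p in out}
        assert ("l1", "p6") in pairs  # distance 11
        assert ("l1", "p7") in pairs  # distance 13
        assert ("l1", "p5") not in pairs  # distance 9
        oracle = all_pairs_distances(net)
        for p in out:
            assert oracle[p.pair] >= 11 and not math.isinf(oracle[p.pair])

    def test_unreachable_pairs_excluded(self):
        net = db.DuplexNetwork.from_edges(
            [("l1", "p1"), ("l2", "p2")], [], ["l1", "l2"], ["p1", "p2"]
        )
        out = db.build_eval_negatives(net, min_distance=3)
        assert out == []
        oracle = all_pairs_distances(net)
        assert math.isinf(oracle[("l1", "p2")])

    def test_absolute_negatives_merged_without_train_overlap(self):
        net = chain_network()
        absolute = [
            LabeledPair("lx", "px", "negative"),
            LabeledPair("l1", "p1", "negative"),
        ]
        out = db.build_eval_negatives(
            net, min_distance=11, absolute_negatives=absolute,
            train_pairs=[("l1", "p1")],
        )
        assert {p.pair for p in out} == {("lx", "px")}


class TestEnforceBothAnnotations:
    def test_single_signed_node_pairs_removed(self):
        pairs = [
            LabeledPair("l1", "p1", "positive"),
            LabeledPair("l1", "p2", "negative"),
            LabeledPair("l2", "p1", "negative"),
            LabeledPair("l2", "p2", "positive"),
            LabeledPair("l3", "p1", "positive"),  # l3 has only positives
        ]
        out = db.enforce_both_annotations(pairs)
        assert all(p.ligand_id != "l3" for p in out)

    def test_balanced_two_by_two_unchanged(self):
        pairs = [
            LabeledPair("l1", "p1", "positive"),
            LabeledPair("l1", "p2", "negative"),
            LabeledPair("l2", "p1", "negative"),
            LabeledPair("l2", "p2", "positive"),
        ]
        assert db.enforce_both_annotations(pairs) == pairs

    def test_cascade_matches_single_pass_fixed_point(self):
        # removing l3 leaves p3 single-signed, which then removes l4's pair
        pairs = [
            LabeledPair("l1", "p1", "positive"),
            LabeledPair("l1", "p2", "negative"),
            LabeledPair("l2", "p1", "negative"),
            LabeledPair("l2", "p2", "positive"),
            LabeledPair("l3", "p3", "positive"),
            LabeledPair("l4", "p3", "negative"),
            LabeledPair("l4", "p1", "positive"),
        ]
        out = db.enforce_both_annotations(pairs)

        def single_pass(ps):
            pos_nodes, neg_nodes = set(), set()
            for p in ps:
                nodes = (("L", p.ligand_id), ("P", p.protein_id))
                (pos_nodes if p.label == "positive" else neg_nodes).update(nodes)
            bad = (pos_nodes - neg_nodes) | (neg_nodes - pos_nodes)
            return [
                p for p in ps
                if ("L", p.ligand_id) not in bad and ("P", p.protein_id) not in bad
            ]

        ref = pairs
        while True:
            nxt = single_pass(ref)
            if nxt == ref:
                break
            ref = nxt
        assert out == ref

    @pytest.mark.parametrize("seed", [0, 5])
    def test_fixed_point_every_survivor_has_both_signs(self, seed):
        rng = np.random.default_rng(seed)
        pairs = []
        seen = set()
        for _ in range(80):
            pr = (f"l{rng.integers(12)}", f"p{rng.integers(12)}")
            if pr in seen:
                continue
            seen.add(pr)
            pairs.append(
                LabeledPair(*pr, "positive" if rng.random() < 0.6 else "negative")
            )
        out = db.enforce_both_annotations(pairs)
        for side, getter in (("L", lambda p: p.ligand_id), ("P", lambda p: p.protein_id)):
            nodes = {getter(p) for p in out}
            for n in nodes:
                labels = {p.label for p in out if getter(p) == n}
                assert labels == {"positive", "negative"}


class TestClassBalance:
    def test_counts_and_ratio(self):
        pairs = [LabeledPair("l", f"p{i}", "positive") for i in range(3)]
        pairs += [LabeledPair("l2", f"p{i}", "negative") for i in range(3)]
        assert db.class_balance_report(pairs) == (3, 3, 1.0)

    def test_all_positive_ratio_infinite(self):
        pairs = [LabeledPair("l", "p", "positive")]
        n_pos, n_neg, ratio = db.class_balance_report(pairs)
        assert (n_pos, n_neg) == (1, 0) and math.isinf(ratio)


class TestIO:
    def test_records_and_pairs_round_trip(self, tmp_path):
        rec_path = tmp_path / "records.tsv"
        rec_path.write_text(
            "ligand_id\tprotein_id\tconstant_type\tvalue_nM\ttemperature_C\tsource\n"
            "l1\tp1\tKd\t500.0\t37.0\tx\n"
            "l2\tp2\tIC50\t2e6\t\ty\n"
        )
        records = read_records_tsv(rec_path)
        assert records[0].value_nM == 500.0
        assert records[1].temperature_C is None
        labeled, _ = db.label_from_kinetics(records)
        pair_path = tmp_path / "pairs.tsv"
        write_labeled_pairs_tsv(labeled, pair_path)
        assert read_labeled_pairs_tsv(pair_path) == labeled
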