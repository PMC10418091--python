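import numpy as np
import pytest

from mgcscan.homology import local_align_score
from mgcscan.ssn import (
    EmptyNetworkError,
    SSN,
    assign_subfamily,
    build_network,
    build_ssn,
    collapse_repnodes,
    filter_sequences,
    global_identity,
)
from mgcscan.synthetic import mutate_to_identity

from oracles import bfs_components, random_protein


class TestFilter:
    @pytest.mark.parametrize("length,kept", [(199, False), (200, True),
                                             (470, True), (471, False)])
    def test_length_window_boundaries(self, length, kept):
        seqs = {"a": "A" * length, "pad": "W" * 300}
        out = filter_sequences(seqs)
        assert ("a" in out) is kept

    def test_internal_stop_dropped_trailing_stop_tolerated(self):
        seqs = {"internal": "M" * 150 + "*" + "M" * 150, "trailing": "M" * 300 + "*"}
        out = filter_sequences(seqs)
        assert set(out) == {"trailing"}
        assert out["trailing"] == "M" * 300

    def test_long_ambiguous_run_dropped(self):
        seqs = {"amb": "M" * 100 + "X" * 15 + "M" * 150, "ok": "M" * 250}
        assert set(filter_sequences(seqs)) == {"ok"}

    def test_everything_dropped_is_refused(self):
        with pytest.raises(EmptyNetworkError):
            filter_sequences({"short": "MKV"})


class TestRepnodeCollapse:
    def test_identical_sequences_share_one_repnode(self, rng):
        s = random_protein(rng, 250)
        (rn,) = collapse_repnodes({"a": s, "b": s, "c": s})
        assert sorted(rn.member_ids) == ["a", "b", "c"]

    def test_unrelated_sequences_stay_apart(self, rng):
        seqs = {"a": random_protein(rng, 250), "b": random_protein(rng, 250)}
        assert global_identity(seqs["a"], seqs["b"]) < 0.2
        assert len(collapse_repnodes(seqs)) == 2

    def test_single_linkage_chains_collapse(self, rng):
        a = random_protein(rng, 300)
        b = mutate_to_identity(a, 0.6, 1)
        c = mutate_to_identity(b, 0.6, 2)

        def hand_identity(x, y):  # independent count for equal-length pairs
            return sum(1 for u, v in zip(x, y) if u == v) / len(x)

        assert hand_identity(a, b) >= 0.5 and hand_identity(b, c) >= 0.5
        assert hand_identity(a, c) < 0.5
        (rn,) = collapse_repnodes({"a": a, "b": b, "c": c})
        assert sorted(rn.member_ids) == ["a", "b", "c"]

    def test_result_invariant_to_input_order(self, rng):
        base = random_protein(rng, 260)
        seqs = {
            "z": base,
            "a": mutate_to_identity(base, 0.7, 3),
            "m": random_protein(rng, 240),
        }
        fwd = collapse_repnodes(dict(sorted(seqs.items())))
        rev = collapse_repnodes(dict(sorted(seqs.items(), reverse=True)))
        assert [(r.rep_id, r.member_ids) for r in fwd] == [
            (r.rep_id, r.member_ids) for r in rev
        ]

    def test_edit_distance_identity_matches_hand_count_for_mutants(self, rng):
        a = random_protein(rng, 300)
        b = mutate_to_identity(a, 0.65, 9)
        hand = sum(1 for u, v in zip(a, b) if u == v) / len(a)
        assert global_identity(a, b) == pytest.approx(hand)


def planted_families(rng, n_families=3, n_members=4, within=0.85, length=300):
    """Distinct random roots, members mutated to a set identity."""
    seqs, truth = {}, {}
    for fam in range(n_families):
        root = random_protein(rng, length)
        for k in range(n_members):
            sid = f"f{fam}_m{k}"
            seqs[sid] = mutate_to_identity(root, within, fam * 100 + k)
            truth[sid] = fam
    return seqs, truth


class TestBuildSSN:
    def test_identical_representatives_connect(self, rng):
        s = random_protein(rng, 300)
        reps = collapse_repnodes({"a": s, "b": random_protein(rng, 300)})
        net = build_ssn(reps)
        # 'a' and the unrelated sequence stay apart
        assert len(set(net.clusters.values())) == 2
        assert net.edges == []

    def test_three_planted_families_give_three_clusters(self, rng):
        seqs, truth = planted_families(rng)
        net = build_network(seqs)
        member_cluster = net.member_cluster()
        assert len(set(member_cluster.values())) == 3
        for sid, fam in truth.items():
            peers = {s for s, f in truth.items() if f == fam}
            assert {member_cluster[p] for p in peers} == {member_cluster[sid]}

    def test_components_match_hand_bfs_on_brute_force_score_matrix(self, rng):
        # distinct repnodes within families: 40% identity to the root
        seqs = {}
        for fam in range(3):
            root = random_protein(rng, 300)
            seqs[f"f{fam}_r"] = root
            for k in range(2):
                seqs[f"f{fam}_m{k}"] = mutate_to_identity(root, 0.40, fam * 10 + k)
        net = build_network(seqs)
        assert len(net.repnodes) == len(seqs)  # nothing collapsed at 40%
        # oracle: full score matrix -> thresholded edges -> BFS components
        import math

        from mgcscan.homology import compute_evalue

        ids = sorted(seqs)
        edges = []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                raw = local_align_score(seqs[a], seqs[b])
                if raw <= 0:
                    continue
                ev = compute_evalue(raw, len(seqs[a]), 1e7)
                if ev > 0 and -math.log10(ev) >= 40:
                    edges.append((a, b))
        expected = bfs_components(ids, edges)
        got = {}
        for sid, c in net.member_cluster().items():
            got.setdefault(c, set()).add(sid)
        assert {frozenset(v) for v in got.values()} == expected

    def test_raising_threshold_only_refines_clusters(self, rng):
        seqs, _ = planted_families(rng, within=0.4)
        kept = filter_sequences(seqs)
        reps = collapse_repnodes(kept)
        loose = build_ssn(reps, score_threshold=20)
        tight = build_ssn(reps, score_threshold=80)

        def partition(net):
            part = {}
            for rid, c in net.clusters.items():
                part.setdefault(c, set()).add(rid)
            return list(part.values())

        loose_parts = partition(loose)
        for block in partition(tight):
            assert any(block <= p for p in loose_parts)

    def test_edges_are_symmetric_and_partition_is_total(self, rng):
        seqs, _ = planted_families(rng)
        net = build_network(seqs)
        seen = set()
        for u, v, _ in net.edges:
            assert u != v
            assert (v, u) not in seen
            seen.add((u, v))
        assert set(net.clusters) == {rn.rep_id for rn in net.repnodes}


class TestSubfamilyAssignment:
    def _net_with_refs(self, rng):
        seqs = {}
        labels = {}
        for fam, name in enumerate(["Mlp1", "Mlp2", "Mlp3"]):
            root = random_protein(rng, 300)
            seqs[f"ref_{name}"] = root
            labels[f"ref_{name}"] = name
            for k in range(3):
                seqs[f"{name.lower()}_m{k}"] = mutate_to_identity(
                    root, 0.6, fam * 7 + k
                )
        seqs["orphan"] = random_protein(rng, 300)
        return build_network(seqs), labels

    def test_members_inherit_their_clusters_reference_label(self, rng):
        net, labels = self._net_with_refs(rng)
        out = assign_subfamily(net, labels)
        for fam in ["Mlp1", "Mlp2", "Mlp3"]:
            for k in range(3):
                assert out[f"{fam.lower()}_m{k}"] == fam

    def test_reference_free_cluster_is_unassigned(self, rng):
        net, labels = self._net_with_refs(rng)
        assert assign_subfamily(net, labels)["orphan"] == "unassigned"

    def test_mixed_reference_cluster_is_unassigned_with_warning(self, rng, caplog):
        s = random_protein(rng, 300)
        net = build_network({"a": s, "b": mutate_to_identity(s, 0.6, 1),
                             "far": random_protein(rng, 300)})
        import logging

        with caplog.at_level(logging.WARNING):
            out = assign_subfamily(net, {"a": "Mlp1", "b": "Mlp3"})
        assert out["a"] == out["b"] == "unassigned"
        assert any("mixed" in r.message for r in caplog.records)

    def test_subfamily_recovery_is_perfect_on_separable_families(self, rng):
        seqs, truth = planted_families(rng, n_members=5, within=0.7)
        labels = {f"f{fam}_m0": f"Mlp{fam + 1}" for fam in range(3)}
        out = assign_subfamily(build_network(seqs), labels)
        assert all(out[sid] == f"Mlp{fam + 1}" for sid, fam in truth.items())
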