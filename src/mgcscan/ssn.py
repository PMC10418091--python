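"""Sequence similarity network construction and Mlp subfamily typing.

This is a self-contained SSN dialect.  Sequences are length- and
quality-filtered, collapsed into representative nodes at 50% global
identity (greedy single linkage), and connected all-vs-all with local
alignments.  The edge statistic is an EFI-EST-style alignment score,
AS = -log10(E), where E comes from our Karlin-Altschul E-value with a
fixed configured effective database size (default 1e7 residues).  Edges
with AS >= the score threshold are kept and connected components define
the clusters.  Subfamily labels (Mlp1/Mlp2/Mlp3) propagate from labelled
reference sequences to every member of their cluster; clusters with
mixed or no references stay unassigned.

This reproduces the thresholding semantics of the webserver-based
original, not its exact scores; reports flag the dialect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import edlib
import networkx as nx

from .homology import compute_evalue, local_align_score, make_aligner

logger = logging.getLogger(__name__)

LENGTH_WINDOW = (200, 470)
SCORE_THRESHOLD = 40.0
REPNODE_IDENTITY = 0.5
EFFECTIVE_DB_SIZE = 1e7


class EmptyNetworkError(ValueError):
    """All sequences were dropped by the quality filter."""


@dataclass
class RepNode:
    rep_id: str
    rep_seq: str
    member_ids: list[str] = field(default_factory=list)


@dataclass
class SSN:
    repnodes: list[RepNode]
    edges: list[tuple[str, str, float]]
    clusters: dict[str, int]
    params: dict

    def member_cluster(self) -> dict[str, int]:
        """Cluster index for every collapsed member sequence."""
        out = {}
        for rn in self.repnodes:
            for m in rn.member_ids:
                out[m] = self.clusters[rn.rep_id]
        return out

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(rn.rep_id for rn in self.repnodes)
        g.add_weighted_edges_from(self.edges, weight="alignment_score")
        return g


def _has_long_ambiguous_run(seq: str, run: int = 10) -> bool:
    return "X" * run in seq


def filter_sequences(
    seqs: dict[str, str],
    length_window: tuple[int, int] = LENGTH_WINDOW,
) -> dict[str, str]:
    """Quality/length filter applied before network construction.

    Drops sequences outside the length window (inclusive), containing an
    internal stop ('*'), or carrying long ambiguous (X) runs.  A trailing
    stop character is stripped, not penalised.  Refuses to continue when
    nothing survives.
    """
    lo, hi = length_window
    kept: dict[str, str] = {}
    for sid in sorted(seqs):
        seq = seqs[sid].upper().rstrip("*")
        if "*" in seq:
            logger.info("SSN filter drop %s: internal stop", sid)
            continue
        if not lo <= len(seq) <= hi:
            logger.info("SSN filter drop %s: length %d outside [%d, %d]",
                        sid, len(seq), lo, hi)
            continue
        if _has_long_ambiguous_run(seq):
            logger.info("SSN filter drop %s: ambiguous run", sid)
            continue
        kept[sid] = seq
    if seqs and not kept:
        raise EmptyNetworkError("all sequences dropped by the SSN filter")
    return kept


def global_identity(a: str, b: str) -> float:
    """Global identity in [0,1] as 1 - edit_distance / max(len).

    Edit distance counts substitutions and indels once each, so for
    equal-length substitution-only variants this is exact fractional
    identity; for unequal lengths it is a conservative lower bound.
    """
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def collapse_repnodes(
    seqs: dict[str, str], identity_cut: float = REPNODE_IDENTITY
) -> list[RepNode]:
    """Greedy single-linkage collapse at ``identity_cut`` global identity.

    The longest member represents each group (ties to smallest id); the
    canonical (length desc, id) processing order makes the result
    invariant to input file order.
    """
    order = sorted(seqs, key=lambda s: (-len(seqs[s]), s))
    parent = {sid: sid for sid in order}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            if find(a) == find(b):
                continue
            if global_identity(seqs[a], seqs[b]) >= identity_cut:
                parent[find(b)] = find(a)
    groups: dict[str, list[str]] = {}
    for sid in order:
        groups.setdefault(find(sid), []).append(sid)
    repnodes = []
    for members in groups.values():
        rep = sorted(members, key=lambda s: (-len(seqs[s]), s))[0]
        repnodes.append(RepNode(rep_id=rep, rep_seq=seqs[rep],
                                member_ids=sorted(members)))
    repnodes.sort(key=lambda rn: rn.rep_id)
    return repnodes


def build_ssn(
    repnodes: list[RepNode],
    score_threshold: float = SCORE_THRESHOLD,
    effective_db_size: float = EFFECTIVE_DB_SIZE,
    length_window: tuple[int, int] = LENGTH_WINDOW,
    repnode_identity: float = REPNODE_IDENTITY,
) -> SSN:
    """All-vs-all local alignment between representatives; threshold edges.

    Edge kept iff AS = -log10(E) >= ``score_threshold``.  Connected
    components are labelled in decreasing size, ties by smallest member id.
    """
    if len(repnodes) < 2:
        raise ValueError("build_ssn needs at least two repnodes")
    aligner = make_aligner()
    edges: list[tuple[str, str, float]] = []
    for i, a in enumerate(repnodes):
        for b in repnodes[i + 1 :]:
            raw = local_align_score(a.rep_seq, b.rep_seq, aligner)
            if raw <= 0:
                continue
            ev = compute_evalue(raw, len(a.rep_seq), effective_db_size)
            score = -math.log10(ev) if ev > 0 else math.inf
            if score >= score_threshold:
                edges.append((a.rep_id, b.rep_id, score))
    g = nx.Graph()
    g.add_nodes_from(rn.rep_id for rn in repnodes)
    g.add_edges_from((u, v) for u, v, _ in edges)
    comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
    clusters = {node: idx for idx, comp in enumerate(comps) for node in comp}
    return SSN(
        repnodes=repnodes,
        edges=edges,
        clusters=clusters,
        params={
            "score_threshold": score_threshold,
            "repnode_identity": repnode_identity,
            "length_window": length_window,
            "effective_db_size": effective_db_size,
            "score_statistic": "-log10(E), in-package dialect",
        },
    )


def build_network(
    seqs: dict[str, str],
    score_threshold: float = SCORE_THRESHOLD,
    repnode_identity: float = REPNODE_IDENTITY,
    length_window: tuple[int, int] = LENGTH_WINDOW,
    effective_db_size: float = EFFECTIVE_DB_SIZE,
) -> SSN:
    """Convenience: filter -> collapse -> build in one call."""
    kept = filter_sequences(seqs, length_window)
    reps = collapse_repnodes(kept, repnode_identity)
    return build_ssn(reps, score_threshold, effective_db_size,
                     length_window, repnode_identity)


def assign_subfamily(
    ssn: SSN, reference_labels: dict[str, str]
) -> dict[str, str]:
    """Propagate reference labels (Mlp1/Mlp2/Mlp3/SCMT) by cluster co-membership.

    Every member inherits its cluster's label when the cluster contains
    references of exactly one label; mixed or reference-free clusters are
    unassigned.
    """
    member_cluster = ssn.member_cluster()
    cluster_labels: dict[int, set[str]] = {}
    for ref_id, label in reference_labels.items():
        if ref_id in member_cluster:
            cluster_labels.setdefault(member_cluster[ref_id], set()).add(label)
    out: dict[str, str] = {}
    for member, cluster in member_cluster.items():
        labels = cluster_labels.get(cluster, set())
        if len(labels) == 1:
            out[member] = next(iter(labels))
        else:
            if len(labels) > 1:
                logger.warning(
                    "SSN cluster %d contains references of mixed labels %s; "
                    "members left unassigned", cluster, sorted(labels)
                )
            out[member] = "unassigned"
    return out


def export_tsv(ssn: SSN, nodes_path, edges_path, clusters_path=None) -> None:
    """Cytoscape-compatible node/edge tables (plus optional membership table)."""
    import pandas as pd

    nodes = pd.DataFrame(
        [
            {
                "rep_id": rn.rep_id,
                "n_members": len(rn.member_ids),
                "members": ",".join(rn.member_ids),
                "cluster": ssn.clusters[rn.rep_id],
                "length": len(rn.rep_seq),
            }
            for rn in ssn.repnodes
        ]
    )
    nodes.to_csv(nodes_path, sep="\t", index=False)
    edges = pd.DataFrame(ssn.edges, columns=["rep_id_a", "rep_id_b", "alignment_score"])
    edges.to_csv(edges_path, sep="\t", index=False)
    if clusters_path is not None:
        membership = pd.DataFrame(
            sorted(ssn.member_cluster().items()), columns=["member_id", "cluster"]
        )
        membership.to_csv(clusters_path, sep="\t", index=False)


def export_graphml(ssn: SSN, path) -> None:
    g = ssn.graph()
    nx.set_node_attributes(g, ssn.clusters, "cluster")
    nx.write_graphml(g, path)
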