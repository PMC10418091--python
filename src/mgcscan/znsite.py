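"""Zn2+ coordination-triad mapping and classification.

UroD-superfamily S-/Se-methyltransferases coordinate their catalytic
Zn2+ through a His-Cys-Cys triad; in O-methyltransferases one or both
Cys ligands are replaced by carboxylates (Asp/Glu) or by non-coordinating
residues.  Queries are aligned to an annotated reference (reference
sequence plus three 1-based triad columns, supplied as configuration —
shipped defaults are curator-supplied examples, see data/), the residues
at the triad columns are read off, and the site is classified:

==================  ==========================================
class               rule on (His-site, Cys-site-1, Cys-site-2)
==================  ==========================================
HCC_S_Se            exactly (H, C, C)
carboxylate_O       His site is H and >=1 Cys site is D or E
noncoordinating     any other fully-mapped combination
undetermined        any triad column maps to a gap / no alignment
==================  ==========================================
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import yaml

from .homology import make_aligner

ZN_CLASSES = ("HCC_S_Se", "carboxylate_O", "noncoordinating", "undetermined")


@dataclass(frozen=True)
class ReferenceProfile:
    reference_id: str
    reference_seq: str
    triad_columns: tuple[int, int, int]  # 1-based positions in reference_seq

    def __post_init__(self) -> None:
        for c in self.triad_columns:
            if not 1 <= c <= len(self.reference_seq):
                raise ValueError(f"triad column {c} outside reference sequence")
        if not (self.triad_columns[0] < self.triad_columns[1] < self.triad_columns[2]):
            raise ValueError("triad columns must be strictly increasing")


@dataclass(frozen=True)
class ZnSiteCall:
    feature_id: str
    triad: tuple[tuple[int, int | None, str], ...]  # (ref_column, query_pos, residue)
    zn_class: str
    reason: str = ""


def classify_triad(his_res: str, cys1_res: str, cys2_res: str) -> str:
    """Pure classification of the three coordination-sphere residues."""
    if his_res == "H" and cys1_res == "C" and cys2_res == "C":
        return "HCC_S_Se"
    if his_res == "H" and (cys1_res in "DE" or cys2_res in "DE"):
        return "carboxylate_O"
    return "noncoordinating"


def load_reference_profile(path) -> ReferenceProfile:
    """Profile YAML: {reference_fasta: x.faa, triad_columns: [c1, c2, c3]}."""
    from Bio import SeqIO

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    import os

    fasta = cfg["reference_fasta"]
    if not os.path.isabs(fasta):
        fasta = os.path.join(os.path.dirname(os.path.abspath(path)), fasta)
    rec = next(SeqIO.parse(fasta, "fasta"))
    return ReferenceProfile(
        reference_id=rec.id,
        reference_seq=str(rec.seq).upper().rstrip("*"),
        triad_columns=tuple(int(c) for c in cfg["triad_columns"]),
    )


def map_triad(
    query_seq: str,
    profile: ReferenceProfile,
    feature_id: str = "query",
) -> ZnSiteCall:
    """Align a query onto the reference and read the triad residues.

    Local alignment tolerates N-/C-terminal extensions; a triad column
    that falls outside the aligned region or inside a deletion maps to a
    gap and yields ``undetermined``.
    """
    if not query_seq:
        raise ValueError("map_triad: empty query")
    aligner = make_aligner()
    if aligner.score(profile.reference_seq, query_seq) <= 0:
        return ZnSiteCall(
            feature_id=feature_id,
            triad=tuple((c, None, "-") for c in profile.triad_columns),
            zn_class="undetermined",
            reason="query does not align to the reference",
        )
    alignment = next(iter(aligner.align(profile.reference_seq, query_seq)))
    ref_blocks, q_blocks = alignment.aligned
    # map each 1-based reference column to a query position via the blocks
    triad = []
    residues = []
    for col in profile.triad_columns:
        ref0 = col - 1
        qpos = None
        for (rs, re_), (qs, qe) in zip(ref_blocks, q_blocks):
            if rs <= ref0 < re_:
                qpos = qs + (ref0 - rs)
                break
        if qpos is None:
            triad.append((col, None, "-"))
            residues.append("-")
        else:
            triad.append((col, qpos + 1, query_seq[qpos]))
            residues.append(query_seq[qpos])
    if "-" in residues:
        zn_class = "undetermined"
        reason = "a triad column maps to a gap"
    else:
        zn_class = classify_triad(*residues)
        reason = ""
    return ZnSiteCall(
        feature_id=feature_id, triad=tuple(triad), zn_class=zn_class, reason=reason
    )


def map_triad_best(
    query_seq: str,
    profiles: list[ReferenceProfile],
    feature_id: str = "query",
) -> ZnSiteCall:
    """Map against the best-aligning of several reference profiles.

    Useful when no single annotated reference covers every query family;
    the profile with the highest local alignment score wins.
    """
    if not profiles:
        raise ValueError("map_triad_best: no profiles supplied")
    aligner = make_aligner()
    best, best_score = profiles[0], -1.0
    for profile in profiles:
        score = aligner.score(profile.reference_seq, query_seq)
        if score > best_score:
            best, best_score = profile, score
    return map_triad(query_seq, best, feature_id=feature_id)


def triad_summary(
    calls: list[ZnSiteCall], subfamilies: dict[str, str] | None = None
) -> pd.DataFrame:
    """Counts and fractions per zn_class, optionally split by subfamily."""
    if not calls:
        return pd.DataFrame(columns=["subfamily", "zn_class", "count", "fraction"])
    rows = [
        {
            "subfamily": (subfamilies or {}).get(c.feature_id, "unassigned"),
            "zn_class": c.zn_class,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows)
    counts = df.groupby(["subfamily", "zn_class"]).size().reset_index(name="count")
    counts["fraction"] = counts.groupby("subfamily")["count"].transform(
        lambda s: s / s.sum()
    )
    return counts.sort_values(["subfamily", "zn_class"]).reset_index(drop=True)


def calls_to_table(calls: list[ZnSiteCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "feature_id": c.feature_id,
                "zn_class": c.zn_class,
                "his_site": c.triad[0][2],
                "cys_site_1": c.triad[1][2],
                "cys_site_2": c.triad[2][2],
                "reason": c.reason,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["feature_id", "zn_class", "his_site", "cys_site_1",
                 "cys_site_2", "reason"],
    )
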