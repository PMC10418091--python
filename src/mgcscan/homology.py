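"""Protein homology search: local alignment, E-values, role assignment.

Local alignments are optimal Smith-Waterman alignments under affine gaps
with BLOSUM62 and the NCBI "11/1" convention: a gap of length L costs
11 + L, i.e. the first gapped residue costs 12 and each further residue 1.
Percent identity uses the BLAST convention — identities divided by the
alignment length including gap columns.

E-values follow Karlin-Altschul statistics, E = K*m'*n'*exp(-lambda*S),
with the standard length adjustment m' = m - l, n' = n - l,
l = ln(K*m*n)/H.  Shipped constants are the NCBI gapped parameters for
BLOSUM62 with gap open 11 / extend 1.  Because E-values depend on the
database size, role assignment thresholds on bit score by default and on
E-value only when an effective database size is configured or hits are
imported from a real BLAST run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: Karlin-Altschul gapped parameters for BLOSUM62, gap open 11 / extend 1.
KARLIN_PARAMS = {"BLOSUM62:11/1": {"lambda": 0.267, "K": 0.041, "H": 0.14}}

#: Roles recognised by the pipeline.  ``OTHER`` is the no-call sentinel.
ROLES = (
    "Mlp",
    "CorrinoidProtein",
    "RamRACE",
    "H4folateMethylase",
    "SelA",
    "SelB",
    "SelC",
    "SelD",
    "MarHDK",
    "GlyReductase",
    "Other",
)

CORE_ROLES = frozenset({"Mlp", "CorrinoidProtein", "RamRACE"})

#: Bit-score threshold used when no effective database size is configured.
#: 50 bits sits far above the expected best score of unrelated ~300-aa
#: proteins (~20 bits) and far below genuine homologs at >=30% identity.
DEFAULT_MIN_BIT_SCORE = 50.0


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    percent_identity: float
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.raw_score < 0:
            raise ValueError("raw_score must be >= 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity out of [0, 100]")
        if self.qend < self.qstart or self.send < self.sstart:
            raise ValueError("alignment end before start")


@dataclass(frozen=True)
class RoleAssignment:
    feature_id: str
    role: str
    best_hit: HomologyHit | None = None
    margin: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role}")
        if self.role != "Other" and self.best_hit is None:
            raise ValueError("non-Other role requires a best_hit")


def make_aligner(matrix_name: str = "BLOSUM62", gap_open: int = 11, gap_extend: int = 1) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.mode = "local"
    # NCBI convention: gap of length L costs open + L*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def bit_score(raw_score: float, karlin: dict | None = None) -> float:
    p = karlin or KARLIN_PARAMS["BLOSUM62:11/1"]
    return (p["lambda"] * raw_score - math.log(p["K"])) / math.log(2.0)


def _alignment_identity_and_coords(alignment) -> tuple[float, int, int, int, int]:
    counts = alignment.counts()
    aln_len = counts.identities + counts.mismatches + counts.gaps
    pid = 100.0 * counts.identities / aln_len if aln_len else 0.0
    # aligned blocks give the local alignment's footprint on each sequence
    tblocks, qblocks = alignment.aligned
    qstart = int(qblocks[0][0]) + 1
    qend = int(qblocks[-1][1])
    sstart = int(tblocks[0][0]) + 1
    send = int(tblocks[-1][1])
    return pid, qstart, qend, sstart, send


def local_align(
    query: str,
    subject: str,
    matrix_name: str = "BLOSUM62",
    gap_open: int = 11,
    gap_extend: int = 1,
    query_id: str = "query",
    subject_id: str = "subject",
    aligner: Align.PairwiseAligner | None = None,
) -> HomologyHit | None:
    """Optimal local alignment of two protein sequences.

    Returns ``None`` when no positive-scoring local alignment exists.
    """
    if not query or not subject:
        raise ValueError("local_align: empty sequence")
    if aligner is None:
        aligner = make_aligner(matrix_name, gap_open, gap_extend)
    # subject as target, query as query: keeps coords in BLAST order
    score = aligner.score(subject, query)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(subject, query)))
    pid, qstart, qend, sstart, send = _alignment_identity_and_coords(alignment)
    return HomologyHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=float(score),
        bit_score=bit_score(float(score)),
        percent_identity=pid,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
    )


def local_align_score(
    query: str, subject: str, aligner: Align.PairwiseAligner | None = None
) -> float:
    """Raw Smith-Waterman score only (no traceback); 0 when no positive cell."""
    if not query or not subject:
        raise ValueError("local_align_score: empty sequence")
    if aligner is None:
        aligner = make_aligner()
    return max(0.0, float(aligner.score(subject, query)))


def compute_evalue(
    raw_score: float,
    query_len: int,
    effective_db_size: float,
    karlin_params: dict | None = None,
    length_adjust: bool = True,
) -> float:
    """Karlin-Altschul expect value for a raw alignment score.

    ``effective_db_size`` is the total residue count of the search space.
    With ``length_adjust`` the standard edge correction
    ``l = ln(K*m*n)/H`` is subtracted from both lengths (floored at 1).
    """
    if karlin_params is None:
        karlin_params = KARLIN_PARAMS["BLOSUM62:11/1"]
    for key in ("lambda", "K"):
        if key not in karlin_params:
            raise ValueError(
                "compute_evalue: Karlin-Altschul parameters (lambda, K) must be "
                "supplied explicitly for non-default matrices"
            )
    lam, K = karlin_params["lambda"], karlin_params["K"]
    m, n = float(query_len), float(effective_db_size)
    if length_adjust:
        H = karlin_params.get("H", 0.14)
        ell = math.log(K * m * n) / H
        # cap the correction so short queries keep a positive length
        ell = min(ell, m - 1.0, n - 1.0) if min(m, n) > 1 else 0.0
        m, n = max(m - ell, 1.0), max(n - ell, 1.0)
    return K * m * n * math.exp(-lam * raw_score)


def alignment_score_from_evalue(evalue: float) -> float:
    """EFI-EST-style alignment score, -log10(E)."""
    if evalue <= 0:
        return math.inf
    return -math.log10(evalue)


def import_blast_tab(path) -> list[HomologyHit]:
    """Read BLAST tabular output (outfmt 6, the default 12 columns)."""
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            (qseqid, sseqid, pident, _length, _mm, _go,
             qstart, qend, sstart, send, evalue, bitscore) = cols
            hits.append(
                HomologyHit(
                    query_id=qseqid,
                    subject_id=sseqid,
                    raw_score=0.0,
                    bit_score=float(bitscore),
                    percent_identity=float(pident),
                    qstart=int(qstart),
                    qend=int(qend),
                    sstart=min(int(sstart), int(send)),
                    send=max(int(sstart), int(send)),
                    evalue=float(evalue),
                )
            )
    return hits


def assign_roles(
    genome,
    seed_sets: dict[str, list[tuple[str, str]]],
    evalue_threshold: float = 1e-10,
    effective_db_size: float | None = None,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
    min_identity: float | None = None,
) -> dict[str, RoleAssignment]:
    """Assign a functional role to every feature of ``genome``.

    Each feature receives the role of its best-bit-score seed hit that
    passes the threshold; ties are broken by higher percent identity,
    then lexicographic seed id.  Features without a passing hit (or
    without a protein sequence) are ``Other``.

    When ``effective_db_size`` is given, hits are thresholded on
    E-value < ``evalue_threshold``; otherwise on bit score >=
    ``min_bit_score`` (database-size independent).
    """
    if not seed_sets:
        raise ValueError("assign_roles: seed_sets is empty")
    aligner = make_aligner()
    assignments: dict[str, RoleAssignment] = {}
    for feature in genome.features():
        if feature.feature_type != "CDS" or not feature.protein_seq:
            logger.info("feature %s has no protein; role Other", feature.feature_id)
            assignments[feature.feature_id] = RoleAssignment(feature.feature_id, "Other")
            continue
        scored: list[tuple[float, float, str, str, float]] = []
        for role, seeds in seed_sets.items():
            for seed_id, seed_seq in seeds:
                score = local_align_score(feature.protein_seq, seed_seq, aligner)
                if score <= 0:
                    continue
                scored.append((score, bit_score(score), role, seed_id, 0.0))
        passing: list[tuple[float, float, str, str, HomologyHit]] = []
        for score, bits, role, seed_id, _ in scored:
            if effective_db_size is not None:
                ev = compute_evalue(score, len(feature.protein_seq), effective_db_size)
                if ev >= evalue_threshold:
                    continue
            elif bits < min_bit_score:
                continue
            seed_seq = dict(seed_sets[role])[seed_id]
            hit = local_align(
                feature.protein_seq,
                seed_seq,
                query_id=feature.feature_id,
                subject_id=seed_id,
                aligner=aligner,
            )
            if hit is None:
                continue
            if effective_db_size is not None:
                hit = HomologyHit(
                    **{**hit.__dict__,
                       "evalue": compute_evalue(score, len(feature.protein_seq), effective_db_size)}
                )
            if min_identity is not None and hit.percent_identity < min_identity:
                continue
            passing.append((hit.bit_score, hit.percent_identity, role, seed_id, hit))
        if not passing:
            assignments[feature.feature_id] = RoleAssignment(feature.feature_id, "Other")
            continue
        passing.sort(key=lambda t: (-t[0], -t[1], t[3]))
        best = passing[0]
        margin = best[0] - passing[1][0] if len(passing) > 1 else best[0]
        assignments[feature.feature_id] = RoleAssignment(
            feature_id=feature.feature_id,
            role=best[2],
            best_hit=best[4],
            margin=margin,
        )
    return assignments
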