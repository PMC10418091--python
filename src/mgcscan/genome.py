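"""Genome annotation containers and coordinate arithmetic.

Gene features are held with 1-based inclusive coordinates (GenBank
convention) throughout; GFF3 input is converted on read.  The cluster
rules operate on gene extents, so compound (``join``) locations are
collapsed to their envelope on parse.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

# IUPAC amino acids plus ambiguity codes and the stop character that
# annotation pipelines occasionally leave on translations.
_AA_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYXBZJUO*]*$")


class GenomeFormatError(ValueError):
    """Raised for unparseable or invariant-violating genome input."""


@dataclass(frozen=True)
class GeneFeature:
    """A single annotated gene with its extent, strand and translation."""

    feature_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int  # inclusive, >= start
    strand: str  # "+" or "-"
    product: str = ""
    protein_seq: str | None = None
    locus_tag: str | None = None
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GenomeFormatError(f"{self.feature_id}: start {self.start} < 1")
        if self.end < self.start:
            raise GenomeFormatError(
                f"{self.feature_id}: end {self.end} < start {self.start}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeFormatError(
                f"{self.feature_id}: strand {self.strand!r} not in {{+,-}} "
                "(strand is required for cluster rules)"
            )
        if self.protein_seq is not None and not _AA_RE.match(self.protein_seq):
            raise GenomeFormatError(
                f"{self.feature_id}: protein_seq contains non-amino-acid characters"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class Contig:
    contig_id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)


@dataclass
class GenomeAnnotation:
    """Ordered, stranded gene features per contig for one genome."""

    genome_id: str
    contigs: dict[str, Contig] = field(default_factory=dict)
    genus: str | None = None
    phylum: str | None = None

    def validate(self) -> None:
        seen: set[str] = set()
        for contig in self.contigs.values():
            prev_start = 0
            for f in contig.features:
                if f.feature_id in seen:
                    raise GenomeFormatError(
                        f"duplicate feature_id {f.feature_id} in {self.genome_id}"
                    )
                seen.add(f.feature_id)
                if f.contig_id != contig.contig_id:
                    raise GenomeFormatError(
                        f"{f.feature_id}: contig_id mismatch "
                        f"({f.contig_id} vs {contig.contig_id})"
                    )
                if f.end > contig.length:
                    raise GenomeFormatError(
                        f"{f.feature_id}: end {f.end} beyond contig length "
                        f"{contig.length}"
                    )
                if f.start < prev_start:
                    raise GenomeFormatError(
                        f"{f.feature_id}: features not sorted by start"
                    )
                prev_start = f.start

    def sort(self) -> None:
        for contig in self.contigs.values():
            contig.features.sort(key=lambda f: (f.start, f.end, f.feature_id))

    def features(self) -> list[GeneFeature]:
        """All features across contigs, in contig then coordinate order."""
        out: list[GeneFeature] = []
        for contig in self.contigs.values():
            out.extend(contig.features)
        return out

    def feature_by_id(self, feature_id: str) -> GeneFeature:
        for f in self.features():
            if f.feature_id == feature_id:
                return f
        raise KeyError(feature_id)


def intergenic_gap(a: GeneFeature, b: GeneFeature) -> int:
    """Strictly intergenic DNA between two genes on one contig, in bp.

    Overlapping or abutting genes give 0 (clamped, never negative).
    Features on different contigs are infinitely separated and rejected.
    """
    if a.contig_id != b.contig_id:
        raise ValueError(
            f"intergenic_gap: {a.feature_id} and {b.feature_id} are on "
            "different contigs"
        )
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end - 1)


def _collapse_location(feat) -> tuple[int, int, str]:
    """Envelope of a (possibly compound) Biopython location, 1-based inclusive."""
    loc = feat.location
    if loc is None:
        raise GenomeFormatError("feature without location")
    start = int(loc.start) + 1
    end = int(loc.end)
    if start > end:
        raise GenomeFormatError(
            "origin-spanning feature locations on circular contigs are not supported"
        )
    if loc.strand == 1:
        strand = "+"
    elif loc.strand == -1:
        strand = "-"
    else:
        raise GenomeFormatError("feature without strand: strand required for cluster rules")
    return start, end, strand


def read_genbank(path) -> GenomeAnnotation:
    """Parse a GenBank flat file into a :class:`GenomeAnnotation`.

    One :class:`GeneFeature` is produced per CDS feature.  CDS features
    without a ``/translation`` are retained with ``protein_seq`` absent
    (they still take part in strand and intervening-gene checks) and a
    warning is logged.
    """
    genome_id = None
    contigs: dict[str, Contig] = {}
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise GenomeFormatError(f"unparseable GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeFormatError(f"no GenBank records found in {path}")
    n = 0
    for rec in records:
        if genome_id is None:
            genome_id = rec.annotations.get("source", "") or rec.id
        contig = Contig(contig_id=rec.id, length=len(rec.seq))
        for feat in rec.features:
            if feat.type not in ("CDS", "tRNA", "rRNA"):
                continue
            start, end, strand = _collapse_location(feat)
            quals = feat.qualifiers
            locus_tag = quals.get("locus_tag", [None])[0]
            n += 1
            fid = locus_tag or quals.get("protein_id", [None])[0] or f"{rec.id}_f{n}"
            protein = None
            if feat.type == "CDS":
                protein = quals.get("translation", [None])[0]
                if protein is None:
                    logger.warning(
                        "CDS %s in %s has no /translation; kept without protein",
                        fid,
                        rec.id,
                    )
                else:
                    protein = protein.upper().rstrip("*")
            contig.features.append(
                GeneFeature(
                    feature_id=fid,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    product=quals.get("product", [""])[0],
                    protein_seq=protein,
                    locus_tag=locus_tag,
                    feature_type=feat.type,
                )
            )
        contig.features.sort(key=lambda f: (f.start, f.end, f.feature_id))
        contigs[rec.id] = contig
    genome = GenomeAnnotation(genome_id=genome_id or "genome", contigs=contigs)
    genome.validate()
    return genome


def write_genbank(genome: GenomeAnnotation, path, contig_seqs: dict[str, str] | None = None) -> None:
    """Write a genome so that :func:`read_genbank` recovers the feature table.

    ``contig_seqs`` supplies nucleotide sequences; contigs without one get
    an all-``N`` placeholder of the recorded length.  Features extending
    beyond the contig length are refused.
    """
    genome.validate()
    records = []
    for contig in genome.contigs.values():
        for f in contig.features:
            if f.end > contig.length:
                raise GenomeFormatError(
                    f"refusing to write {f.feature_id}: end beyond contig length"
                )
        seq = None
        if contig_seqs and contig.contig_id in contig_seqs:
            seq = contig_seqs[contig.contig_id]
            if len(seq) != contig.length:
                raise GenomeFormatError(
                    f"sequence length mismatch for contig {contig.contig_id}"
                )
        else:
            seq = "N" * contig.length
        rec = SeqRecord(
            Seq(seq),
            id=contig.contig_id,
            name=contig.contig_id[:16],
            description="",
            annotations={
                "molecule_type": "DNA",
                "source": genome.genome_id,
                "organism": genome.genome_id,
            },
        )
        for f in contig.features:
            quals: dict[str, list[str]] = {}
            if f.locus_tag:
                quals["locus_tag"] = [f.locus_tag]
            if f.product:
                quals["product"] = [f.product]
            if f.feature_type == "CDS" and f.protein_seq is not None:
                quals["translation"] = [f.protein_seq]
            quals.setdefault("locus_tag", [f.feature_id])
            rec.features.append(
                SeqFeature(
                    SimpleLocation(f.start - 1, f.end, strand=1 if f.strand == "+" else -1),
                    type=f.feature_type,
                    qualifiers=quals,
                )
            )
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def read_gff_fasta(gff_path, protein_fasta_path) -> GenomeAnnotation:
    """Read GFF3 CDS features and attach proteins from a companion FASTA.

    FASTA ids are matched against the GFF ``ID`` or ``locus_tag``
    attribute; unmatched FASTA records are logged and ignored.  A CDS with
    strand ``.`` is an error — the cluster rules need strands.
    """
    proteins: dict[str, str] = {
        rec.id: str(rec.seq).upper().rstrip("*")
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta")
    }
    contigs: dict[str, Contig] = {}
    contig_lengths: dict[str, int] = {}
    used: set[str] = set()
    genome_id = None
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype not in ("CDS", "tRNA", "rRNA"):
                continue
            if strand not in ("+", "-"):
                raise GenomeFormatError(
                    f"{gff_path}:{lineno}: strand {strand!r}; strand required "
                    "for cluster rules"
                )
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            fid = attr.get("ID") or attr.get("locus_tag")
            if fid is None:
                raise GenomeFormatError(f"{gff_path}:{lineno}: feature without ID")
            protein = proteins.get(fid) or proteins.get(attr.get("locus_tag", ""))
            if protein is not None:
                used.add(fid if fid in proteins else attr.get("locus_tag", ""))
            contigs.setdefault(seqid, Contig(contig_id=seqid, length=0))
            contigs[seqid].features.append(
                GeneFeature(
                    feature_id=fid,
                    contig_id=seqid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    product=attr.get("product", ""),
                    protein_seq=protein if ftype == "CDS" else None,
                    locus_tag=attr.get("locus_tag"),
                    feature_type=ftype,
                )
            )
            genome_id = genome_id or seqid
    for name in set(proteins) - used:
        logger.warning("FASTA record %s matches no GFF feature; ignored", name)
    for contig in contigs.values():
        contig.features.sort(key=lambda f: (f.start, f.end, f.feature_id))
        recorded = contig_lengths.get(contig.contig_id, 0)
        contig.length = max(
            recorded, max((f.end for f in contig.features), default=0)
        )
    genome = GenomeAnnotation(genome_id=genome_id or "genome", contigs=contigs)
    genome.validate()
    return genome
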