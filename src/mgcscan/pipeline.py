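"""End-to-end orchestration: genomes -> roles -> candidates -> subfamilies
-> type 1 calls -> Zn-site calls -> selenium context -> summary report.

Each stage writes its intermediate as TSV so a real BLAST run can be
spliced in at the homology stage; a JSON-lines log records one line per
decision (role call, criterion pass/fail), which makes the manual
genomic-context inspection step auditable.  Given the same config and
seed the pipeline is deterministic and idempotent.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import clusters, selenium_traits, ssn as ssn_mod, znsite
from .genome import GenomeAnnotation, read_genbank
from .homology import assign_roles, local_align_score, make_aligner
from .synthetic import TRIAD_COLUMNS, seed_proteins, seed_sets

logger = logging.getLogger(__name__)

#: Default subfamily labels of the built-in synthetic Mlp references.
BUILTIN_REFERENCE_LABELS = {
    "seed_mlp1": "Mlp1",
    "seed_mlp2": "Mlp2",
    "seed_mlp3": "Mlp3",
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, genome_id: str | None, cause: Exception):
        super().__init__(f"stage {stage} failed"
                         + (f" on genome {genome_id}" if genome_id else "")
                         + f": {cause}")
        self.stage = stage
        self.genome_id = genome_id


@dataclass
class PipelineConfig:
    genomes: list[str] = field(default_factory=list)  # GenBank file paths
    genome_dir: str | None = None
    seed_fasta: dict[str, str] = field(default_factory=dict)  # role -> FASTA
    reference_labels: dict[str, str] = field(default_factory=dict)
    znsite_profile: str | None = None  # YAML path; None -> builtin synthetic
    evalue_threshold: float = 1e-10
    min_bit_score: float = 50.0
    effective_db_size: float | None = None
    max_gap_bp: int = 2000
    exclusion_radius_bp: int = 20000
    ssn_score_threshold: float = 40.0
    repnode_identity: float = 0.5
    length_window: tuple[int, int] = (200, 470)
    subfamily_fallback: str | None = "nearest_reference"
    cooccurrence_full_machinery_only: bool = False
    taxon_metadata: dict[str, tuple[str, str]] = field(default_factory=dict)
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("evalue_threshold", "max_gap_bp", "exclusion_radius_bp",
                     "ssn_score_threshold", "repnode_identity"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = os.path.dirname(os.path.abspath(path))

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        kwargs = {}
        if "genome_dir" in raw:
            kwargs["genome_dir"] = resolve(raw.pop("genome_dir"))
        if "genomes" in raw:
            kwargs["genomes"] = [resolve(p) for p in raw.pop("genomes")]
        if "roles" in raw:
            kwargs["seed_fasta"] = {
                role: resolve(p) for role, p in raw.pop("roles").items()
            }
        if "znsite_profile" in raw:
            kwargs["znsite_profile"] = resolve(raw.pop("znsite_profile"))
        if "taxon_metadata" in raw:
            kwargs["taxon_metadata"] = {
                g: tuple(v) for g, v in raw.pop("taxon_metadata").items()
            }
        if "length_window" in raw:
            kwargs["length_window"] = tuple(raw.pop("length_window"))
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise ConfigError(f"unknown config key {key!r}")
            kwargs[key] = value
        cfg = cls(**kwargs)
        for p in cfg.genomes + list(cfg.seed_fasta.values()):
            if not os.path.exists(p):
                raise ConfigError(f"configured file does not exist: {p}")
        return cfg


@dataclass
class SummaryReport:
    candidates: pd.DataFrame
    subfamilies: pd.DataFrame
    znsite_calls: pd.DataFrame
    selenium: pd.DataFrame
    type1_count: int
    cooccurrence_fraction: float | None
    phylum_tally: pd.DataFrame
    n_genomes: int

    def to_dict(self) -> dict:
        return {
            "n_genomes": self.n_genomes,
            "n_candidates": int(len(self.candidates)),
            "type1_count": self.type1_count,
            "selenium_cooccurrence_fraction": self.cooccurrence_fraction,
            "zn_class_distribution": (
                self.znsite_calls["zn_class"].value_counts().to_dict()
                if len(self.znsite_calls) else {}
            ),
            "phylum_tally": (
                self.phylum_tally.set_index("phylum")["n_genera"].to_dict()
                if len(self.phylum_tally) else {}
            ),
        }


def _load_seed_sets(config: PipelineConfig) -> dict[str, list[tuple[str, str]]]:
    if not config.seed_fasta:
        return seed_sets()
    from Bio import SeqIO

    out: dict[str, list[tuple[str, str]]] = {}
    for role, path in config.seed_fasta.items():
        out[role] = [
            (rec.id, str(rec.seq).upper().rstrip("*"))
            for rec in SeqIO.parse(path, "fasta")
        ]
        if not out[role]:
            raise ConfigError(f"seed FASTA {path} for role {role} is empty")
    return out


def _load_genomes(config: PipelineConfig) -> list[GenomeAnnotation]:
    paths = list(config.genomes)
    if config.genome_dir:
        for pattern in ("*.gbk", "*.gb", "*.gbff"):
            paths.extend(sorted(glob.glob(os.path.join(config.genome_dir, pattern))))
    genomes = []
    for path in paths:
        try:
            genomes.append(read_genbank(path))
        except Exception as exc:
            raise StageError("genome_io", path, exc) from exc
    return genomes


def _builtin_znsite_profiles() -> list[znsite.ReferenceProfile]:
    # one profile per synthetic Mlp family; real runs supply a single
    # characterized reference (e.g. MtaA) that aligns to every Mlp
    seeds = seed_proteins()
    return [
        znsite.ReferenceProfile(
            reference_id=f"seed_{name}",
            reference_seq=seeds[name][1],
            triad_columns=TRIAD_COLUMNS,
        )
        for name in ("mlp1", "mlp2", "mlp3")
    ]


def _nearest_reference_label(
    seq: str, references: dict[str, tuple[str, str]]
) -> str:
    aligner = make_aligner()
    best, best_score = "unassigned", 0.0
    for ref_id, (label, ref_seq) in sorted(references.items()):
        score = local_align_score(seq, ref_seq, aligner)
        if score > best_score:
            best, best_score = label, score
    return best


def run_pipeline(
    config: PipelineConfig,
    genomes: list[GenomeAnnotation] | None = None,
) -> SummaryReport:
    """Execute all stages; returns the summary (and writes artifacts when
    ``config.output_dir`` is set).

    ``genomes`` may be passed directly for library use, bypassing file I/O.
    """
    log_records: list[dict] = []

    def log(stage: str, **kv) -> None:
        log_records.append({"stage": stage, **kv})

    if genomes is None:
        genomes = _load_genomes(config)
    seed_sets_ = _load_seed_sets(config)
    reference_labels = dict(BUILTIN_REFERENCE_LABELS)
    reference_labels.update(config.reference_labels)

    all_roles: dict[str, dict] = {}
    all_candidates: list[clusters.MGCCandidate] = []
    mlp_seqs: dict[str, str] = {}
    feature_genome: dict[str, str] = {}
    for genome in genomes:
        try:
            roles = assign_roles(
                genome,
                seed_sets_,
                evalue_threshold=config.evalue_threshold,
                effective_db_size=config.effective_db_size,
                min_bit_score=config.min_bit_score,
            )
        except Exception as exc:
            raise StageError("homology", genome.genome_id, exc) from exc
        all_roles[genome.genome_id] = roles
        for fid, ra in roles.items():
            if ra.role != "Other":
                log("homology", genome=genome.genome_id, feature=fid,
                    role=ra.role, bit_score=ra.best_hit.bit_score)
        try:
            cands = clusters.find_mgc_candidates(
                genome, roles,
                max_gap_bp=config.max_gap_bp,
                exclusion_radius_bp=config.exclusion_radius_bp,
            )
        except Exception as exc:
            raise StageError("cluster_rules", genome.genome_id, exc) from exc
        all_candidates.extend(cands)
        log("cluster_rules", genome=genome.genome_id, n_candidates=len(cands))
        for f in genome.features():
            if roles.get(f.feature_id) and roles[f.feature_id].role == "Mlp" \
                    and f.protein_seq:
                mlp_seqs[f.feature_id] = f.protein_seq
            feature_genome[f.feature_id] = genome.genome_id

    # SSN stage: candidate Mlps plus labelled references
    subfamilies: dict[str, str] = {}
    references: dict[str, tuple[str, str]] = {}
    for role_seeds in seed_sets_.values():
        for sid, seq in role_seeds:
            if sid in reference_labels:
                references[sid] = (reference_labels[sid], seq)
    network = None
    if mlp_seqs:
        pool = dict(mlp_seqs)
        pool.update({rid: seq for rid, (_, seq) in references.items()})
        try:
            kept = ssn_mod.filter_sequences(pool, config.length_window)
            if len(kept) >= 2:
                reps = ssn_mod.collapse_repnodes(kept, config.repnode_identity)
                network = ssn_mod.build_ssn(
                    reps, config.ssn_score_threshold,
                    length_window=config.length_window,
                    repnode_identity=config.repnode_identity,
                )
                subfamilies = ssn_mod.assign_subfamily(network, reference_labels)
        except ssn_mod.EmptyNetworkError:
            logger.warning("SSN skipped: all Mlp sequences dropped by filter")
        if config.subfamily_fallback == "nearest_reference" and references:
            for fid, seq in mlp_seqs.items():
                if subfamilies.get(fid, "unassigned") == "unassigned":
                    subfamilies[fid] = _nearest_reference_label(seq, references)

    all_candidates = [clusters.classify_type(c, subfamilies) for c in all_candidates]
    for c in all_candidates:
        log("classify_type", genome=c.genome_id, core=list(c.core_ids),
            label=c.label, subfamilies=sorted(c.mlp_subfamilies))

    # Zn-site stage over candidate Mlps
    if config.znsite_profile:
        profiles_zn = [znsite.load_reference_profile(config.znsite_profile)]
    else:
        profiles_zn = _builtin_znsite_profiles()
    zn_calls = []
    candidate_mlps = {
        f.feature_id
        for c in all_candidates
        for f, role in c.core_members
        if role == "Mlp"
    }
    for fid in sorted(candidate_mlps):
        zn_calls.append(
            znsite.map_triad_best(mlp_seqs[fid], profiles_zn, feature_id=fid)
        )

    # Selenium stage
    profiles = []
    for genome in genomes:
        profiles.append(
            selenium_traits.scan_traits(genome, all_roles[genome.genome_id])
        )
    type1_genomes = {c.genome_id for c in all_candidates if c.label == "type1"}
    coocc = None
    if type1_genomes:
        coocc = selenium_traits.cooccurrence_fraction(
            profiles, type1_genomes,
            full_machinery_only=config.cooccurrence_full_machinery_only,
        )

    cand_table = clusters.candidates_to_table(all_candidates)
    if len(cand_table):
        sel_class = {p.genome_id: p.classification for p in profiles}
        cand_table["selenium_context"] = [
            "selenium_associated" if sel_class.get(g, "none") != "none"
            else "non_selenium"
            for g in cand_table["genome_id"]
        ]
    subfam_table = pd.DataFrame(
        [
            {"feature_id": fid, "genome_id": feature_genome.get(fid, ""),
             "subfamily": sf}
            for fid, sf in sorted(subfamilies.items())
        ],
        columns=["feature_id", "genome_id", "subfamily"],
    )
    report = SummaryReport(
        candidates=cand_table,
        subfamilies=subfam_table,
        znsite_calls=znsite.calls_to_table(zn_calls),
        selenium=selenium_traits.profiles_to_table(profiles),
        type1_count=int(sum(c.label == "type1" for c in all_candidates)),
        cooccurrence_fraction=coocc,
        phylum_tally=tally_phyla(all_candidates, config.taxon_metadata),
        n_genomes=len(genomes),
    )
    if config.output_dir:
        _write_artifacts(config, report, network, log_records)
    return report


def tally_phyla(
    candidates: list, taxon_metadata: dict[str, tuple[str, str]]
) -> pd.DataFrame:
    """Distinct genera per phylum among MGC-positive genomes.

    Genomes without metadata are counted under ``unclassified``; the
    fraction column sums to 1 (when any genera are counted).
    """
    positive = sorted({c.genome_id for c in candidates})
    if not positive:
        return pd.DataFrame(columns=["phylum", "n_genera", "fraction"])
    genera_by_phylum: dict[str, set[str]] = {}
    for genome_id in positive:
        genus, phylum = taxon_metadata.get(
            genome_id, (genome_id, "unclassified")
        )
        genera_by_phylum.setdefault(phylum, set()).add(genus)
    rows = [
        {"phylum": ph, "n_genera": len(gs)}
        for ph, gs in sorted(genera_by_phylum.items())
    ]
    df = pd.DataFrame(rows)
    df["fraction"] = df["n_genera"] / df["n_genera"].sum()
    return df.sort_values("n_genera", ascending=False).reset_index(drop=True)


def _write_artifacts(config, report: SummaryReport, network, log_records) -> None:
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    report.candidates.to_csv(os.path.join(out, "candidates.tsv"),
                             sep="\t", index=False)
    report.subfamilies.to_csv(os.path.join(out, "subfamilies.tsv"),
                              sep="\t", index=False)
    report.znsite_calls.to_csv(os.path.join(out, "znsite.tsv"),
                               sep="\t", index=False)
    report.selenium.to_csv(os.path.join(out, "selenium.tsv"),
                           sep="\t", index=False)
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(out, "log.jsonl"), "w") as fh:
        for rec in log_records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    if network is not None:
        ssn_mod.export_tsv(
            network,
            os.path.join(out, "ssn_nodes.tsv"),
            os.path.join(out, "ssn_edges.tsv"),
            os.path.join(out, "ssn_clusters.tsv"),
        )
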