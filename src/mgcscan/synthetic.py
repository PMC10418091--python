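"""Ground-truthed synthetic genomes and kinetic datasets.

Every pipeline stage is exercisable at desk scale from these generators:

* a deterministic set of synthetic seed proteins, one family per role in
  the role vocabulary (the shipped ``data/seeds/synthetic_*.faa`` files
  are this generator's output — they are synthetic stand-ins, not
  database sequences);
* planted gene clusters whose proteins are seeded point-mutants of the
  seed proteins at a requested identity, with Zn-triad columns protected;
* decoy clusters violating exactly one MGC criterion each, with the
  violated criterion recorded in the truth table;
* background genes with seed-like composition but no seed homology
  (residue-shuffled seeds);
* noisy initial-rate datasets from the substrate-inhibition model.

All generators are pure functions of (spec, seed): the same inputs give
byte-identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .genome import Contig, GeneFeature, GenomeAnnotation, write_genbank
from .kinetics import KineticDataset, substrate_inhibition_rate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: 1-based Zn-triad columns engineered into every Mlp seed (His, Cys, Cys).
TRIAD_COLUMNS = (120, 180, 220)

#: (role, length) of each synthetic seed family.  The Mlp seeds sit inside
#: the 200-470 aa SSN length window.
SEED_SPECS = {
    "mlp1": ("Mlp", 330),
    "mlp2": ("Mlp", 330),
    "mlp3": ("Mlp", 330),
    "corrinoid": ("CorrinoidProtein", 220),
    "ram": ("RamRACE", 400),
    "h4folate": ("H4folateMethylase", 300),
    "selA": ("SelA", 350),
    "selB": ("SelB", 450),
    "selD": ("SelD", 340),
    "glyreductase": ("GlyReductase", 300),
    "marHDK": ("MarHDK", 280),
}

_SEED_MASTER_SEED = 20230731

DEFAULT_CLUSTER_ORDER = ("mlp1", "mlp2", "corrinoid", "mlp3", "ram")

VIOLATIONS = (
    "none",
    "missing_ram",
    "missing_corrinoid",
    "one_mlp_only",
    "divergent_intervening",
    "gap_gt_2kb",
    "h4folate_within_20kb",
)

#: MGC criterion targeted by each decoy violation.
VIOLATED_CRITERION = {
    "missing_ram": 1,
    "missing_corrinoid": 1,
    "one_mlp_only": 1,
    "divergent_intervening": 2,
    "gap_gt_2kb": 3,
    "h4folate_within_20kb": 4,
}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def seed_proteins() -> dict[str, tuple[str, str]]:
    """The synthetic seed set: seed name -> (role, sequence).

    Deterministic; Mlp seeds carry H/C/C at :data:`TRIAD_COLUMNS`.
    """
    rng = np.random.default_rng(_SEED_MASTER_SEED)
    out: dict[str, tuple[str, str]] = {}
    for name, (role, length) in SEED_SPECS.items():
        seq = list(_random_protein(rng, length))
        if role == "Mlp":
            for col, res in zip(TRIAD_COLUMNS, "HCC"):
                seq[col - 1] = res
        out[name] = (role, "".join(seq))
    return out


def seed_sets() -> dict[str, list[tuple[str, str]]]:
    """Seed proteins grouped by role, as assign_roles expects."""
    groups: dict[str, list[tuple[str, str]]] = {}
    for name, (role, seq) in seed_proteins().items():
        groups.setdefault(role, []).append((f"seed_{name}", seq))
    return groups


def write_seed_fasta(directory) -> dict[str, str]:
    """Write one synthetic multi-FASTA per role; returns role -> path."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths: dict[str, str] = {}
    by_role: dict[str, list[tuple[str, str]]] = seed_sets()
    for role, seeds in sorted(by_role.items()):
        path = os.path.join(directory, f"synthetic_{role.lower()}.faa")
        with open(path, "w") as fh:
            for sid, seq in seeds:
                fh.write(f">{sid} synthetic seed protein, role {role}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        paths[role] = path
    return paths


def mutate_to_identity(
    seq: str,
    target_identity: float,
    seed: int | np.random.Generator,
    protected_columns: tuple[int, ...] = (),
) -> str:
    """Seeded point mutations taking ``seq`` to a requested global identity.

    Substitutions (always to a different residue) are placed at positions
    outside ``protected_columns`` (1-based), so the realized identity is
    exactly ``1 - k/len`` with ``k = round((1-target)*len)`` — within two
    percentage points of the target whenever enough unprotected positions
    exist.
    """
    if not 0.2 < target_identity <= 1.0:
        raise ValueError("target_identity must be in (0.2, 1.0]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = len(seq)
    k = round((1.0 - target_identity) * L)
    if k == 0:
        return seq
    candidates = np.array(
        [i for i in range(L) if (i + 1) not in protected_columns], dtype=int
    )
    if k > len(candidates):
        raise ValueError("too many mutations requested for protected sequence")
    positions = rng.choice(candidates, size=k, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def shuffled_background_protein(
    rng: np.random.Generator, length: int, pool: list[str]
) -> str:
    """A background protein: seed-pool composition, no seed homology.

    Draws residues (with replacement) from the concatenated seed pool,
    keeping amino-acid frequencies realistic without retaining order.
    """
    concat = "".join(pool)
    idx = rng.integers(0, len(concat), size=length)
    return "".join(concat[i] for i in idx)


@dataclass(frozen=True)
class ClusterSpec:
    """One planted cluster (violation == 'none') or decoy (anything else)."""

    gene_order: tuple[str, ...] = DEFAULT_CLUSTER_ORDER
    strand: str = "+"
    intergenic_gaps: tuple[int, ...] | int = 100
    violation: str = "none"
    triad_spec: dict[str, tuple[str, str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.violation not in VIOLATIONS:
            raise ValueError(f"unknown violation {self.violation}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


DecoySpec = ClusterSpec  # a decoy is a ClusterSpec with a violation set


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    seed: int
    genome_id: str = "syn"
    n_background_genes: int = 20
    planted_clusters: tuple[ClusterSpec, ...] = ()
    decoys: tuple[ClusterSpec, ...] = ()
    identity_to_seed: float = 0.6
    extra_roles: tuple[str, ...] = ()  # seed names planted as standalone genes
    unit_spacing_bp: int = 25000
    background_spacing_bp: tuple[int, int] = (200, 2000)


def _apply_violation(spec: ClusterSpec) -> tuple[ClusterSpec, list[str]]:
    """Rewrite the gene order/gaps for the requested violation.

    Returns the effective spec and a list of post-processing directives.
    """
    order = list(spec.gene_order)
    directives: list[str] = []
    if spec.violation == "missing_ram":
        order = [g for g in order if g != "ram"]
    elif spec.violation == "missing_corrinoid":
        order = [g for g in order if g != "corrinoid"]
    elif spec.violation == "one_mlp_only":
        mlps = [g for g in order if g.startswith("mlp")]
        order = [g for g in order if not g.startswith("mlp") or g == mlps[0]]
    elif spec.violation == "divergent_intervening":
        directives.append("insert_divergent")
    elif spec.violation == "gap_gt_2kb":
        directives.append("widen_gap")
    elif spec.violation == "h4folate_within_20kb":
        directives.append("append_h4folate")
    return replace(spec, gene_order=tuple(order)), directives


def _build_unit(
    spec: ClusterSpec,
    unit_id: str,
    start: int,
    identity: float,
    seeds: dict[str, tuple[str, str]],
    rng: np.random.Generator,
    feature_counter: list[int],
    contig_id: str,
    pool: list[str],
) -> tuple[list[GeneFeature], dict[str, str], int]:
    """Lay out one planted unit; returns (features, roles_by_gene_name, end)."""
    eff, directives = _apply_violation(spec)
    order = list(eff.gene_order)
    n_gaps = max(len(order) - 1, 0)
    if isinstance(eff.intergenic_gaps, int):
        gaps = [eff.intergenic_gaps] * n_gaps
    else:
        gaps = list(eff.intergenic_gaps)
        if len(gaps) != n_gaps:
            raise ValueError("intergenic_gaps length mismatch")
    if "widen_gap" in directives and n_gaps:
        gaps[min(2, n_gaps - 1)] = 2500  # > the 2 kb criterion
    features: list[GeneFeature] = []
    gene_names: dict[str, str] = {}
    pos = start
    insert_after = len(order) // 2 - 1 if "insert_divergent" in directives else None
    for i, seed_name in enumerate(order):
        role, seed_seq = seeds[seed_name]
        protected = TRIAD_COLUMNS if role == "Mlp" else ()
        protein = mutate_to_identity(seed_seq, identity, rng, protected)
        if role == "Mlp":
            triad = spec.triad_spec.get(seed_name, ("H", "C", "C"))
            plist = list(protein)
            for col, res in zip(TRIAD_COLUMNS, triad):
                plist[col - 1] = res
            protein = "".join(plist)
        feature_counter[0] += 1
        fid = f"{unit_id}_{seed_name}"
        length_bp = 3 * len(protein) + 3
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=contig_id,
                start=pos,
                end=pos + length_bp - 1,
                strand=eff.strand,
                product=f"synthetic {seed_name} homolog",
                protein_seq=protein,
                locus_tag=fid,
            )
        )
        gene_names[seed_name] = fid
        pos += length_bp
        if i == insert_after:
            # a divergently-transcribed background gene inside the cluster
            div_protein = shuffled_background_protein(rng, 150, pool)
            div_len = 3 * len(div_protein) + 3
            div_id = f"{unit_id}_divergent"
            features.append(
                GeneFeature(
                    feature_id=div_id,
                    contig_id=contig_id,
                    start=pos + 100,
                    end=pos + 100 + div_len - 1,
                    strand="-" if eff.strand == "+" else "+",
                    product="synthetic divergent background gene",
                    protein_seq=div_protein,
                    locus_tag=div_id,
                )
            )
            pos += 100 + div_len + 100
            if i < n_gaps:
                gaps[i] = 100  # gap beyond the inserted gene
        if i < n_gaps:
            pos += gaps[i]
    if "append_h4folate" in directives:
        role, seed_seq = seeds["h4folate"]
        protein = mutate_to_identity(seed_seq, identity, rng)
        fid = f"{unit_id}_h4folate"
        length_bp = 3 * len(protein) + 3
        h4_start = pos + 5000  # well inside the 20 kb exclusion radius
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=contig_id,
                start=h4_start,
                end=h4_start + length_bp - 1,
                strand=eff.strand,
                product="synthetic H4folate methylase homolog",
                protein_seq=protein,
                locus_tag=fid,
            )
        )
        pos = h4_start + length_bp
    return features, gene_names, pos - 1


def generate_genome(spec: SyntheticGenomeSpec):
    """Build a synthetic genome and its truth table.

    Returns ``(GenomeAnnotation, truth_rows)`` where ``truth_rows`` is a
    list of dicts (unit id, kind, span, expected label, violation and
    the criterion a decoy must be rejected by, plus the planted core
    gene ids).
    """
    rng = np.random.default_rng(spec.seed)
    seeds = seed_proteins()
    pool = [seq for _, seq in seeds.values()]
    contig_id = f"{spec.genome_id}_c1"
    features: list[GeneFeature] = []
    truth: list[dict] = []
    counter = [0]
    pos = 1 + int(rng.integers(0, 500))

    units = [("cluster", i, c) for i, c in enumerate(spec.planted_clusters)]
    units += [("decoy", i, d) for i, d in enumerate(spec.decoys)]
    for kind, idx, cspec in units:
        unit_id = f"{spec.genome_id}_{kind}{idx}"
        unit_feats, gene_names, end = _build_unit(
            cspec, unit_id, pos, spec.identity_to_seed, seeds, rng,
            counter, contig_id, pool,
        )
        features.extend(unit_feats)
        core_ids = [
            f.feature_id
            for f in unit_feats
            if seeds.get(f.feature_id.rsplit("_", 1)[-1], ("", ""))[0]
            in ("Mlp", "CorrinoidProtein", "RamRACE")
        ]
        truth.append(
            {
                "unit_id": unit_id,
                "kind": kind,
                "contig_id": contig_id,
                "start": min(f.start for f in unit_feats),
                "end": end,
                "violation": cspec.violation,
                "expected_label": "type1" if cspec.violation == "none" else "none",
                "expected_criterion": VIOLATED_CRITERION.get(cspec.violation, 0),
                "core_ids": ",".join(core_ids),
            }
        )
        pos = end + spec.unit_spacing_bp

    for seed_name in spec.extra_roles:
        role, seed_seq = seeds[seed_name]
        protein = mutate_to_identity(seed_seq, spec.identity_to_seed, rng)
        fid = f"{spec.genome_id}_{seed_name}"
        length_bp = 3 * len(protein) + 3
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=contig_id,
                start=pos,
                end=pos + length_bp - 1,
                strand="+" if rng.integers(2) else "-",
                product=f"synthetic {seed_name} homolog",
                protein_seq=protein,
                locus_tag=fid,
            )
        )
        pos += length_bp + spec.unit_spacing_bp

    lo, hi = spec.background_spacing_bp
    for i in range(spec.n_background_genes):
        length_aa = int(rng.integers(150, 451))
        protein = shuffled_background_protein(rng, length_aa, pool)
        fid = f"{spec.genome_id}_bg{i:04d}"
        length_bp = 3 * length_aa + 3
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=contig_id,
                start=pos,
                end=pos + length_bp - 1,
                strand="+" if rng.integers(2) else "-",
                product="synthetic background gene",
                protein_seq=protein,
                locus_tag=fid,
            )
        )
        pos += length_bp + int(rng.integers(lo, hi + 1))

    features.sort(key=lambda f: (f.start, f.end, f.feature_id))
    contig = Contig(contig_id=contig_id, length=pos + 1000, features=features)
    genome = GenomeAnnotation(genome_id=spec.genome_id, contigs={contig_id: contig})
    genome.validate()
    return genome, truth


def truth_table(truth_rows: list[dict]):
    import pandas as pd

    return pd.DataFrame(
        truth_rows,
        columns=["unit_id", "kind", "contig_id", "start", "end", "violation",
                 "expected_label", "expected_criterion", "core_ids"],
    )


def write_genome_files(spec: SyntheticGenomeSpec, genbank_path, truth_path=None,
                       fasta_path=None) -> None:
    """Materialise a spec as GenBank + truth TSV + protein FASTA.

    The nucleotide sequence is seeded random DNA, so identical
    (spec, seed) gives byte-identical files.
    """
    genome, truth = generate_genome(spec)
    rng = np.random.default_rng(spec.seed + 1)
    seqs = {
        cid: "".join(rng.choice(list("ACGT"), size=contig.length))
        for cid, contig in genome.contigs.items()
    }
    write_genbank(genome, genbank_path, contig_seqs=seqs)
    if truth_path is not None:
        truth_table(truth).to_csv(truth_path, sep="\t", index=False)
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for f in genome.features():
                if f.protein_seq:
                    fh.write(f">{f.feature_id}\n{f.protein_seq}\n")


def generate_kinetic_dataset(
    kcat: float,
    KM: float,
    KI: float,
    substrate_levels_uM,
    replicates: int = 3,
    noise_cv: float = 0.03,
    seed: int = 0,
) -> KineticDataset:
    """Noisy initial rates from the substrate-inhibition model.

    Rates are ``model(S) * (1 + eps)`` with ``eps ~ Normal(0, noise_cv)``;
    ``noise_cv = 0`` returns exact model values.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    S = np.repeat(np.asarray(substrate_levels_uM, dtype=float), replicates)
    rep = np.tile(np.arange(replicates), len(substrate_levels_uM))
    v = substrate_inhibition_rate(S, kcat, KM, KI)
    if noise_cv > 0:
        v = v * (1.0 + rng.normal(0.0, noise_cv, size=len(S)))
    return KineticDataset(substrate_uM=S, rate_per_min=v, replicate_id=rep)


def random_role_genome(
    seed: int, n_genes: int = 60, genome_id: str = "rand"
) -> tuple[GenomeAnnotation, dict[str, str]]:
    """A random annotated genome plus a random role map (no proteins).

    Used for rule-engine stress tests: roles are drawn directly (skipping
    homology search), strands come in runs, and intergenic gaps straddle
    the 2 kb criterion boundary; occasional large gaps and H4folate
    methylase calls exercise criteria 3 and 4.
    """
    rng = np.random.default_rng(seed)
    contig_id = f"{genome_id}_c1"
    roles = {}
    features = []
    pos = 1
    strand = "+"
    role_choices = np.array(
        ["Mlp", "CorrinoidProtein", "RamRACE", "H4folateMethylase", "Other"]
    )
    role_p = np.array([0.28, 0.14, 0.14, 0.05, 0.39])
    for i in range(n_genes):
        if rng.random() < 0.25:
            strand = "+" if strand == "-" else "-"
        length = int(rng.integers(200, 1600))
        fid = f"{genome_id}_g{i:04d}"
        features.append(
            GeneFeature(
                feature_id=fid,
                contig_id=contig_id,
                start=pos,
                end=pos + length - 1,
                strand=strand,
            )
        )
        roles[fid] = str(rng.choice(role_choices, p=role_p))
        gap_kind = rng.random()
        if gap_kind < 0.15:
            gap = int(rng.integers(0, 3))  # abutting / tiny
        elif gap_kind < 0.75:
            gap = int(rng.integers(50, 1900))
        elif gap_kind < 0.92:
            gap = int(rng.integers(1900, 2300))  # straddles the 2 kb boundary
        else:
            gap = int(rng.integers(15000, 26000))  # straddles the 20 kb radius
        pos += length + gap
    contig = Contig(contig_id=contig_id, length=pos + 1000, features=features)
    genome = GenomeAnnotation(genome_id=genome_id, contigs={contig_id: contig})
    return genome, roles
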