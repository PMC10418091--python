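"""The four-criterion gene-cluster rule engine and type 1 classification.

A "true" *mlp* gene cluster (MGC) must:

1. encode at least two Mlps, a corrinoid protein and a Ram/RACE protein;
2. have all of these transcribed in the same direction with no
   intervening divergently-transcribed genes;
3. have no more than 2 kb of intergenic DNA between adjacent core genes
   (same-strand non-core genes sitting inside the cluster reduce the
   measured intergenic DNA by their extents);
4. have no tetrahydrofolate-methylase homolog within 20 kb of any core
   gene (nearest-edge distance).

``find_mgc_candidates`` is the production path; ``brute_force_candidates``
re-checks the criteria literally on every contiguous window and serves as
the testing oracle.  Reported candidates are maximal: no candidate is a
sub-run of another.

A cluster is "type 1" when its Mlps include at least one Mlp2 and one
Mlp3 subfamily member (subfamilies come from the SSN stage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome import GeneFeature, GenomeAnnotation, intergenic_gap
from .homology import CORE_ROLES, RoleAssignment

MAX_GAP_BP = 2000
EXCLUSION_RADIUS_BP = 20000

CRITERION_DESCRIPTIONS = {
    1: "composition: >=2 Mlps, >=1 corrinoid protein, >=1 Ram/RACE",
    2: "co-directional with no intervening divergently-transcribed genes",
    3: "no more than 2 kb of intergenic DNA between adjacent core genes",
    4: "no H4folate methylase within 20 kb of any core gene",
}


@dataclass
class MGCCandidate:
    genome_id: str
    contig_id: str
    core_members: list[tuple[GeneFeature, str]]
    noncore_members: list[tuple[GeneFeature, str]]
    span: tuple[int, int]
    max_internal_gap: int
    strand: str
    mlp_subfamilies: list[str] = field(default_factory=list)
    label: str = "other_mgc"
    rejection_log: list[tuple[int, str]] = field(default_factory=list)

    @property
    def core_ids(self) -> tuple[str, ...]:
        return tuple(f.feature_id for f, _ in self.core_members)

    def key(self) -> tuple:
        """Identity of a candidate for set comparisons."""
        return (self.genome_id, self.contig_id, self.core_ids)

    @property
    def n_mlps(self) -> int:
        return sum(1 for _, role in self.core_members if role == "Mlp")


def _roles_of(roles) -> dict[str, str]:
    """Accept either a role-name map or a RoleAssignment map."""
    out = {}
    for fid, r in roles.items():
        out[fid] = r.role if isinstance(r, RoleAssignment) else r
    return out


def _coding_features(contig, include_rna: bool) -> list[GeneFeature]:
    if include_rna:
        return list(contig.features)
    return [f for f in contig.features if f.feature_type == "CDS"]


def _measured_gap(a: GeneFeature, b: GeneFeature, between: list[GeneFeature]) -> int:
    """Intergenic DNA between adjacent core members a < b.

    bp covered by other annotated genes inside the interval are not
    counted as intergenic DNA (interval-union arithmetic; the brute-force
    oracle recounts per-position).
    """
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    gap_lo, gap_hi = lo.end + 1, hi.start - 1  # inclusive interval
    if gap_hi < gap_lo:
        return 0
    intervals = []
    for g in between:
        s, e = max(g.start, gap_lo), min(g.end, gap_hi)
        if s <= e:
            intervals.append((s, e))
    covered = 0
    intervals.sort()
    cur_s, cur_e = None, None
    for s, e in intervals:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return (gap_hi - gap_lo + 1) - covered


def _edge_distance(a: GeneFeature, b: GeneFeature) -> int:
    """Nearest-edge distance in bp between two gene extents (0 if overlapping)."""
    if a.contig_id != b.contig_id:
        raise ValueError("edge distance across contigs is undefined")
    return intergenic_gap(a, b)


def _check_window(
    core: list[GeneFeature],
    role_map: dict[str, str],
    all_features: list[GeneFeature],
    h4f_features: list[GeneFeature],
    max_gap_bp: int,
    exclusion_radius_bp: int,
) -> list[tuple[int, str]]:
    """Evaluate the four criteria for a window of core genes; return failures."""
    failures: list[tuple[int, str]] = []
    roles = [role_map[f.feature_id] for f in core]
    n_mlp = roles.count("Mlp")
    n_corr = roles.count("CorrinoidProtein")
    n_ram = roles.count("RamRACE")
    if not (n_mlp >= 2 and n_corr >= 1 and n_ram >= 1):
        failures.append(
            (1, f"composition {n_mlp} Mlp / {n_corr} corrinoid / {n_ram} Ram "
                "(need >=2/>=1/>=1)")
        )
    strands = {f.strand for f in core}
    span_start, span_end = min(f.start for f in core), max(f.end for f in core)
    core_ids = {f.feature_id for f in core}
    inside = [
        g for g in all_features
        if g.feature_id not in core_ids and g.end >= span_start and g.start <= span_end
    ]
    if len(strands) > 1:
        failures.append((2, "core genes on both strands"))
    else:
        strand = next(iter(strands))
        divergent = [g for g in inside if g.strand != strand]
        if divergent:
            failures.append(
                (2, "divergently-transcribed gene(s) inside cluster: "
                    + ",".join(g.feature_id for g in divergent))
            )
    ordered = sorted(core, key=lambda f: (f.start, f.end))
    max_gap_seen = 0
    for a, b in zip(ordered, ordered[1:]):
        gap = _measured_gap(a, b, inside)
        max_gap_seen = max(max_gap_seen, gap)
        if gap > max_gap_bp:
            failures.append(
                (3, f"{gap} bp of intergenic DNA between {a.feature_id} and "
                    f"{b.feature_id} (> {max_gap_bp})")
            )
    for h in h4f_features:
        for f in core:
            d = _edge_distance(h, f)
            if d <= exclusion_radius_bp:
                failures.append(
                    (4, f"H4folate methylase {h.feature_id} within "
                        f"{d} bp of {f.feature_id} (<= {exclusion_radius_bp})")
                )
                break
    return failures


def _window_to_candidate(
    genome: GenomeAnnotation,
    contig_id: str,
    core: list[GeneFeature],
    role_map: dict[str, str],
    all_features: list[GeneFeature],
) -> MGCCandidate:
    ordered = sorted(core, key=lambda f: (f.start, f.end))
    span = (min(f.start for f in ordered), max(f.end for f in ordered))
    core_ids = {f.feature_id for f in ordered}
    inside = [
        g for g in all_features
        if g.feature_id not in core_ids and g.end >= span[0] and g.start <= span[1]
    ]
    max_gap = 0
    for a, b in zip(ordered, ordered[1:]):
        max_gap = max(max_gap, _measured_gap(a, b, inside))
    return MGCCandidate(
        genome_id=genome.genome_id,
        contig_id=contig_id,
        core_members=[(f, role_map[f.feature_id]) for f in ordered],
        noncore_members=[(g, role_map.get(g.feature_id, "Other")) for g in inside],
        span=span,
        max_internal_gap=max_gap,
        strand=ordered[0].strand,
    )


def _maximal(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Keep windows (index ranges over core features) not contained in another."""
    out = []
    for i, j in windows:
        if not any((p <= i and j <= q) and (p, q) != (i, j) for p, q in windows):
            out.append((i, j))
    return sorted(set(out))


def find_mgc_candidates(
    genome: GenomeAnnotation,
    roles,
    max_gap_bp: int = MAX_GAP_BP,
    exclusion_radius_bp: int = EXCLUSION_RADIUS_BP,
    include_rna: bool = False,
) -> list[MGCCandidate]:
    """All maximal gene windows satisfying the four MGC criteria.

    ``roles`` maps feature_id to a role name (or RoleAssignment).  Returns
    an empty list when nothing qualifies.
    """
    role_map = _roles_of(roles)
    candidates: list[MGCCandidate] = []
    for contig in genome.contigs.values():
        feats = _coding_features(contig, include_rna)
        core_feats = [f for f in feats if role_map.get(f.feature_id) in CORE_ROLES]
        if len(core_feats) < 4:
            continue
        h4f = [f for f in feats if role_map.get(f.feature_id) == "H4folateMethylase"]
        # chain break-points between consecutive core features: strand flip,
        # oversized measured gap, or an opposite-strand gene in between.
        chains: list[list[int]] = [[0]]
        for idx in range(1, len(core_feats)):
            a, b = core_feats[idx - 1], core_feats[idx]
            between = [
                g for g in feats
                if g.feature_id not in (a.feature_id, b.feature_id)
                and g.end >= a.start and g.start <= b.end
            ]
            ok = (
                a.strand == b.strand
                and _measured_gap(a, b, between) <= max_gap_bp
                and all(
                    g.strand == a.strand
                    for g in between
                    if g.end >= a.start and g.start <= b.end
                )
            )
            if ok:
                chains[-1].append(idx)
            else:
                chains.append([idx])
        for chain in chains:
            passing: list[tuple[int, int]] = []
            for i in range(len(chain)):
                for j in range(i, len(chain)):
                    window = [core_feats[k] for k in chain[i : j + 1]]
                    if not _check_window(
                        window, role_map, feats, h4f, max_gap_bp, exclusion_radius_bp
                    ):
                        passing.append((chain[i], chain[j]))
            for i, j in _maximal(passing):
                candidates.append(
                    _window_to_candidate(
                        genome, contig.contig_id, core_feats[i : j + 1], role_map, feats
                    )
                )
    candidates.sort(key=lambda c: (c.contig_id, c.span))
    return candidates


def brute_force_candidates(
    genome: GenomeAnnotation,
    roles,
    max_gap_bp: int = MAX_GAP_BP,
    exclusion_radius_bp: int = EXCLUSION_RADIUS_BP,
    include_rna: bool = False,
    size_guard: int = 500,
) -> list[MGCCandidate]:
    """Literal re-check of the four criteria on every contiguous window.

    Testing oracle for :func:`find_mgc_candidates`; refuses genomes above
    ``size_guard`` features.  The gap measurement recounts intergenic
    positions one by one, independent of the fast path's interval
    arithmetic.
    """
    n_features = len(genome.features())
    if n_features > size_guard:
        raise ValueError(f"brute_force_candidates: genome too large ({n_features})")
    role_map = _roles_of(roles)
    candidates: list[MGCCandidate] = []
    for contig in genome.contigs.values():
        feats = _coding_features(contig, include_rna)
        core_feats = [f for f in feats if role_map.get(f.feature_id) in CORE_ROLES]
        h4f = [f for f in feats if role_map.get(f.feature_id) == "H4folateMethylase"]
        passing: list[tuple[int, int]] = []
        for i in range(len(core_feats)):
            for j in range(i, len(core_feats)):
                window = core_feats[i : j + 1]
                if _bf_window_passes(
                    window, role_map, feats, h4f, max_gap_bp, exclusion_radius_bp
                ):
                    passing.append((i, j))
        for i, j in _maximal(passing):
            candidates.append(
                _window_to_candidate(
                    genome, contig.contig_id, core_feats[i : j + 1], role_map, feats
                )
            )
    candidates.sort(key=lambda c: (c.contig_id, c.span))
    return candidates


def _bf_window_passes(
    core: list[GeneFeature],
    role_map: dict[str, str],
    feats: list[GeneFeature],
    h4f: list[GeneFeature],
    max_gap_bp: int,
    exclusion_radius_bp: int,
) -> bool:
    roles = [role_map[f.feature_id] for f in core]
    if roles.count("Mlp") < 2 or roles.count("CorrinoidProtein") < 1 or roles.count("RamRACE") < 1:
        return False
    if len({f.strand for f in core}) != 1:
        return False
    strand = core[0].strand
    span_start = min(f.start for f in core)
    span_end = max(f.end for f in core)
    core_ids = {f.feature_id for f in core}
    inside = [
        g for g in feats
        if g.feature_id not in core_ids and g.end >= span_start and g.start <= span_end
    ]
    if any(g.strand != strand for g in inside):
        return False
    ordered = sorted(core, key=lambda f: (f.start, f.end))
    for a, b in zip(ordered, ordered[1:]):
        # literal per-position count of intergenic DNA between a and b
        gap = 0
        for pos in range(a.end + 1, b.start):
            if not any(g.start <= pos <= g.end for g in inside):
                gap += 1
        if gap > max_gap_bp:
            return False
    for h in h4f:
        for f in core:
            if intergenic_gap(h, f) <= exclusion_radius_bp:
                return False
    return True


def diagnose_window(
    genome: GenomeAnnotation,
    roles,
    core_feature_ids: list[str],
    max_gap_bp: int = MAX_GAP_BP,
    exclusion_radius_bp: int = EXCLUSION_RADIUS_BP,
    include_rna: bool = False,
) -> list[tuple[int, str]]:
    """Which criteria a given set of core genes fails, with reasons.

    Used to audit near-misses: an empty list means the window qualifies.
    """
    role_map = _roles_of(roles)
    wanted = set(core_feature_ids)
    for contig in genome.contigs.values():
        feats = _coding_features(contig, include_rna)
        window = [f for f in feats if f.feature_id in wanted]
        if not window:
            continue
        if len(window) != len(wanted):
            raise KeyError("core features span multiple contigs or are missing")
        h4f = [f for f in feats if role_map.get(f.feature_id) == "H4folateMethylase"]
        return _check_window(
            window, role_map, feats, h4f, max_gap_bp, exclusion_radius_bp
        )
    raise KeyError(f"no features found for {core_feature_ids}")


def classify_type(
    candidate: MGCCandidate, subfamily_assignments: dict[str, str]
) -> MGCCandidate:
    """Set the type 1 / other label from Mlp subfamily membership.

    A candidate is type 1 iff its Mlps include at least one Mlp2 and at
    least one Mlp3; a missing Mlp1 does not matter.
    """
    subfams = [
        subfamily_assignments.get(f.feature_id, "unassigned")
        for f, role in candidate.core_members
        if role == "Mlp"
    ]
    label = "type1" if ("Mlp2" in subfams and "Mlp3" in subfams) else "other_mgc"
    return replace(candidate, mlp_subfamilies=subfams, label=label)


def candidates_to_table(candidates: list[MGCCandidate]):
    """Flatten candidates into a report table (one row per candidate)."""
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append(
            {
                "genome_id": c.genome_id,
                "contig_id": c.contig_id,
                "span_start": c.span[0],
                "span_end": c.span[1],
                "strand": c.strand,
                "n_core": len(c.core_members),
                "n_mlps": c.n_mlps,
                "max_internal_gap": c.max_internal_gap,
                "subfamilies": ",".join(sorted(c.mlp_subfamilies)),
                "label": c.label,
                "core_ids": ",".join(c.core_ids),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "contig_id", "span_start", "span_end", "strand",
            "n_core", "n_mlps", "max_internal_gap", "subfamilies", "label",
            "core_ids",
        ],
    )
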