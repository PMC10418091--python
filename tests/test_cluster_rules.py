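import pytest

from mgcscan.clusters import (
    brute_force_candidates,
    classify_type,
    diagnose_window,
    find_mgc_candidates,
)
from mgcscan.genome import Contig, GenomeAnnotation
from mgcscan.synthetic import random_role_genome

from conftest import F, make_genome


def cluster_genome(extra=(), ram_strand="+", gap_corr_mlp3=100, h4f_offset=None):
    """A canonical five-gene cluster, optionally perturbed."""
    feats = [
        F("mlp1", 1000, 1999),
        F("mlp2", 2100, 3099),
        F("corr", 3200, 3899),
    ]
    mlp3_start = 3900 + gap_corr_mlp3
    feats.append(F("mlp3", mlp3_start, mlp3_start + 999))
    ram_start = mlp3_start + 1100
    feats.append(F("ram", ram_start, ram_start + 1199, strand=ram_strand))
    if h4f_offset is not None:
        h_start = feats[-1].end + h4f_offset + 1
        feats.append(F("h4f", h_start, h_start + 899))
    feats = list(feats) + list(extra)
    roles = {
        "mlp1": "Mlp", "mlp2": "Mlp", "mlp3": "Mlp",
        "corr": "CorrinoidProtein", "ram": "RamRACE", "h4f": "H4folateMethylase",
    }
    for f in extra:
        roles.setdefault(f.feature_id, "Other")
    return make_genome(feats, length=200000), roles


class TestPlantedExamples:
    def test_canonical_cluster_found_with_three_mlps(self):
        genome, roles = cluster_genome()
        (cand,) = find_mgc_candidates(genome, roles)
        assert cand.n_mlps == 3
        assert cand.core_ids == ("mlp1", "mlp2", "corr", "mlp3", "ram")
        assert cand.strand == "+"

    def test_divergent_ram_inside_cluster_disqualifies(self):
        # ram on the minus strand between corr and mlp3
        feats = [
            F("mlp1", 1000, 1999), F("mlp2", 2100, 3099), F("corr", 3200, 3899),
            F("ram", 4000, 4999, strand="-"), F("mlp3", 5100, 6099),
        ]
        roles = {"mlp1": "Mlp", "mlp2": "Mlp", "mlp3": "Mlp",
                 "corr": "CorrinoidProtein", "ram": "RamRACE"}
        genome = make_genome(feats, length=20000)
        assert find_mgc_candidates(genome, roles) == []

    @pytest.mark.parametrize("offset,n_expected", [(19000, 0), (21000, 1)])
    def test_h4folate_exclusion_radius(self, offset, n_expected):
        genome, roles = cluster_genome(h4f_offset=offset)
        assert len(find_mgc_candidates(genome, roles)) == n_expected

    @pytest.mark.parametrize("gap,n_expected", [(2001, 0), (2000, 1)])
    def test_two_kb_gap_boundary(self, gap, n_expected):
        genome, roles = cluster_genome(gap_corr_mlp3=gap)
        assert len(find_mgc_candidates(genome, roles)) == n_expected

    def test_same_strand_noncore_gene_inside_reduces_measured_gap(self):
        # corr..mlp3 raw distance 2700 bp, but a same-strand 1-kb gene inside
        # leaves only 1700 bp of intergenic DNA -> cluster accepted
        extra = (F("ins", 4400, 5399),)
        genome, roles = cluster_genome(extra=extra, gap_corr_mlp3=2700)
        (cand,) = find_mgc_candidates(genome, roles)
        assert "ins" in {f.feature_id for f, _ in cand.noncore_members}

    def test_opposite_strand_gene_inside_disqualifies(self):
        extra = (F("ins", 4000, 4050, strand="-"),)
        genome, roles = cluster_genome(extra=extra)
        assert find_mgc_candidates(genome, roles) == []

    def test_rna_feature_inside_is_ignored_by_default(self):
        extra = (F("trna", 4000, 4070, strand="-", ftype="tRNA"),)
        genome, roles = cluster_genome(extra=extra)
        assert len(find_mgc_candidates(genome, roles)) == 1
        assert find_mgc_candidates(genome, roles, include_rna=True) == []


class TestClassifyType:
    def _candidate(self, subfams):
        genome, roles = cluster_genome()
        (cand,) = find_mgc_candidates(genome, roles)
        mapping = dict(zip(["mlp1", "mlp2", "mlp3"], subfams))
        return classify_type(cand, mapping)

    def test_all_three_subfamilies_is_type1(self):
        assert self._candidate(["Mlp1", "Mlp2", "Mlp3"]).label == "type1"

    def test_mlp1_absence_does_not_matter(self):
        assert self._candidate(["unassigned", "Mlp2", "Mlp3"]).label == "type1"

    def test_missing_mlp3_is_other(self):
        assert self._candidate(["Mlp1", "Mlp2", "unassigned"]).label == "other_mgc"


class TestDiagnose:
    def test_missing_ram_fails_composition(self):
        genome, roles = cluster_genome()
        failed = diagnose_window(genome, roles, ["mlp1", "mlp2", "corr", "mlp3"])
        assert {c for c, _ in failed} == {1}

    def test_wide_gap_fails_criterion_3_only(self):
        genome, roles = cluster_genome(gap_corr_mlp3=2500)
        failed = diagnose_window(
            genome, roles, ["mlp1", "mlp2", "corr", "mlp3", "ram"]
        )
        assert {c for c, _ in failed} == {3}

    def test_nearby_h4folate_fails_criterion_4_only(self):
        genome, roles = cluster_genome(h4f_offset=5000)
        failed = diagnose_window(
            genome, roles, ["mlp1", "mlp2", "corr", "mlp3", "ram"]
        )
        assert {c for c, _ in failed} == {4}

    def test_qualifying_window_has_no_failures(self):
        genome, roles = cluster_genome()
        assert diagnose_window(
            genome, roles, ["mlp1", "mlp2", "corr", "mlp3", "ram"]
        ) == []


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_genomes(self):
        for seed in range(150):
            genome, roles = random_role_genome(seed, n_genes=40)
            fast = [c.key() for c in find_mgc_candidates(genome, roles)]
            slow = [c.key() for c in brute_force_candidates(genome, roles)]
            assert fast == slow, f"seed {seed}"

    def test_zero_role_genome_is_empty(self):
        genome, _ = random_role_genome(3, n_genes=20)
        roles = {f.feature_id: "Other" for f in genome.features()}
        assert find_mgc_candidates(genome, roles) == []
        assert brute_force_candidates(genome, roles) == []

    def test_one_giant_valid_cluster_spans_contig(self):
        feats, roles = [], {}
        pos = 1
        for i, role in enumerate(
            ["Mlp", "CorrinoidProtein", "Mlp", "RamRACE"] * 4
        ):
            fid = f"g{i}"
            feats.append(F(fid, pos, pos + 899))
            roles[fid] = role
            pos += 1000
        genome = make_genome(feats)
        (fast,) = find_mgc_candidates(genome, roles)
        (slow,) = brute_force_candidates(genome, roles)
        assert fast.key() == slow.key()
        assert len(fast.core_members) == 16

    def test_size_guard_refuses_large_genomes(self):
        genome, roles = random_role_genome(1, n_genes=30)
        with pytest.raises(ValueError, match="too large"):
            brute_force_candidates(genome, roles, size_guard=10)


class TestStructuralProperties:
    def test_deleting_any_core_member_removes_the_candidate(self):
        removed_any = False
        for seed in range(40):
            genome, roles = random_role_genome(seed, n_genes=50)
            for cand in find_mgc_candidates(genome, roles):
                for victim in cand.core_ids:
                    contig = next(iter(genome.contigs.values()))
                    pruned = make_genome(
                        [f for f in contig.features if f.feature_id != victim],
                        length=contig.length,
                        contig=contig.contig_id,
                    )
                    keys = {c.key()[2] for c in find_mgc_candidates(pruned, roles)}
                    assert cand.core_ids not in keys
                    removed_any = True
        assert removed_any  # the corpus actually produced candidates

    def test_strand_mirror_symmetry(self):
        flip = {"+": "-", "-": "+"}
        for seed in range(30):
            genome, roles = random_role_genome(seed, n_genes=50)
            contig = next(iter(genome.contigs.values()))
            L = contig.length
            mirrored = make_genome(
                [
                    F(f.feature_id, L - f.end + 1, L - f.start + 1,
                      flip[f.strand])
                    for f in contig.features
                ],
                length=L,
            )
            orig = {frozenset(c.core_ids) for c in find_mgc_candidates(genome, roles)}
            mirr = {
                frozenset(c.core_ids)
                for c in find_mgc_candidates(mirrored, roles)
            }
            assert orig == mirr, f"seed {seed}"

    def test_tightening_parameters_never_creates_new_ground(self):
        # every candidate under tighter settings is a sub-run of a looser one
        for seed in range(30):
            genome, roles = random_role_genome(seed, n_genes=50)
            loose = find_mgc_candidates(genome, roles)
            for kw in ({"max_gap_bp": 800}, {"exclusion_radius_bp": 40000}):
                tight = find_mgc_candidates(genome, roles, **kw)
                for c in tight:
                    assert any(
                        set(c.core_ids) <= set(p.core_ids) for p in loose
                    ), f"seed {seed} {kw}"


def test_candidates_are_maximal_never_nested():
    for seed in range(40):
        genome, roles = random_role_genome(seed, n_genes=60)
        cands = find_mgc_candidates(genome, roles)
        for i, a in enumerate(cands):
            for b in cands[i + 1 :]:
                assert not set(a.core_ids) <= set(b.core_ids)
                assert not set(b.core_ids) <= set(a.core_ids)
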