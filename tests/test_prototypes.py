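import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scsim import (SnvModelParams, assign_substitutions,
                   build_prototype_genomes, place_snv_sites)
from scsim.errors import ConfigurationError
from scsim.prototypes import (TIER_ALL, TIER_HALF, TIER_UNIFORM, ZYG_HET,
                              ZYG_HOM, tier_counts)
from scsim.reads import materialize_haplotype


class TestPlacement:
    def test_protocol_spacing(self):
        sites = place_snv_sites(1_000_000, 100, K=3, margin_fraction=0.1, seed=0)
        gaps = np.diff([s.position for s in sites])
        assert set(gaps) == {8080}
        assert sites[0].position == 100_000

    def test_single_site_at_midpoint(self):
        sites = place_snv_sites(1000, 1, K=2, seed=0)
        assert len(sites) == 1 and sites[0].position == 500
        assert sites[0].tier == TIER_ALL

    def test_too_dense_raises(self):
        with pytest.raises(ConfigurationError):
            place_snv_sites(100, 90, K=2, margin_fraction=0.1, seed=0)

    @given(st.integers(min_value=1, max_value=500))
    def test_tier_split_sums_and_matches_rule(self, n):
        c_all, c_half, c_unif = tier_counts(n)
        assert c_all + c_half + c_unif == n
        assert c_all == -(-n // 3)
        if n % 3 == 0:
            assert c_all == c_half == c_unif == n // 3

    def test_all_tier_present_everywhere(self):
        sites = place_snv_sites(100_000, 99, K=4, seed=1)
        all_sites = [s for s in sites if s.tier == TIER_ALL]
        assert len(all_sites) == 33
        assert all(s.presence.all() for s in all_sites)

    def test_half_tier_ceil_k_over_2(self):
        for K in (2, 3, 4, 5):
            sites = place_snv_sites(100_000, 30, K=K, seed=2)
            for s in sites:
                if s.tier == TIER_HALF:
                    assert s.presence.sum() == -(-K // 2)

    def test_uniform_tier_never_orphan(self):
        sites = place_snv_sites(100_000, 300, K=5, seed=3)
        assert all(s.presence.sum() >= 1 for s in sites if s.tier == TIER_UNIFORM)


class TestSubstitutions:
    def test_all_het_at_p_one(self, small_reference):
        sites = place_snv_sites(len(small_reference), 40, K=3, seed=5)
        sites = assign_substitutions(sites, small_reference,
                                     SnvModelParams(p_het=1.0), seed=6)
        for s in sites:
            assert all(z in (0, ZYG_HET) for z in s.zygosity)
            assert (s.zygosity == ZYG_HET).sum() == s.presence.sum()

    def test_deterministic_matrix_forces_alt(self, small_reference):
        m = np.zeros((4, 4))
        m[0, 2] = 1.0            # A -> G
        m[1, 3] = 1.0            # C -> T
        m[2, 0] = 1.0            # G -> A
        m[3, 1] = 1.0            # T -> C
        params = SnvModelParams(subst_matrix=m)
        sites = place_snv_sites(len(small_reference), 40, K=2, seed=7)
        sites = assign_substitutions(sites, small_reference, params, seed=8)
        expect = {"A": "G", "C": "T", "G": "A", "T": "C"}
        assert all(s.alt_base == expect[s.ref_base] for s in sites)

    def test_alt_differs_from_ref_and_shared(self, assigned_sites):
        for s in assigned_sites:
            assert s.alt_base != s.ref_base
            assert s.ref_base in "ACGT"

    def test_n_reference_bases_shifted_right(self):
        ref = "ACGT" * 10 + "N" * 5 + "ACGT" * 10
        sites = place_snv_sites(len(ref), 5, K=1, margin_fraction=0.0, seed=9)
        sites = assign_substitutions(sites, ref, SnvModelParams(), seed=10)
        assert all(ref[s.position] != "N" for s in sites)
        assert len({s.position for s in sites}) == len(sites)

    def test_bad_matrix_rejected(self, small_reference):
        m = np.full((4, 4), 0.25)
        with pytest.raises(ConfigurationError):
            SnvModelParams(subst_matrix=m)  # nonzero diagonal


class TestGenomes:
    def test_hom_edits_both_het_edits_one(self, small_reference, assigned_sites):
        genomes = build_prototype_genomes(small_reference, assigned_sites, seed=11)
        by_pos = {s.position: s for s in assigned_sites}
        for g in genomes:
            a, b = dict(g.haplotype_a), dict(g.haplotype_b)
            for pos, site in by_pos.items():
                z = int(site.zygosity[g.index])
                n_haps = (pos in a) + (pos in b)
                assert n_haps == {0: 0, ZYG_HET: 1, ZYG_HOM: 2}[z]

    def test_absent_prototype_equals_reference(self, small_reference):
        sites = place_snv_sites(len(small_reference), 10, K=3, seed=12)
        # force everything into prototype 0 only
        for s in sites:
            s.presence[:] = False
            s.presence[0] = True
        sites = assign_substitutions(sites, small_reference,
                                     SnvModelParams(), seed=13)
        genomes = build_prototype_genomes(small_reference, sites, seed=14)
        assert genomes[1].haplotype_a == () and genomes[1].haplotype_b == ()

    def test_brute_force_diff_recovers_site_table(self):
        """Materialize each haplotype and per-base diff against the
        reference: the edits recovered must equal the SnvSite table."""
        from scsim import make_fixture_reference
        _, ref = make_fixture_reference(1000, seed=55)
        sites = place_snv_sites(1000, 10, K=3, seed=56)
        sites = assign_substitutions(sites, ref, SnvModelParams(), seed=57)
        genomes = build_prototype_genomes(ref, sites, seed=58)
        ref_codes = materialize_haplotype(ref, [])
        union_edited = set()
        for g in genomes:
            for hap in (g.haplotype_a, g.haplotype_b):
                codes = materialize_haplotype(ref, hap)
                assert codes.shape == ref_codes.shape  # SNVs only: no indels
                diff_pos = set(np.flatnonzero(codes != ref_codes).tolist())
                assert diff_pos == {p for p, _ in hap}
                for p, alt in hap:
                    assert "ACGTN"[codes[p]] == alt
                union_edited |= diff_pos
        present_somewhere = {s.position for s in sites if s.presence.any()}
        assert union_edited == present_somewhere
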