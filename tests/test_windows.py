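"""Window construction, FST, diversity, fixed differences, distances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster

from supergene.windows import (
    fixed_differences,
    genotype_distance_matrix,
    make_windows,
    multilocus_fst,
    nucleotide_diversity,
    str_fixed_differences,
)

from .util import brute_force_fst, build_sampleset, build_str, build_vt


class TestMakeWindows:
    def test_plain_tiling_without_gaps(self):
        seq = "A" * 100_000
        wins = make_windows(seq, "s", 30_000, 10_000)
        full = [w for w in wins if not w.partial]
        assert [w.start for w in full] == [0, 10_000, 20_000, 30_000,
                                           40_000, 50_000, 60_000, 70_000]
        assert all(w.accessible == 30_000 for w in full)

    def test_window_stretches_over_n_gap(self):
        seq = "A" * 10_000 + "N" * 5_000 + "A" * 100_000
        wins = make_windows(seq, "s", 30_000, 10_000)
        w0 = wins[0]
        # oracle: explicit scan of non-N positions
        non_n = [i for i, c in enumerate(seq[:50_000]) if c != "N"]
        assert w0.start == non_n[0]
        assert w0.end == non_n[30_000 - 1] + 1
        assert w0.end == 35_000  # 5 kb N block pushes the end 5 kb further
        assert w0.accessible == 30_000
        # steps are in accessible coordinates too
        assert wins[1].start == non_n[10_000]

    def test_size_equals_step_is_nonoverlapping(self):
        wins = make_windows("A" * 50_000, "s", 10_000, 10_000)
        full = [w for w in wins if not w.partial]
        for a, b in zip(full, full[1:]):
            assert a.end == b.start

    def test_all_n_sequence_yields_no_windows(self):
        assert make_windows("N" * 5_000, "s", 1_000, 500) == []

    def test_terminal_partial_window_flagged(self):
        wins = make_windows("A" * 25_000, "s", 10_000, 10_000)
        assert [w.partial for w in wins] == [False, False, True]
        assert wins[-1].accessible == 5_000


class TestMultilocusFst:
    def test_fixed_difference_site_is_one(self):
        ss = build_sampleset(8)
        vt = build_vt([[0] * 8 + [1] * 8])
        assert multilocus_fst(vt, ss) == pytest.approx(1.0)

    def test_private_singleton_in_groups_of_two_is_zero(self):
        ss = build_sampleset(2)
        # calls {A,A} vs {A,T}
        vt = build_vt([[0, 0, 0, 1]])
        assert multilocus_fst(vt, ss) == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_window_undefined(self):
        ss = build_sampleset(4)
        vt = build_vt([[0] * 8])
        assert np.isnan(multilocus_fst(vt, ss))

    def test_pair_private_variants_give_negative_fst(self):
        ss = build_sampleset(8)
        rows = []
        for pair in range(8):
            row = [0] * 16
            row[pair] = 1
            row[8 + pair] = 1
            rows.append(row)
        vt = build_vt(rows)
        assert multilocus_fst(vt, ss) < 0

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_agrees_with_brute_force_anova(self, seed):
        rng = np.random.default_rng(seed)
        n_sites = int(rng.integers(1, 20))
        geno = rng.integers(0, rng.integers(2, 4), size=(n_sites, 16))
        ss = build_sampleset(8)
        vt = build_vt(geno)
        mine = multilocus_fst(vt, ss)
        oracle = brute_force_fst(geno[:, :8], geno[:, 8:])
        if np.isnan(oracle):
            assert np.isnan(mine)
        else:
            assert mine == pytest.approx(oracle, abs=1e-12)


class TestNucleotideDiversity:
    def test_monomorphic_window_is_zero(self):
        ss = build_sampleset(4)
        vt = build_vt([[0] * 8])
        assert nucleotide_diversity(vt, ss, "SB", accessible=10_000) == 0.0

    def test_balanced_snp_among_eight(self):
        # 4/4 split among 8 haploids over 10 kb: mean pairwise difference
        # = 16/28 per site
        ss = build_sampleset(8)
        vt = build_vt([[0, 0, 0, 0, 1, 1, 1, 1] + [0] * 8])
        pi = nucleotide_diversity(vt, ss, "SB", accessible=10_000)
        assert pi == pytest.approx(16 / 28 / 10_000)
        assert pi == pytest.approx(5.714e-5, rel=1e-3)

    def test_two_singletons_among_eight(self):
        ss = build_sampleset(8)
        rows = [[1] + [0] * 7 + [0] * 8, [0] * 7 + [1] + [0] * 8]
        pi = nucleotide_diversity(build_vt(rows), ss, "SB", accessible=10_000)
        assert pi == pytest.approx(5.0e-5)

    def test_equals_mean_pairwise_difference_oracle(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(0, 2, size=(30, 16))
        ss = build_sampleset(8)
        pi = nucleotide_diversity(build_vt(geno), ss, "SB", accessible=1_000)
        # oracle: average hamming distance over all 28 pairs
        g = geno[:, :8]
        total = 0
        pairs = 0
        for i in range(8):
            for j in range(i + 1, 8):
                total += (g[:, i] != g[:, j]).sum()
                pairs += 1
        assert pi == pytest.approx(total / pairs / 1_000)

    def test_unbiased_under_subsampling(self, small_sim):
        # the unbiased estimator's expectation is invariant to taking a
        # random subset of the group's samples
        from supergene import filters
        from supergene.io import SampleSet

        ss = small_sim.samples
        vt = filters.apply_variant_filters(small_sim.variants, ss, "SB")
        acc = sum(small_sim.truth.accessible.values())
        full = nucleotide_diversity(vt, ss, "SB", accessible=acc)
        sb = ss.group_members("SB")
        subs = []
        rng = np.random.default_rng(8)
        for _ in range(30):
            pick = list(rng.choice(sb, size=4, replace=False))
            ss_sub = SampleSet(pick + ss.group_members("Sb"),
                               dict(ss.groups), dict(ss.coverage_class))
            subs.append(nucleotide_diversity(vt, ss_sub, "SB", accessible=acc))
        assert np.mean(subs) == pytest.approx(full, rel=0.05)

    def test_invariant_to_relabelling_within_group(self):
        rng = np.random.default_rng(6)
        geno = rng.integers(0, 2, size=(40, 16))
        ss = build_sampleset(8)
        pi1 = nucleotide_diversity(build_vt(geno), ss, "SB", accessible=1_000)
        perm = np.concatenate([rng.permutation(8), np.arange(8, 16)])
        pi2 = nucleotide_diversity(build_vt(geno[:, perm]), ss, "SB",
                                   accessible=1_000)
        assert pi1 == pytest.approx(pi2)


class TestFixedDifferences:
    def test_clean_fixed_site_counted(self):
        ss = build_sampleset(8)
        snp, indel, idx = fixed_differences(build_vt([[0] * 8 + [1] * 8]), ss)
        assert (snp, indel) == (1, 0) and list(idx) == [0]

    def test_one_discordant_call_not_counted(self):
        ss = build_sampleset(8)
        row = [0] * 8 + [1] * 7 + [0]
        snp, indel, _ = fixed_differences(build_vt([row]), ss)
        assert snp == 0

    def test_indels_tallied_separately(self):
        ss = build_sampleset(8)
        vt = build_vt([[0] * 8 + [1] * 8], vclass="indel", ref="AT", alt="A")
        snp, indel, _ = fixed_differences(vt, ss)
        assert (snp, indel) == (0, 1)

    def test_fixed_site_has_unit_fst(self):
        # every fixed-difference site, restricted to itself, has FST 1
        rng = np.random.default_rng(7)
        geno = rng.integers(0, 2, size=(50, 16))
        geno[13] = [0] * 8 + [1] * 8
        geno[29] = [1] * 8 + [0] * 8
        ss = build_sampleset(8)
        vt = build_vt(geno)
        _, _, idx = fixed_differences(vt, ss)
        assert {13, 29} <= set(idx.tolist())
        for i in idx:
            one = vt.take_sites(np.array([i]))
            assert multilocus_fst(one, ss) == pytest.approx(1.0)


class TestSTRFixedDifferences:
    def test_all_equal_units_no_loci(self):
        ss = build_sampleset(4)
        df = str_fixed_differences(build_str([[10] * 8]), ss)
        assert df.empty

    def test_fixed_unit_difference_reported(self):
        ss = build_sampleset(4)
        df = str_fixed_differences(build_str([[10, 10, 10, 10, 12, 12, 12, 12]]), ss)
        assert len(df) == 1
        assert df.loc[0, "unit_difference"] == 2

    def test_within_group_variation_excluded(self):
        ss = build_sampleset(4)
        df = str_fixed_differences(build_str([[10, 11, 10, 10, 12, 12, 12, 12]]), ss)
        assert df.empty


class TestGenotypeDistances:
    def test_identical_samples_distance_zero(self):
        vt = build_vt(np.zeros((10, 4)))
        d, _, _ = genotype_distance_matrix(vt)
        assert np.all(d == 0)

    def test_k_differences_give_sqrt_k(self):
        geno = np.zeros((9, 4), dtype=int)
        geno[:4, 1] = 1  # sample 2 differs from sample 1 at 4 sites
        d, _, _ = genotype_distance_matrix(build_vt(geno))
        assert d[0, 1] == pytest.approx(2.0)

    def test_planted_two_cluster_structure_recovered(self, small_sim):
        from supergene import filters
        from supergene.windows import Window

        ss = small_sim.samples
        vt = filters.apply_variant_filters(small_sim.variants, ss, "all")
        scaf, start, end = small_sim.truth.region_span
        w = Window(scaf, start, end, end - start)
        sub = vt.take_sites((vt.scaffold == scaf) & (vt.pos - 1 >= start)
                            & (vt.pos - 1 < end))
        d, z, samples = genotype_distance_matrix(sub)
        clusters = fcluster(z, t=2, criterion="maxclust")
        by_group = {g: {clusters[i] for i, s in enumerate(samples)
                        if ss.groups[s] == g} for g in ("SB", "Sb")}
        assert len(by_group["SB"]) == 1 and len(by_group["Sb"]) == 1
        assert by_group["SB"] != by_group["Sb"]
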