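"""Windowed empirical-style analyses on hand-built micro-fixtures."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tepop import popgen_windows as pw


def mk_calls(rows, genotypes, samples=None):
    """rows: list of dicts (chrom/pos/clade/...); genotypes: (loci, n) array."""
    defaults = {
        "chrom": "chr1", "clade": "L1", "category": "nLTR-RT", "length": 1000,
        "divergence": 0.01, "call_rate": 1.0,
        "consensus_start": np.nan, "consensus_end": np.nan,
    }
    meta = pd.DataFrame(
        [{**defaults, **r} for r in rows],
        columns=["pos", *defaults],
    )
    G = np.asarray(genotypes, np.int8)
    if samples is None:
        samples = [f"s{i}" for i in range(G.shape[1])]
    return pw.TECallSet(meta, G, samples)


def windows_df(*triples):
    return pd.DataFrame(
        [{"chrom": c, "start": s, "end": e} for c, s, e in triples]
    )


class TestResolveDuplicates:
    def test_lower_divergence_wins(self):
        calls = mk_calls(
            [
                {"pos": 1000, "divergence": 0.04},
                {"pos": 2500, "divergence": 0.02},
            ],
            [[1, 0], [0, 1]],
        )
        out = pw.resolve_duplicates(calls)
        assert out.n_loci == 1
        assert out.meta["divergence"].iloc[0] == 0.02

    def test_equal_divergence_highest_call_rate_wins(self):
        calls = mk_calls(
            [
                {"pos": 1000, "divergence": 0.02, "call_rate": 0.9},
                {"pos": 1500, "divergence": 0.02, "call_rate": 1.0},
            ],
            [[1, 0], [0, 1]],
        )
        out = pw.resolve_duplicates(calls)
        assert out.n_loci == 1
        assert out.meta["call_rate"].iloc[0] == 1.0

    def test_beyond_threshold_both_kept(self):
        calls = mk_calls(
            [{"pos": 1000}, {"pos": 3500}],
            [[1, 0], [0, 1]],
        )
        assert pw.resolve_duplicates(calls).n_loci == 2

    def test_exactly_2000_bp_not_duplicates(self):
        calls = mk_calls(
            [{"pos": 1000}, {"pos": 3000}],  # distance exactly 2000
            [[1, 0], [0, 1]],
        )
        assert pw.resolve_duplicates(calls).n_loci == 2

    def test_different_clades_not_duplicates(self):
        calls = mk_calls(
            [{"pos": 1000, "clade": "L1"}, {"pos": 1500, "clade": "L2"}],
            [[1, 0], [0, 1]],
        )
        assert pw.resolve_duplicates(calls).n_loci == 2

    def test_chain_of_three_keeps_one(self):
        calls = mk_calls(
            [
                {"pos": 1000, "divergence": 0.05},
                {"pos": 2500, "divergence": 0.01},
                {"pos": 4000, "divergence": 0.03},
            ],
            [[1, 0], [0, 1], [1, 1]],
        )
        out = pw.resolve_duplicates(calls)
        assert out.n_loci == 1
        assert out.meta["divergence"].iloc[0] == 0.01


class TestDropMissing:
    def test_locus_with_missing_dropped(self):
        calls = mk_calls(
            [{"pos": 1000}, {"pos": 9000}],
            [[1, pw.MISSING], [0, 1]],
        )
        out = pw.drop_missing(calls)
        assert out.n_loci == 1
        assert out.meta["pos"].iloc[0] == 9000

    def test_complete_matrix_identity(self):
        calls = mk_calls([{"pos": 1000}], [[1, 2]])
        assert pw.drop_missing(calls).n_loci == 1

    def test_empty_input(self):
        calls = mk_calls([], np.empty((0, 2), np.int8))
        assert pw.drop_missing(calls).n_loci == 0


class TestWindowTEStats:
    def test_below_min_poly_mean_undefined(self):
        calls = mk_calls(
            [{"pos": 100}, {"pos": 200}],
            [[1, 0, 0], [1, 1, 0]],
        )
        w = windows_df(("chr1", 0, 1000))
        out = pw.window_te_stats(calls, w, ["s0", "s1", "s2"], min_poly=3)
        assert out.loc[0, "n_poly"] == 2
        assert np.isnan(out.loc[0, "mean_freq"])

    def test_all_fixed(self):
        calls = mk_calls(
            [{"pos": p} for p in (10, 20, 30, 40, 50)],
            np.full((5, 2), 2),
        )
        w = windows_df(("chr1", 0, 1000))
        out = pw.window_te_stats(calls, w, ["s0", "s1"])
        assert out.loc[0, "n_fixed"] == 5
        assert out.loc[0, "n_poly"] == 0

    def test_mean_frequency_arithmetic(self):
        # frequencies 0.25, 0.5, 0.75 in a 2-diploid population
        calls = mk_calls(
            [{"pos": p} for p in (10, 20, 30)],
            [[1, 0], [1, 1], [2, 1]],
        )
        w = windows_df(("chr1", 0, 1000))
        out = pw.window_te_stats(calls, w, ["s0", "s1"], min_poly=3)
        assert out.loc[0, "mean_freq"] == pytest.approx(0.5)

    def test_zero_te_window_excluded(self):
        calls = mk_calls([{"pos": 100}], [[1, 0]])
        w = windows_df(("chr1", 0, 1000), ("chr1", 1000, 2000))
        out = pw.window_te_stats(calls, w, ["s0", "s1"])
        assert not out.loc[0, "excluded"]
        assert out.loc[1, "excluded"]

    def test_unsorted_windows_error(self):
        calls = mk_calls([{"pos": 100}], [[1, 0]])
        w = windows_df(("chr1", 1000, 2000), ("chr1", 0, 1000))
        with pytest.raises(ValueError, match="unsorted"):
            pw.window_te_stats(calls, w, ["s0", "s1"])

    def test_overlapping_windows_error(self):
        calls = mk_calls([{"pos": 100}], [[1, 0]])
        w = windows_df(("chr1", 0, 1000), ("chr1", 500, 1500))
        with pytest.raises(ValueError, match="overlap"):
            pw.window_te_stats(calls, w, ["s0", "s1"])

    def test_row_order_invariance(self):
        rows = [{"pos": p} for p in (10, 500, 900)]
        G = [[1, 0], [1, 1], [0, 1]]
        w = windows_df(("chr1", 0, 1000))
        a = pw.window_te_stats(mk_calls(rows, G), w, ["s0", "s1"])
        perm = [2, 0, 1]
        b = pw.window_te_stats(
            mk_calls([rows[i] for i in perm], [G[i] for i in perm]),
            w, ["s0", "s1"],
        )
        pd.testing.assert_frame_equal(a, b)

    def test_counts_conservation(self):
        rng = np.random.default_rng(3)
        rows = [{"pos": int(p)} for p in rng.integers(1, 3001, 60)]
        G = rng.integers(0, 3, size=(60, 4))
        calls = mk_calls(rows, G)
        w = windows_df(("chr1", 0, 1000), ("chr1", 1000, 2000), ("chr1", 2000, 3000))
        out = pw.window_te_stats(calls, w, [f"s{i}" for i in range(4)])
        ac = calls.allele_counts([f"s{i}" for i in range(4)])
        n_absent = int((ac == 0).sum())
        assert out["n_total"].sum() == 60
        assert (out["n_poly"] + out["n_fixed"]).sum() == 60 - n_absent


def mk_snps(positions, genotypes, samples, chrom="chr1"):
    meta = pd.DataFrame({"chrom": chrom, "pos": positions})
    return pw.SNPSet(meta, np.asarray(genotypes, np.int8), samples)


@pytest.fixture
def toy_popmap():
    return pw.PopulationMap(
        {
            "a1": "A", "a2": "A", "b1": "B", "b2": "B",
            "og1": "outgroup_allisoni", "og2": "outgroup_porcatus",
        }
    )


class TestPolarize:
    def test_outgroups_reference_homozygous(self, toy_popmap):
        # outgroups 0/0 -> ALT is derived; ingroup ALT dosages sum 2.4/8? use 0.3
        snps = mk_snps(
            [100],
            [[1, 1, 0, 0, 0, 0]],  # freq(alt)=2/8? columns a1,a2,b1,b2,og1,og2
            ["a1", "a2", "b1", "b2", "og1", "og2"],
        )
        res = pw.polarize(snps, toy_popmap)
        assert res.n_dropped == 0
        assert res.daf[0] == pytest.approx(0.25)
        assert res.derived_is_alt[0]

    def test_outgroups_alt_homozygous_flips_direction(self, toy_popmap):
        snps = mk_snps(
            [100],
            [[2, 2, 2, 1, 2, 2]],
            ["a1", "a2", "b1", "b2", "og1", "og2"],
        )
        res = pw.polarize(snps, toy_popmap)
        # ancestral is ALT; derived (REF) frequency = 1 - 7/8
        assert res.daf[0] == pytest.approx(1 / 8)
        assert not res.derived_is_alt[0]

    def test_disagreeing_outgroups_dropped(self, toy_popmap):
        snps = mk_snps(
            [100, 200],
            [[1, 0, 0, 0, 0, 2], [1, 0, 0, 0, 2, 2]],
            ["a1", "a2", "b1", "b2", "og1", "og2"],
        )
        res = pw.polarize(snps, toy_popmap)
        assert res.n_dropped == 1
        assert res.kept.tolist() == [False, True]

    def test_heterozygous_outgroup_dropped(self, toy_popmap):
        snps = mk_snps(
            [100],
            [[1, 0, 0, 0, 1, 0]],
            ["a1", "a2", "b1", "b2", "og1", "og2"],
        )
        assert pw.polarize(snps, toy_popmap).n_dropped == 1


def brute_force_pairwise(G1, G2, L):
    """Mean between-population pairwise difference per bp by enumerating
    haplotype draws binomially from genotype frequencies (independent oracle:
    expected difference per site = p1(1-p2) + p2(1-p1))."""
    p1 = G1.sum(axis=1) / (2 * G1.shape[1])
    p2 = G2.sum(axis=1) / (2 * G2.shape[1])
    return float(np.sum(p1 * (1 - p2) + p2 * (1 - p1)) / L)


class TestWindowSNPStats:
    def test_identical_populations_fst_zero(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(40, 4))
        snps = mk_snps(
            np.arange(1, 41) * 10, np.hstack([G, G]),
            [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        )
        w = windows_df(("chr1", 0, 1000))
        pops = {
            "A": [f"a{i}" for i in range(4)],
            "B": [f"b{i}" for i in range(4)],
        }
        out = pw.window_snp_stats(snps, w, pops)
        assert out.loc[0, "fst_A_B"] == pytest.approx(0.0, abs=1e-9) or (
            out.loc[0, "fst_A_B"] < 0
        )

    def test_fixed_differences(self):
        n_snp = 10
        GA = np.full((n_snp, 3), 2)
        GB = np.zeros((n_snp, 3))
        snps = mk_snps(
            np.arange(1, n_snp + 1) * 50, np.hstack([GA, GB]),
            ["a0", "a1", "a2", "b0", "b1", "b2"],
        )
        w = windows_df(("chr1", 0, 1000))
        out = pw.window_snp_stats(
            snps, w, {"A": ["a0", "a1", "a2"], "B": ["b0", "b1", "b2"]}
        )
        assert out.loc[0, "fst_A_B"] == pytest.approx(1.0)
        assert out.loc[0, "dxy_A_B"] == pytest.approx(n_snp / 1000)
        assert out.loc[0, "theta_pi_A"] == 0.0

    def test_hand_computed_hudson(self):
        # 3 SNPs, allele counts written out
        GA = np.array([[1, 1], [2, 0], [1, 0]])  # p1 = .5, .5, .25 (n1=4)
        GB = np.array([[0, 0], [2, 2], [1, 1]])  # p2 = 0, 1, .5  (n2=4)
        snps = mk_snps(
            [10, 20, 30], np.hstack([GA, GB]), ["a0", "a1", "b0", "b1"]
        )
        w = windows_df(("chr1", 0, 100))
        out = pw.window_snp_stats(
            snps, w, {"A": ["a0", "a1"], "B": ["b0", "b1"]}
        )
        num, den = pw.hudson_fst(
            np.array([0.5, 0.5, 0.25]), np.array([0.0, 1.0, 0.5]),
            np.array([4, 4, 4]), np.array([4, 4, 4]),
        )
        # manual: per-SNP numerators (p1-p2)^2 - p1(1-p1)/3 - p2(1-p2)/3
        man_num = [
            0.25 - 0.25 / 3 - 0.0, 0.25 - 0.25 / 3 - 0.0,
            0.0625 - (0.25 * 0.75) / 3 - 0.25 / 3,
        ]
        man_den = [0.5, 0.5, 0.25 * 0.5 + 0.5 * 0.75]
        assert num == pytest.approx(man_num)
        assert den == pytest.approx(man_den)
        assert out.loc[0, "fst_A_B"] == pytest.approx(sum(man_num) / sum(man_den))
        assert out.loc[0, "dxy_A_B"] == pytest.approx(
            brute_force_pairwise(GA, GB, 100)
        )

    def test_theta_pi_unbiased_factor(self):
        # one SNP at p=0.5 in 2 diploids: 2p(1-p) * n/(n-1) = .5 * 4/3
        snps = mk_snps([10], [[1, 1]], ["a0", "a1"])
        w = windows_df(("chr1", 0, 100))
        out = pw.window_snp_stats(snps, w, {"A": ["a0", "a1"]})
        assert out.loc[0, "theta_pi_A"] == pytest.approx(0.5 * 4 / 3 / 100)


class TestROverMu:
    def test_zero_rho(self):
        assert pw.r_over_mu([0.0], [1e-3])[0] == 0.0

    def test_arithmetic(self):
        assert pw.r_over_mu([4e-3], [2e-3])[0] == pytest.approx(2.0)

    def test_ne_scaling_invariance(self):
        a = pw.r_over_mu([4e-3], [2e-3])[0]
        b = pw.r_over_mu([8e-3], [4e-3])[0]
        assert a == pytest.approx(b)

    def test_undefined_when_theta_zero(self):
        assert np.isnan(pw.r_over_mu([1e-3], [0.0])[0])


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pw.correlate(x, x)[0] == pytest.approx(1.0)
        assert pw.correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_rank_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 0.5, 6.0])
        # brute-force: Pearson correlation of the rank vectors
        rx = np.argsort(np.argsort(x))
        ry = np.argsort(np.argsort(y))
        expected = np.corrcoef(rx, ry)[0, 1]
        assert pw.correlate(x, y)[0] == pytest.approx(expected)

    def test_nan_pairwise_deletion(self):
        x = np.array([1, 2, 3, 4, np.nan])
        y = np.array([1, 2, 3, np.nan, 5])
        r, p = pw.correlate(x, y)
        assert r == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            pw.correlate([1, 2], [3, 4])

    def test_correlogram_mask(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "a": np.arange(30.0),
                "b": np.arange(30.0) + rng.normal(0, 0.1, 30),
                "c": rng.normal(0, 1, 30),
            }
        )
        rho, pval, mask = pw.correlogram(df)
        assert rho.loc["a", "b"] > 0.95
        assert not mask.loc["a", "b"]
        assert mask.loc["a", "c"] or abs(rho.loc["a", "c"]) < 0.4


class TestStratifyLines:
    @pytest.mark.parametrize(
        "length,expect",
        [(900, "short"), (999, "short"), (1000, "neither"), (1250, "neither"),
         (1500, "neither"), (1501, "long"), (1600, "long")],
    )
    def test_boundaries(self, length, expect):
        # clade maximum 5000: short < 1000, long > 1500
        calls = mk_calls(
            [{"pos": 100, "length": length}, {"pos": 9000, "length": 5000}],
            [[1, 0], [0, 1]],
        )
        short, long = pw.stratify_lines(calls)
        got = (
            "short" if short.meta["length"].iloc[0:1].eq(length).any()
            else "long" if (long.meta["length"] == length).any()
            else "neither"
        )
        assert got == expect

    def test_explicit_maxima(self):
        calls = mk_calls([{"pos": 100, "length": 900}], [[1, 0]])
        short, long = pw.stratify_lines(calls, clade_maxima={"L1": 5000})
        assert short.n_loci == 1 and long.n_loci == 0


class TestSharing:
    def samples(self):
        return ["a1", "a2", "b1", "og1", "og2"]

    def popmap(self):
        return pw.PopulationMap(
            {"a1": "A", "a2": "A", "b1": "B",
             "og1": "outgroup_allisoni", "og2": "outgroup_porcatus"}
        )

    def test_private(self):
        calls = mk_calls([{"pos": 100}], [[1, 0, 0, 0, 0]], self.samples())
        out = pw.sharing_counts(calls, self.popmap())
        assert out.loc["a1", "private"] == 1
        assert out.loc["a1", "n_het"] == 1

    def test_outgroup_precedence(self):
        # het in a1, present in outgroup AND in another cluster: outgroup wins
        calls = mk_calls([{"pos": 100}], [[1, 0, 2, 1, 0]], self.samples())
        out = pw.sharing_counts(calls, self.popmap())
        assert out.loc["a1", "shared_outgroup"] == 1
        assert out.loc["a1", "shared_other_cluster"] == 0

    def test_within_cluster(self):
        calls = mk_calls([{"pos": 100}], [[1, 2, 0, 0, 0]], self.samples())
        out = pw.sharing_counts(calls, self.popmap())
        assert out.loc["a1", "shared_within_cluster"] == 1

    def test_other_cluster(self):
        calls = mk_calls([{"pos": 100}], [[1, 0, 1, 0, 0]], self.samples())
        out = pw.sharing_counts(calls, self.popmap())
        assert out.loc["a1", "shared_other_cluster"] == 1
        assert out.loc["b1", "shared_other_cluster"] == 1

    def test_planted_category_counts(self):
        rng = np.random.default_rng(4)
        # build 40 loci with known categories for individual a1
        rows, G, expected = [], [], {c: 0 for c in pw.SHARING_CATEGORIES}
        for i in range(40):
            cat = pw.SHARING_CATEGORIES[i % 4]
            g = [1, 0, 0, 0, 0]
            if cat == "shared_outgroup":
                g[3] = 1
                if rng.random() < 0.5:
                    g[2] = 1  # also in another cluster; precedence keeps outgroup
            elif cat == "shared_other_cluster":
                g[2] = 2
            elif cat == "shared_within_cluster":
                g[1] = 1
            expected[cat] += 1
            rows.append({"pos": 100 + 10 * i})
            G.append(g)
        out = pw.sharing_counts(mk_calls(rows, G, self.samples()), self.popmap())
        for cat, n in expected.items():
            assert out.loc["a1", cat] == n


class TestCompareFrequencies:
    def test_identical_paired(self):
        a = np.array([0.1, 0.2, 0.3])
        res = pw.compare_frequencies(a, a, paired=True)
        assert res.pvalue == 1.0
        assert res.degenerate

    def test_disjoint_supports_minimal_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        res = pw.compare_frequencies(a, b)
        # minimal attainable two-sided p for n1=n2=4: 2 / C(8,4)
        assert res.pvalue == pytest.approx(2 / 70)

    def test_matches_exact_enumeration(self):
        a = np.array([0.3, 0.9, 0.55])
        b = np.array([0.1, 0.2, 0.4, 0.6])
        res = pw.compare_frequencies(a, b)
        # enumerate all C(7,3) rank assignments for the exact two-sided p of
        # the Mann-Whitney U statistic
        pooled = np.concatenate([a, b])
        ranks = pooled.argsort().argsort() + 1
        u_obs = ranks[:3].sum() - 3 * 4 / 2
        us = []
        for comb in itertools.combinations(range(7), 3):
            r = np.sort(ranks)[list(comb)].sum()  # ranks are 1..7 unique
            us.append(r - 6)
        us = np.array(us)
        p_exact = min(1.0, 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs)))
        assert res.pvalue == pytest.approx(p_exact)

    def test_paired_direction(self):
        a = np.array([0.5, 0.6, 0.7, 0.8, 0.9, 0.85])
        b = a - 0.2
        res = pw.compare_frequencies(a, b, paired=True)
        assert res.pvalue < 0.05


class TestFilterCandidates:
    def records(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.sort(rng.choice(10**6, n, replace=False)) + 1,
                "XtX": rng.gamma(4, 1, n),
                "eBPis": rng.gamma(3, 1, n),
                "freq_north": rng.uniform(0, 0.4, n),
                "freq_south": rng.uniform(0, 0.4, n),
            }
        )

    def tracks(self):
        return {
            "lsd": windows_df(("chr1", 0, 10**6)),
            "baypass": windows_df(("chr1", 0, 10**6)),
            "diploshic": windows_df(("chr1", 500_000, 10**6)),
        }

    def test_impossible_delta_empty(self):
        out = pw.filter_candidates(self.records(), self.tracks(), delta=1.01)
        assert len(out) == 0

    def test_triple_overlap_counting(self):
        recs = self.records()
        recs.loc[0, ["XtX", "eBPis"]] = [99.0, 99.0]
        recs.loc[0, ["freq_north", "freq_south"]] = [0.95, 0.05]
        recs.loc[0, "pos"] = 600_001  # inside all three tracks
        out = pw.filter_candidates(recs, self.tracks())
        assert len(out) == 1
        assert out.loc[0, "n_tests_supporting"] == 3
        assert out.loc[0, "in_lsd"] and out.loc[0, "in_diploshic"]

    def test_partial_overlap(self):
        recs = self.records()
        recs.loc[0, ["XtX", "eBPis"]] = [99.0, 99.0]
        recs.loc[0, ["freq_north", "freq_south"]] = [0.95, 0.05]
        recs.loc[0, "pos"] = 100  # outside diploS/HIC track
        out = pw.filter_candidates(recs, self.tracks())
        assert out.loc[0, "n_tests_supporting"] == 2

    def test_both_statistics_required(self):
        recs = self.records()
        recs.loc[0, "XtX"] = 99.0
        recs.loc[0, ["freq_north", "freq_south"]] = [0.95, 0.05]
        out = pw.filter_candidates(recs, self.tracks())
        assert 600_001 not in out["pos"].tolist()
        assert len(out) == 0 or (out["eBPis"] >= np.quantile(recs["eBPis"], 0.99)).all()

    def test_delta_boundary_inclusive(self):
        recs = self.records()
        recs.loc[0, ["XtX", "eBPis"]] = [99.0, 99.0]
        recs.loc[0, ["freq_north", "freq_south"]] = [0.5, 0.0]
        out = pw.filter_candidates(recs, self.tracks(), delta=0.5)
        assert (out["pos"] == recs.loc[0, "pos"]).any()

    def test_threshold_ties_included(self):
        recs = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 101) * 100,
                "XtX": np.concatenate([np.full(99, 1.0), [5.0]]),
                "eBPis": np.concatenate([np.full(99, 1.0), [5.0]]),
                "freq_north": np.full(100, 0.9),
                "freq_south": np.full(100, 0.0),
            }
        )
        out = pw.filter_candidates(recs, {"t": windows_df(("chr1", 0, 10**6))})
        # quantile(0.99) lies between 1 and 5; only the extreme locus passes
        assert len(out) == 1
        assert out.loc[0, "XtX"] == 5.0

    def test_empty_track_errors(self):
        with pytest.raises(ValueError, match="empty"):
            pw.filter_candidates(
                self.records(), {"t": windows_df()}, delta=0.5
            )


class TestTruncation:
    def test_full_length_elements(self):
        calls = mk_calls(
            [
                {"pos": 100, "consensus_start": 0.0, "consensus_end": 5000.0},
                {"pos": 9000, "consensus_start": 0.0, "consensus_end": 5000.0},
            ],
            [[1, 0], [0, 1]],
        )
        out = pw.truncation_summary(calls)["L1"]
        assert out["start_hist"][0] == 2
        assert out["end_hist"][-1] == 2
        assert out["mean_start_frac"] == 0.0
        assert out["mean_end_frac"] == 1.0

    def test_five_prime_truncation_shifts_start_only(self):
        calls = mk_calls(
            [
                {"pos": 100, "consensus_start": 4000.0, "consensus_end": 5000.0},
                {"pos": 9000, "consensus_start": 2500.0, "consensus_end": 5000.0},
                {"pos": 20000, "consensus_start": 0.0, "consensus_end": 5000.0},
            ],
            [[1, 0], [0, 1], [1, 1]],
        )
        out = pw.truncation_summary(calls)["L1"]
        assert out["mean_start_frac"] == pytest.approx((0.8 + 0.5 + 0.0) / 3)
        assert out["mean_end_frac"] == 1.0

    def test_missing_consensus_coords_skipped(self):
        calls = mk_calls([{"pos": 100}], [[1, 0]])
        assert pw.truncation_summary(calls) == {}
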