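"""Heterozygosity, rarefaction, inbreeding, coancestry and differentiation."""

from __future__ import annotations

import numpy as np
import pytest

from popkit.diversity import (
    AlleleFrequencyTable,
    allele_frequencies,
    allelic_richness,
    coancestry,
    inbreeding_coefficient,
    nei_minimum_distance,
    observed_expected_het,
    pairwise_fst,
    pairwise_summary,
)

from conftest import make_gm, make_popmap
from oracles import coancestry_matching


def freq_table(freq_rows, copies=None, pops=None):
    """AlleleFrequencyTable from explicit frequencies (integer-compatible)."""
    freq = np.asarray(freq_rows, dtype=float)
    P, V = freq.shape
    if copies is None:
        copies = np.full((P, V), 10, dtype=np.int64)
    alt = np.round(freq * copies).astype(np.int64)
    return AlleleFrequencyTable(
        pops or [f"p{i}" for i in range(P)], alt, np.asarray(copies),
        np.asarray(copies).max(axis=1) // 2,
    )


class TestAlleleFrequencies:
    def test_closed_form(self):
        gm = make_gm([[0], [1], [2]])
        pm = make_popmap({"p": ["s0", "s1", "s2"]})
        t = allele_frequencies(gm, pm)
        assert t.freq[0, 0] == 0.5

    def test_all_missing_flagged(self):
        gm = make_gm([[-1], [-1]])
        pm = make_popmap({"p": ["s0", "s1"]})
        t = allele_frequencies(gm, pm)
        assert not t.covered[0, 0]
        assert np.isnan(t.freq[0, 0])

    def test_empty_population_errors(self):
        gm = make_gm([[0], [1]])
        pm = make_popmap({"p": ["s0", "s1"], "q": []})
        with pytest.raises(ValueError, match="'q'"):
            allele_frequencies(gm, pm)

    def test_matches_truth_within_binomial_error(self, small_sim):
        _, gm, pm, truth = small_sim
        t = allele_frequencies(gm, pm, pm.analysis_populations)
        for k, pop in enumerate(pm.analysis_populations):
            p = truth.subpop_freq[pop]
            n = t.called_copies[k]
            err = np.abs(t.freq[k] - p)
            bound = 4 * np.sqrt(p * (1 - p) / np.maximum(n, 1)) + 1e-9
            assert (err <= bound).mean() > 0.99


class TestHeterozygosity:
    def test_two_het_calls_closed_form(self):
        """{0/1, 0/1}: H_O = 1; H_E = 0.5 * 4/3 = 0.6667."""
        gm = make_gm([[1], [1]])
        pm = make_popmap({"p": ["s0", "s1"]})
        het = observed_expected_het(gm, pm)
        assert het.loc["p", "H_O"] == 1.0
        assert het.loc["p", "H_E"] == pytest.approx(2 / 3, abs=1e-12)

    def test_fixed_locus_contributes_zero(self):
        gm = make_gm([[2, 1], [2, 1]])
        pm = make_popmap({"p": ["s0", "s1"]})
        het = observed_expected_het(gm, pm)
        assert het.loc["p", "H_O"] == 0.5     # mean over the two loci
        assert het.loc["p", "H_E"] == pytest.approx((0 + 2 / 3) / 2)

    def test_single_diploid_population_errors(self):
        gm = make_gm([[1], [1]])
        pm = make_popmap({"p": ["s0"], "q": ["s1"]})
        with pytest.raises(ValueError, match="single diploid"):
            observed_expected_het(gm, pm)


class TestAllelicRichness:
    def test_hypergeometric_example(self):
        """Counts 9 ref : 1 alt at g = 2 give A_R = 0.2 + 1.0 = 1.2."""
        t = freq_table([[0.1]], copies=np.array([[10]]))
        ar = allelic_richness(t, rarefaction_g=2)
        assert ar["A_R"].iloc[0] == pytest.approx(1.2, abs=1e-12)

    def test_fixed_locus_is_one(self):
        t = freq_table([[0.0]], copies=np.array([[10]]))
        for g in (2, 5, 10):
            assert allelic_richness(t, g)["A_R"].iloc[0] == pytest.approx(1.0)

    def test_full_depth_equals_observed_count(self):
        t = freq_table([[0.3, 0.0]], copies=np.array([[10, 10]]))
        ar = allelic_richness(t, rarefaction_g=10)
        assert ar["A_R"].iloc[0] == pytest.approx((2 + 1) / 2)

    def test_g_below_two_errors(self):
        t = freq_table([[0.3]])
        with pytest.raises(ValueError):
            allelic_richness(t, rarefaction_g=1)

    def test_shallow_loci_skipped_and_counted(self):
        t = freq_table([[0.5, 0.5]], copies=np.array([[10, 4]]))
        ar = allelic_richness(t, rarefaction_g=6)
        assert ar["loci_skipped"].iloc[0] == 1
        assert ar["loci_used"].iloc[0] == 1


class TestInbreeding:
    def test_all_het_individuals_negative_F(self):
        """Individuals heterozygous everywhere at p = 0.5 loci show excess
        heterozygosity, so F < 0."""
        geno = np.ones((4, 6), dtype=np.int8)
        pm = make_popmap({"p": [f"s{i}" for i in range(4)]})
        f_df = inbreeding_coefficient(make_gm(geno), pm)
        assert f_df.loc["p", "F"] < 0

    def test_fully_homozygous_individual_F_one(self):
        geno = np.array([[0, 2, 0, 2], [1, 1, 1, 1], [1, 1, 1, 1], [2, 0, 2, 0]],
                        dtype=np.int8)
        gm = make_gm(geno)
        pm = make_popmap({"p": [f"s{i}" for i in range(4)]})
        # per-individual F of the homozygous-everywhere individual equals 1;
        # check via a population made of homozygotes only
        pm2 = make_popmap({"hom": ["s0", "s3"], "het": ["s1", "s2"]})
        f_df = inbreeding_coefficient(gm, pm2)
        assert f_df.loc["hom", "F"] == pytest.approx(1.0)

    def test_recovers_simulated_fis(self):
        from popkit.simdata import SimulationConfig, simulate_metapopulation

        cfg = SimulationConfig(
            n_subpops=3, samples_per_subpop=(6, 6, 6), n_outgroup=0,
            n_variants=20_000, genome=(("1", 5_000_000),),
            inbreeding_Fis=0.35, missing_rate=0.0, deleterious_fraction=0.0,
            seed=9,
        )
        gm, pm, _ = simulate_metapopulation(cfg)
        f_df = inbreeding_coefficient(gm, pm)
        assert f_df["F"].mean() == pytest.approx(0.35, abs=0.05)


class TestCoancestry:
    def test_half_frequency_everywhere(self):
        t = freq_table([[0.5, 0.5], [0.5, 0.5]])
        f = coancestry(t)
        assert np.allclose(f.f, 0.5)

    def test_identical_monomorphic_pops(self):
        t = freq_table([[1.0, 0.0], [1.0, 0.0]])
        f = coancestry(t)
        assert np.allclose(f.f, 1.0)

    def test_matches_allele_matching_enumeration(self):
        rng = np.random.default_rng(4)
        copies = np.full((3, 20), 8)
        alt = rng.integers(0, 9, size=(3, 20))
        t = AlleleFrequencyTable(["a", "b", "c"], alt, copies, np.array([4, 4, 4]))
        f = coancestry(t)
        for i in range(3):
            for j in range(3):
                expected = np.mean([
                    coancestry_matching(
                        ["A"] * int(alt[i, v]) + ["a"] * int(8 - alt[i, v]),
                        ["A"] * int(alt[j, v]) + ["a"] * int(8 - alt[j, v]),
                    )
                    for v in range(20)
                ])
                assert f.f[i, j] == pytest.approx(expected, abs=1e-12)

    def test_no_shared_loci_errors(self):
        t = AlleleFrequencyTable(
            ["a", "b"],
            np.array([[1, 0], [0, 1]]),
            np.array([[4, 0], [0, 4]]),
            np.array([2, 2]),
        )
        with pytest.raises(ValueError, match="no shared loci"):
            coancestry(t)


class TestDifferentiation:
    def test_identical_populations_zero(self):
        t = freq_table([[0.3, 0.6], [0.3, 0.6]])
        f = coancestry(t)
        assert nei_minimum_distance(f).iloc[0, 1] == pytest.approx(0.0)
        fst, _ = pairwise_fst(f)
        assert fst.iloc[0, 1] == pytest.approx(0.0)

    def test_fixed_difference_maximal(self):
        """Single locus with p_i = 1, p_j = 0: D_nei = 1 and F_ST = 1."""
        t = freq_table([[1.0], [0.0]])
        f = coancestry(t)
        assert nei_minimum_distance(f).iloc[0, 1] == pytest.approx(1.0)
        fst, _ = pairwise_fst(f)
        assert fst.iloc[0, 1] == pytest.approx(1.0)

    def test_symmetry_under_population_swap(self):
        rng = np.random.default_rng(5)
        t = freq_table(rng.uniform(0, 1, size=(4, 30)))
        f = coancestry(t)
        D = nei_minimum_distance(f).to_numpy()
        F, _ = pairwise_fst(f)
        assert np.allclose(D, D.T)
        assert np.allclose(F.to_numpy(), F.to_numpy().T)
        assert (D >= 0).all()

    def test_fst_dnei_identity(self):
        """F_ST(i,j) = D_nei(i,j) / (2 H_T(i,j)) to 1e-12."""
        rng = np.random.default_rng(6)
        t = freq_table(rng.uniform(0.05, 0.95, size=(5, 100)))
        f = coancestry(t)
        D = nei_minimum_distance(f).to_numpy()
        F, _ = pairwise_fst(f)
        diag = np.diag(f.f)
        h_t = 1.0 - (diag[:, None] + diag[None, :] + 2 * f.f) / 4.0
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                assert F.iloc[i, j] == pytest.approx(D[i, j] / (2 * h_t[i, j]), abs=1e-12)

    def test_degenerate_pair_defined_zero(self):
        t = freq_table([[1.0], [1.0]])
        fst, _ = pairwise_fst(coancestry(t))
        assert fst.iloc[0, 1] == 0.0

    def test_star_topology_rank_consistency(self):
        """A hub population planted midway between distinct satellites has
        the smallest average D_nei and average F_ST."""
        hub = np.full(60, 0.5)
        rng = np.random.default_rng(7)
        sats = [np.clip(hub + rng.choice([-0.35, 0.35], size=60), 0.01, 0.99)
                for _ in range(4)]
        t = freq_table([hub] + sats, pops=["hub", "s1", "s2", "s3", "s4"])
        summary = pairwise_summary(coancestry(t))
        assert summary["avg_Dnei"].idxmin() == "hub"
        assert summary["avg_FST"].idxmin() == "hub"
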