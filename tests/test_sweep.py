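"""Window statistics, Z-transformation and sweep calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popkit.sweep import (
    SweepCallSet,
    annotate_windows,
    call_sweeps,
    hudson_fst,
    read_bed4,
    read_gff3_genes,
    window_fst,
    window_pi,
    window_scan,
    zscore,
)

from conftest import make_gm, make_popmap
from oracles import interval_overlaps_allpairs, pi_pairwise_counting


class TestWindowPi:
    def test_single_snp_closed_form(self):
        """One SNP at p = 0.5 with 10 gene copies in a 10 kb window:
        theta-pi = 0.5 * (10/9) / 10000."""
        gm = make_gm(np.array([[1], [1], [1], [1], [1]], dtype=np.int8),
                     positions=[500])
        out = window_pi(gm, gm.sample_ids, 10_000)
        assert out["pi"].iloc[0] == pytest.approx(0.5 * (10 / 9) / 10_000)
        assert out["n_snps"].iloc[0] == 1

    def test_empty_window_zero(self):
        gm = make_gm(np.array([[1], [1]], dtype=np.int8), positions=[15_000])
        out = window_pi(gm, gm.sample_ids, 10_000)
        assert len(out) == 2
        assert out["pi"].iloc[0] == 0.0

    def test_nonpositive_window_errors(self):
        gm = make_gm([[1], [1]])
        with pytest.raises(ValueError):
            window_pi(gm, gm.sample_ids, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, v = 8, 40
        geno = rng.integers(0, 3, size=(n, v)).astype(np.int8)
        geno[rng.random((n, v)) < 0.1] = -1
        positions = np.sort(rng.choice(np.arange(1, 30_000), v, replace=False))
        gm = make_gm(geno, positions=positions)
        out = window_pi(gm, gm.sample_ids, 10_000)
        expected = np.zeros(len(out))
        for j, pos in enumerate(positions):
            w = (pos - 1) // 10_000
            val = pi_pairwise_counting(geno[:, j])
            if np.isfinite(val):
                expected[w] += val
        np.testing.assert_allclose(out["pi"].to_numpy(), expected / 10_000, atol=1e-12)

    def test_invariant_to_sample_order_and_label_swap(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(6, 30)).astype(np.int8)
        gm = make_gm(geno)
        base = window_pi(gm, gm.sample_ids, 1_000)["pi"]
        shuffled = window_pi(gm, gm.sample_ids[::-1], 1_000)["pi"]
        swapped = window_pi(make_gm(2 - geno), gm.sample_ids, 1_000)["pi"]
        np.testing.assert_allclose(base, shuffled, atol=1e-15)
        np.testing.assert_allclose(base, swapped, atol=1e-15)


class TestWindowFst:
    def test_fixed_difference_is_one(self):
        geno = np.array([[2, 2, 2], [2, 2, 2], [0, 0, 0], [0, 0, 0]], dtype=np.int8)
        gm = make_gm(geno)
        out = window_fst(gm, ["s0", "s1"], ["s2", "s3"], 10_000)
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_panmictic_null_near_zero(self):
        rng = np.random.default_rng(8)
        geno = rng.binomial(2, rng.uniform(0.2, 0.8, size=2_000),
                            size=(20, 2_000)).astype(np.int8)
        gm = make_gm(geno, positions=np.arange(1, 2_001) * 5)
        out = window_fst(gm, gm.sample_ids[:10], gm.sample_ids[10:], 10_000)
        assert abs(out["fst"].mean()) < 0.02

    def test_recovers_two_deme_drift(self):
        from popkit.simdata import SimulationConfig, simulate_metapopulation

        vals = []
        for seed in range(5):
            cfg = SimulationConfig(
                n_subpops=2, samples_per_subpop=(10, 10), n_outgroup=0,
                n_variants=10_000, genome=(("1", 5_000_000),), drift_F=0.2,
                inbreeding_Fis=0.0, missing_rate=0.0, deleterious_fraction=0.0,
                seed=seed,
            )
            gm, pm, _ = simulate_metapopulation(cfg)
            vals.append(hudson_fst(gm, pm.samples_of("pop01"), pm.samples_of("pop02")))
        assert np.mean(vals) == pytest.approx(0.2, abs=0.03)


class TestZscore:
    def test_basic_example(self):
        np.testing.assert_allclose(zscore(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="zero standard deviation"):
            zscore(np.array([2.0, 2.0, 2.0]), "pi ratio")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=30).filter(
            lambda xs: max(xs) - min(xs) > 1e-3
        ),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_shift_scale_invariance(self, xs, a, b):
        x = np.array(xs)
        np.testing.assert_allclose(zscore(a * x + b), zscore(x), atol=1e-6)

    def test_nan_propagates_as_masked(self):
        z = zscore(np.array([1.0, np.nan, 3.0, 5.0]))
        assert np.isnan(z[1])
        assert np.isfinite(z[[0, 2, 3]]).all()


def scan_table(z_fst, z_ratio, masked=None):
    n = len(z_fst)
    return pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "start": np.arange(n) * 10_000,
            "end": (np.arange(n) + 1) * 10_000,
            "n_snps": 20,
            "pi_study": 1e-3,
            "pi_outgroup": 1e-3,
            "pi_ratio": z_ratio,
            "fst": z_fst,
            "masked": masked if masked is not None else np.zeros(n, bool),
            "z_fst": z_fst,
            "z_ratio": z_ratio,
        }
    )


class TestCallSweeps:
    def test_engineered_maximum_called(self):
        rng = np.random.default_rng(9)
        z1 = rng.normal(size=1_000)
        z2 = rng.normal(size=1_000)
        z1[500] = z1.max() + 5
        z2[500] = z2.max() + 5
        calls = call_sweeps(scan_table(z1, z2), 0.999)
        assert len(calls.candidates) == 1
        assert calls.candidates["start"].iloc[0] == 500 * 10_000

    def test_candidates_in_both_top_sets(self):
        rng = np.random.default_rng(10)
        t = scan_table(rng.normal(size=2_000), rng.normal(size=2_000))
        calls = call_sweeps(t, 0.99)
        assert calls.candidates["in_top_fst"].all()
        assert calls.candidates["in_top_ratio"].all()

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(11)
        t = scan_table(rng.normal(size=2_000), rng.normal(size=2_000))
        strict = call_sweeps(t, 0.99)
        loose = call_sweeps(t, 0.95)
        s99 = set(strict.candidates["start"])
        s95 = set(loose.candidates["start"])
        assert s99 <= s95

    def test_independent_null_rate(self):
        """Independent standard-normal Z pairs: the top-1% intersection
        calls about 0.01^2 of windows on average."""
        rng = np.random.default_rng(12)
        n, reps = 20_000, 40
        fracs = []
        for _ in range(reps):
            t = scan_table(rng.normal(size=n), rng.normal(size=n))
            fracs.append(len(call_sweeps(t, 0.99).candidates) / n)
        mean = np.mean(fracs)
        se = np.std(fracs, ddof=1) / np.sqrt(reps)
        assert abs(mean - 1e-4) <= max(4 * se, 5e-5)

    def test_merged_intervals_nonoverlapping(self):
        rng = np.random.default_rng(13)
        t = scan_table(rng.normal(size=500), rng.normal(size=500))
        calls = call_sweeps(t, 0.95)
        m = calls.merged.sort_values(["chrom", "start"])
        for c, sub in m.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()


class TestWindowScan:
    def test_group_swap_symmetry(self, small_sim):
        """Swapping study and outgroup leaves Z_FST unchanged and inverts
        the diversity ratio (within masking)."""
        _, gm, pm, _ = small_sim
        from popkit.variant_io import filter_sites, PopulationMap

        fgm, _ = filter_sites(gm)
        t1 = window_scan(fgm, pm, 50_000, min_snps=5)
        # swapped map: make every study pop the outgroup's role by pooling
        swapped = PopulationMap(
            sample_to_pop={
                s: ("study" if p == "wild" else "wild")
                for s, p in pm.sample_to_pop.items()
            },
            populations=["study", "wild"],
            outgroup="wild",
        )
        t2 = window_scan(fgm, swapped, 50_000, min_snps=5)
        both = ~(t1["masked"] | t2["masked"]).to_numpy()
        np.testing.assert_allclose(
            t1.loc[both, "fst"], t2.loc[both, "fst"], atol=1e-12
        )
        np.testing.assert_allclose(
            t1.loc[both, "pi_ratio"].to_numpy(),
            1.0 / t2.loc[both, "pi_ratio"].to_numpy(),
            rtol=1e-10,
        )

    def test_z_columns_standardised(self, small_sim):
        _, gm, pm, _ = small_sim
        from popkit.variant_io import filter_sites

        fgm, _ = filter_sites(gm)
        t = window_scan(fgm, pm, 50_000, min_snps=5)
        ok = ~t["masked"]
        for col in ("z_fst", "z_ratio"):
            z = t.loc[ok, col]
            assert z.mean() == pytest.approx(0.0, abs=1e-9)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_windows_tile_without_overlap(self, small_sim):
        _, gm, pm, _ = small_sim
        t = window_scan(gm, pm, 10_000)
        for c, sub in t.groupby("chrom"):
            assert (sub["end"] - sub["start"] == 10_000).all()
            assert (np.diff(sub["start"]) == 10_000).all()


class TestAnnotateWindows:
    def cand(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        return SweepCallSet(candidates=df, merged=df, quantile=0.99)

    def test_overlap_and_boundary(self):
        genes = pd.DataFrame(
            [("1", 5_000, 15_000, "gA"), ("1", 20_000, 30_000, "gB")],
            columns=["chrom", "start", "end", "name"],
        )
        calls = self.cand([("1", 10_000, 20_000)])
        out = annotate_windows(calls, genes)
        assert out["gene"].tolist() == ["gA"]  # gB abuts half-open boundary

    def test_chromosome_mismatch_errors(self):
        genes = pd.DataFrame([("chr9", 0, 10, "g")],
                             columns=["chrom", "start", "end", "name"])
        calls = self.cand([("1", 0, 10_000)])
        with pytest.raises(ValueError, match="no chromosome names shared"):
            annotate_windows(calls, genes)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        wins = [("1", int(s) * 1_000, (int(s) + 1) * 1_000)
                for s in rng.choice(50, 10, replace=False)]
        genes = [("1", int(a), int(a) + int(rng.integers(100, 5_000)), f"g{i}")
                 for i, a in enumerate(rng.integers(0, 50_000, size=30))]
        calls = self.cand(wins)
        gdf = pd.DataFrame(genes, columns=["chrom", "start", "end", "name"])
        got = set(map(tuple, annotate_windows(calls, gdf).to_numpy()))
        expected = set(interval_overlaps_allpairs(wins, genes))
        assert got == expected

    def test_gff3_gene_parsing(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=geneX;Name=X\n"
            "1\tsrc\texon\t1001\t1500\t.\t+\t.\tParent=geneX\n"
        )
        genes = read_gff3_genes(p)
        assert len(genes) == 1
        assert genes["start"].iloc[0] == 1000  # converted to 0-based
        assert genes["name"].iloc[0] == "geneX"
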