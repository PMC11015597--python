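"""Profile matrices: flat-field, strand symmetry, scaling, clustering."""

import numpy as np
import pandas as pd
import pytest

from chromstate import (
    GeneModel,
    GenomicInterval,
    SignalTrack,
    SimulationConfig,
    cluster_profiles,
    metagene_profile,
    profile_contrast,
    region_scaled_profile,
    simulate_genome,
    simulate_plad_signal,
    tss_matrix,
)
from chromstate.profiles import ProfileMatrix

SIZES = {"chr1": 100_000}


def _gene(start, end, strand, gid):
    return GeneModel(gid, GenomicInterval("chr1", start, end, strand), strand)


def _step_track(edge, left, right, size=100_000):
    return SignalTrack(
        {"chr1": (np.array([0, edge]), np.array([edge, size]), np.array([left, right]))}
    )


class TestTssMatrix:
    def test_constant_field(self):
        t = SignalTrack.constant(SIZES, 3.0)
        m = tss_matrix(t, [_gene(50_000, 52_000, "+", "g")], chrom_sizes=SIZES)
        assert np.allclose(m.matrix.values, 3.0, atol=1e-9)

    def test_step_orientation_plus(self):
        t = _step_track(50_000, 0.0, 7.0)
        m = tss_matrix(t, [_gene(50_000, 52_000, "+", "g")])
        vals = m.matrix.iloc[0].to_numpy()
        assert np.allclose(vals[:20], 0.0) and np.allclose(vals[20:], 7.0)

    def test_step_mirrored_for_minus_strand(self):
        """A physically mirrored setup gives the same oriented profile."""
        plus = tss_matrix(_step_track(50_000, 0.0, 7.0),
                          [_gene(50_000, 52_000, "+", "g")]).matrix.iloc[0].to_numpy()
        minus = tss_matrix(_step_track(50_000, 7.0, 0.0),
                           [_gene(48_000, 50_000, "-", "g")]).matrix.iloc[0].to_numpy()
        assert np.allclose(plus, minus)

    def test_strand_flip_mirrors_row(self):
        t = _step_track(50_000, 1.0, 4.0)
        g_plus = _gene(49_000, 51_000, "+", "g")
        g_minus = _gene(49_000, 51_001, "-", "g")  # tss at 51_000
        row_p = tss_matrix(t, [g_plus]).matrix.iloc[0].to_numpy()
        # mirror of the minus row about its own TSS equals the physical bins
        row_m = tss_matrix(t, [g_minus]).matrix.iloc[0].to_numpy()
        edges = 51_001 - 1_000 + np.arange(41) * 50.0
        physical = np.array([t.mean("chr1", a, b) for a, b in zip(edges[:-1], edges[1:])])
        assert np.allclose(row_m, physical[::-1])

    def test_chromosome_end_clipping(self):
        t = SignalTrack.constant(SIZES, 2.0)
        m = tss_matrix(t, [_gene(100, 2_000, "+", "g")], chrom_sizes=SIZES)
        vals = m.matrix.iloc[0].to_numpy()
        assert np.allclose(vals[vals > 0], 2.0)  # covered bins keep the level

    def test_flank_not_divisible_errors(self):
        t = SignalTrack.constant(SIZES, 1.0)
        with pytest.raises(ValueError, match="divisible"):
            tss_matrix(t, [_gene(50_000, 52_000, "+", "g")], flank_bp=1000, bin_bp=33)


class TestMetagene:
    def test_flat_profile_on_uniform_track(self):
        t = SignalTrack.constant(SIZES, 4.5)
        genes = [_gene(10_000, 11_000, "+", "a"), _gene(40_000, 50_000, "-", "b")]
        m = metagene_profile(t, genes, chrom_sizes=SIZES)
        assert np.allclose(m.matrix.values, 4.5, atol=1e-9)

    def test_percent_scaling_is_length_invariant(self):
        """Body-constant signal yields identical body columns for 1 kb and
        10 kb genes."""
        genes = [_gene(10_000, 11_000, "+", "short"), _gene(40_000, 50_000, "+", "long")]
        data = {"chr1": (np.array([10_000, 40_000]), np.array([11_000, 50_000]),
                         np.array([6.0, 6.0]))}
        t = SignalTrack(data)
        m = metagene_profile(t, genes)
        body_cols = [c for c in m.columns if c.startswith("b")]
        flank_cols = [c for c in m.columns if c.startswith(("u", "d"))]
        assert np.allclose(m.matrix.loc["short", body_cols],
                           m.matrix.loc["long", body_cols])
        assert np.allclose(m.matrix[body_cols].values, 6.0)
        assert np.allclose(m.matrix[flank_cols].values, 0.0)

    def test_matches_per_base_resampling_oracle(self, rng):
        """Column means equal direct per-base resampling on a random track."""
        starts = np.arange(0, 100_000, 100)
        vals = rng.random(len(starts)) * 5
        t = SignalTrack({"chr1": (starts, starts + 100, vals)})
        base = np.repeat(vals, 100)
        genes = [_gene(20_000, 23_000, "+", "g1"), _gene(60_000, 64_000, "+", "g2")]
        m = metagene_profile(t, genes, flank_bp=1000, body_bins=50, flank_bin_bp=50)
        for g in genes:
            s, e = g.body.start, g.body.end
            L = e - s
            expected = []
            for i in range(20):  # upstream flank
                a = s - 1000 + i * 50
                expected.append(base[a : a + 50].mean())
            bounds = s + np.arange(51) * (L / 50)
            for a, b in zip(bounds[:-1], bounds[1:]):
                ai, bi = int(np.floor(a)), int(np.ceil(b))
                w = np.ones(bi - ai)
                w[0] -= a - ai
                w[-1] -= bi - b
                expected.append((base[ai:bi] * w).sum() / (b - a))
            for i in range(20):  # downstream flank
                a = e + i * 50
                expected.append(base[a : a + 50].mean())
            assert np.allclose(m.matrix.loc[g.gene_id].to_numpy(), expected, atol=1e-9)

    def test_short_genes_skipped_with_warning(self):
        t = SignalTrack.constant(SIZES, 1.0)
        genes = [_gene(10_000, 10_020, "+", "tiny"), _gene(40_000, 42_000, "+", "ok")]
        with pytest.warns(UserWarning, match="skipped"):
            m = metagene_profile(t, genes, body_bins=50)
        assert list(m.matrix.index) == ["ok"]

    def test_empty_gene_list_errors(self):
        t = SignalTrack.constant(SIZES, 1.0)
        with pytest.raises(ValueError):
            metagene_profile(t, [])


class TestRegionScaled:
    def test_flat_on_uniform_track(self):
        t = SignalTrack.constant(SIZES, 2.0)
        regs = [GenomicInterval("chr1", 30_000, 37_000)]
        m = region_scaled_profile(t, regs, chrom_sizes=SIZES)
        assert np.allclose(m.matrix.values, 2.0, atol=1e-9)

    def test_single_region_hand_resampling(self):
        """One 300-bp region resampled to 60 bins: 5 bp of track per bin."""
        base_vals = np.arange(300, dtype=float)
        t = SignalTrack({"chr1": (np.arange(10_000, 10_300),
                                  np.arange(10_001, 10_301), base_vals)})
        m = region_scaled_profile(t, [GenomicInterval("chr1", 10_000, 10_300)],
                                  target_bp=3_000, flank_bp=2_000, bin_bp=50)
        interior = m.matrix.iloc[0][[c for c in m.columns if c.startswith("r")]]
        expected = base_vals.reshape(60, 5).mean(axis=1)
        assert np.allclose(interior.to_numpy(), expected, atol=1e-9)

    def test_plad_fixture_shape(self):
        """Body mark high inside, border mark peaking at the boundaries."""
        cfg = SimulationConfig(seed=21, n_genes=0, plad_count=15, signal_noise=True)
        _, _, plads = simulate_genome(cfg)
        body, border = simulate_plad_signal(cfg, plads, cfg.chrom_sizes)
        pb = region_scaled_profile(body, plads).mean_profile()
        interior_cols = [c for c in pb.index if c.startswith("r")]
        flank_cols = [c for c in pb.index if c.startswith(("u", "d"))]
        assert pb[interior_cols].mean() > 2 * pb[flank_cols].mean()
        pr = region_scaled_profile(border, plads).mean_profile()
        n = len(interior_cols)
        edge = interior_cols[: n // 5] + interior_cols[-n // 5 :]
        center = interior_cols[2 * n // 5 : 3 * n // 5]
        assert pr[edge].mean() > 2 * pr[center].mean()
        assert pr.idxmax() in edge + flank_cols

    def test_short_region_skipped(self):
        t = SignalTrack.constant(SIZES, 1.0)
        regs = [GenomicInterval("chr1", 100, 130), GenomicInterval("chr1", 5_000, 12_000)]
        with pytest.warns(UserWarning, match="skipped"):
            m = region_scaled_profile(t, regs)
        assert m.matrix.shape[0] == 1


class TestClustering:
    def _planted_matrices(self, sep=5.0, n=60, seed=0):
        rng = np.random.default_rng(seed)
        cols = [str(c) for c in range(20)]
        a = rng.normal(0.0, 1.0, (n // 2, 20))
        b = rng.normal(sep, 1.0, (n // 2, 20))
        ids = [f"g{i}" for i in range(n)]
        mat = pd.DataFrame(np.vstack([a, b]), index=ids, columns=cols)
        return ProfileMatrix(mat, "tss"), ids

    def test_planted_partition_recovered(self):
        pm, ids = self._planted_matrices(sep=5.0)
        ca = cluster_profiles([pm], k=2, seed=0)
        first = {ca.labels[i] for i in ids[:30]}
        second = {ca.labels[i] for i in ids[30:]}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_determinism_under_seed(self):
        pm, _ = self._planted_matrices(sep=1.0, n=80, seed=3)
        c1 = cluster_profiles([pm], k=8, seed=7)
        c2 = cluster_profiles([pm], k=8, seed=7)
        assert c1.labels == c2.labels

    def test_labels_ordered_by_descending_size(self):
        pm, _ = self._planted_matrices(sep=4.0, n=90, seed=5)
        ca = cluster_profiles([pm], k=3, seed=1)
        sizes = [ca.sizes()[f"C{i + 1}"] for i in range(3)]
        assert sizes == sorted(sizes, reverse=True)

    def test_identical_rows_warn_empty_clusters(self):
        mat = pd.DataFrame(np.ones((10, 5)), index=[f"g{i}" for i in range(10)],
                           columns=list("abcde"))
        pm = ProfileMatrix(mat, "tss")
        with pytest.warns(UserWarning, match="empty"):
            ca = cluster_profiles([pm], k=3, seed=0)
        assert len({ca.labels[f"g{i}"] for i in range(10)}) == 1

    def test_k_exceeding_rows_errors(self):
        pm, _ = self._planted_matrices(n=6)
        with pytest.raises(ValueError, match="exceeds"):
            cluster_profiles([pm], k=10)

    def test_mismatched_row_sets_error(self):
        pm1, _ = self._planted_matrices(n=10, seed=1)
        pm2, _ = self._planted_matrices(n=12, seed=2)
        with pytest.raises(ValueError, match="row set"):
            cluster_profiles([pm1, pm2], k=2)


class TestContrast:
    def test_identical_profiles(self):
        s = pd.Series([1.0, 2.0], index=["a", "b"])
        out = profile_contrast(s, s)
        assert np.allclose(out["difference"], 0.0)
        assert np.allclose(out["ratio"], 1.0)

    def test_double_ratio(self):
        b = pd.Series([1.0, 2.0], index=["a", "b"])
        out = profile_contrast(2 * b, b)
        assert np.allclose(out["ratio"], 2.0)

    def test_zero_denominator_is_nan(self):
        a = pd.Series([1.0, 1.0], index=["a", "b"])
        b = pd.Series([0.0, 2.0], index=["a", "b"])
        out = profile_contrast(a, b)
        assert np.isnan(out["ratio"].iloc[0]) and out["ratio"].iloc[1] == 0.5

    def test_mismatched_schemes_error(self):
        a = pd.Series([1.0], index=["a"])
        b = pd.Series([1.0], index=["x"])
        with pytest.raises(ValueError, match="mismatch"):
            profile_contrast(a, b)
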