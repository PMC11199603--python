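import numpy as np
import pytest

from genefold.matrix import ObsExpMatrix, compute_obs_exp
from genefold.pmga import (chip_metagene, eligible_pairs, extract_block,
                           orient, peak_pileup, pmga_inter, pmga_intra,
                           rescale_to)
from genefold.synthetic import (SyntheticGene, SyntheticSpec,
                                make_contact_matrix, make_genes, make_track)
from genefold.tracks import CoverageTrack, GeneRecord


def oe_matrix(values, resolution=1_000):
    return ObsExpMatrix(values=np.asarray(values, dtype=float),
                        resolution=resolution)


def gene(start, end, strand="+", gid="g"):
    return GeneRecord(chrom="chrS", start=start, end=end, strand=strand, id=gid)


class TestExtractBlock:
    def test_block_coordinates(self):
        v = np.arange(40 * 40, dtype=float).reshape(40, 40)
        oe = oe_matrix((v + v.T) / 2)
        block = extract_block(oe, gene(10_000, 20_000))
        assert block.shape == (30, 30)
        assert block[0, 0] == oe.values[0, 0]
        assert block[-1, -1] == oe.values[29, 29]

    def test_edge_gene_skipped(self):
        oe = oe_matrix(np.ones((30, 30)))
        assert extract_block(oe, gene(2_000, 12_000)) is None

    def test_center_is_gene_midpoint(self):
        oe = oe_matrix(np.ones((60, 60)))
        g = gene(20_000, 30_000)
        block = extract_block(oe, g)
        mid_bin = (20 + 30) // 2  # gene midpoint bin in matrix coordinates
        assert block.shape[0] // 2 + (20 - 10) == mid_bin


class TestRescale:
    def test_all_ones_preserved(self):
        out = rescale_to(np.ones((120, 120)), 60)
        assert out.shape == (60, 60)
        assert np.allclose(out, 1.0)

    def test_integer_ratio_block_means(self):
        rng = np.random.default_rng(1)
        src = rng.uniform(0, 1, (120, 120))
        out = rescale_to(src, 60)
        oracle = src.reshape(60, 2, 60, 2).mean(axis=(1, 3))
        assert np.allclose(out, oracle)

    def test_non_integer_ratio_uniform_stays_uniform(self):
        out = rescale_to(np.full((90, 90), 3.7), 60)
        assert np.allclose(out, 3.7)

    def test_mean_preservation(self):
        rng = np.random.default_rng(5)
        src = rng.uniform(0, 2, (120, 120))
        assert rescale_to(src, 60).mean() == pytest.approx(src.mean(),
                                                           abs=1e-12)
        src2 = rng.uniform(0, 2, (97, 97))
        assert rescale_to(src2, 60).mean() == pytest.approx(src2.mean(),
                                                            rel=0.01)

    def test_upsampling_refused(self):
        with pytest.raises(ValueError, match="upsample"):
            rescale_to(np.ones((30, 30)), 60)

    def test_masked_pixels_excluded(self):
        src = np.ones((120, 120))
        src[0, 0] = np.nan
        out = rescale_to(src, 60)
        assert out[0, 0] == pytest.approx(1.0)  # remaining 3 pixels average


class TestOrient:
    def test_forward_identity(self):
        b = np.arange(9.0).reshape(3, 3)
        assert np.array_equal(orient(b, "+"), b)

    def test_reverse_marker_moves_to_opposite_corner(self):
        b = np.zeros((60, 60))
        b[0, 0] = 1.0
        flipped = orient(b, "-")
        assert flipped[59, 59] == 1.0
        assert flipped[0, 0] == 0.0

    def test_involution(self):
        rng = np.random.default_rng(0)
        b = rng.uniform(0, 1, (10, 10))
        assert np.array_equal(orient(orient(b, "-"), "-"), b)


class TestPmgaIntra:
    def test_single_gene_equals_own_block(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0.5, 2, (90, 90))
        oe = oe_matrix((a + a.T) / 2)
        g = gene(30_000, 60_000)
        res = pmga_intra(oe, [g])
        block = rescale_to(extract_block(oe, g), 60)
        assert res.n == 1
        assert np.allclose(res.values, block)

    def test_two_genes_elementwise_mean(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0.5, 2, (200, 200))
        oe = oe_matrix((a + a.T) / 2)
        g1, g2 = gene(40_000, 70_000), gene(120_000, 160_000)
        res = pmga_intra(oe, [g1, g2])
        b1 = rescale_to(extract_block(oe, g1), 60)
        b2 = rescale_to(extract_block(oe, g2), 60)
        assert np.allclose(res.values, (b1 + b2) / 2)

    def test_identical_blocks_reproduce_block(self):
        oe = oe_matrix(np.ones((90, 90)) * 2.5)
        res = pmga_intra(oe, [gene(30_000, 60_000)] * 5)
        assert np.allclose(res.values, 2.5)

    def test_empty_cluster_raises(self):
        oe = oe_matrix(np.ones((30, 30)))
        with pytest.raises(ValueError, match="eligible"):
            pmga_intra(oe, [gene(0, 10_000)])  # flank out of bounds

    def test_implanted_loop_enriches_tss_tts_corner(self):
        """Synthetic TSS-TTS loops put the pileup maximum at the corner
        pixels joining the start and end of the gene third."""
        genes_spec = [SyntheticGene(s, s + 60_000, loop_strength=6.0)
                      for s in (99_000, 300_000, 501_000)]
        spec = SyntheticSpec(chrom_length=700_000, resolution=3_000,
                             genes=genes_spec, seed=0)
        oe = compute_obs_exp(make_contact_matrix(spec))
        res = pmga_intra(oe, make_genes(spec))
        # gene body occupies pseudo-bins 20..39; TSS-TTS pixel near (20, 39)
        corner = res.values[19:22, 38:41].max()
        assert corner > 2.0 * np.nanmedian(res.values)


class TestChipMetagene:
    def test_constant_track_flat_profile(self):
        t = CoverageTrack("chrS", [0], [400_000], [2.0])
        res = chip_metagene(t, [gene(100_000, 160_000)])
        assert np.allclose(res.values, 2.0)

    def test_synthetic_tss_peak_lands_at_gene_start_third(self):
        spec = SyntheticSpec(chrom_length=400_000, resolution=2_000,
                             background_level=0.1, tss_peak_height=8.0,
                             tss_peak_width=2_000,
                             genes=[SyntheticGene(150_000, 250_000,
                                                  body_level=1.0)], seed=0)
        track = make_track(spec)
        res = chip_metagene(track, make_genes(spec),
                            chrom_length=spec.chrom_length)
        assert 20 <= int(np.argmax(res.values)) <= 22

    def test_reverse_strand_peak_flipped_to_same_bins(self):
        spec = SyntheticSpec(chrom_length=400_000, resolution=2_000,
                             background_level=0.1, tss_peak_height=8.0,
                             tss_peak_width=2_000,
                             genes=[SyntheticGene(150_000, 250_000, strand="-",
                                                  body_level=1.0)], seed=0)
        track = make_track(spec)
        res = chip_metagene(track, make_genes(spec),
                            chrom_length=spec.chrom_length)
        assert 20 <= int(np.argmax(res.values)) <= 22


class TestPmgaInter:
    def test_flat_map_identical_genes_all_ones(self):
        oe = oe_matrix(np.ones((400, 400)))
        g1 = gene(50_000, 70_000, gid="a")
        g2 = gene(250_000, 270_000, gid="b")
        res = pmga_inter(oe, [g1, g2], min_sep=0, max_sep=10**9)
        assert res.values.shape == (30, 30)
        assert np.allclose(res.values, 1.0)
        assert res.n == 1

    def test_separation_filter_matches_enumeration(self):
        genes = [gene(s, s + 20_000, gid=f"g{i}")
                 for i, s in enumerate(range(50_000, 2_000_000, 90_000))]
        got = eligible_pairs(genes, 128_000, 500_000)
        mids = [(g.start + g.end) / 2 for g in genes]
        oracle = [(i, j) for i in range(len(genes)) for j in range(i + 1, len(genes))
                  if 128_000 <= abs(mids[j] - mids[i]) <= 500_000]
        assert len(got) == len(oracle)

    def test_implanted_cross_enrichment_centered(self):
        """Body-body contact enrichment between two genes shows up in the
        central block of the inter-gene pileup."""
        n = 400
        res = 1_000
        d = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        base = (d + 1.0) ** -1.0
        g1 = gene(50_000, 90_000, gid="a")
        g2 = gene(250_000, 290_000, gid="b")
        b1 = slice(50, 90)
        b2 = slice(250, 290)
        base[b1, b2] *= 4.0
        base[b2, b1] *= 4.0
        from genefold.matrix import ContactMatrix
        oe = compute_obs_exp(ContactMatrix(values=(base + base.T) / 2,
                                           resolution=res))
        out = pmga_inter(oe, [g1, g2], min_sep=0, max_sep=10**9)
        center = out.values[10:20, 10:20]
        border = np.concatenate([out.values[:5, :].ravel(),
                                 out.values[-5:, :].ravel()])
        assert np.nanmean(center) > 2.0 * np.nanmean(border)


class TestStripeRecovery:
    def test_stripe_elevates_tss_row_sign_test(self):
        """Full pipeline: implanted promoter stripes raise the TSS-row mean
        inside the gene third of the pileup versus matched no-stripe
        fixtures (paired over 20 noise seeds, one-sided sign test)."""
        from scipy import stats

        def tss_row_mean(stripe, seed):
            genes_spec = [SyntheticGene(s, s + 60_000, stripe_strength=stripe)
                          for s in (99_000, 501_000, 900_000)]
            spec = SyntheticSpec(chrom_length=1_200_000, resolution=3_000,
                                 noise_level=0.4, seed=seed, genes=genes_spec)
            oe = compute_obs_exp(make_contact_matrix(spec))
            res = pmga_intra(oe, make_genes(spec))
            return np.nanmean(res.values[20, 22:38])

        wins = sum(tss_row_mean(2.5, s) > tss_row_mean(1.0, s)
                   for s in range(20))
        assert stats.binomtest(wins, 20, alternative="greater").pvalue < 0.05


class TestPeakPileup:
    def flat_oe(self, n=600):
        return oe_matrix(np.ones((n, n)), resolution=1_000)

    def test_no_pair_in_range_flagged_empty(self):
        oe = self.flat_oe()
        res = peak_pileup(oe, [(10_000, 12_000), (20_000, 22_000)], window=5)
        assert res.n == 0
        assert np.isnan(res.values).all()

    def test_pair_count_matches_brute_force(self):
        rng = np.random.default_rng(8)
        starts = np.sort(rng.choice(np.arange(50_000, 550_000, 1_000), 30,
                                    replace=False))
        peaks = [(int(s), int(s) + 500) for s in starts]
        oe = self.flat_oe()
        res = peak_pileup(oe, peaks, window=3)
        centers = [(s + e) // 2 for s, e in peaks]
        oracle = sum(1 for i in range(30) for j in range(i + 1, 30)
                     if 160_000 <= abs(centers[j] - centers[i]) <= 320_000)
        assert res.n == oracle

    def test_implanted_loops_put_maximum_at_center(self):
        n = 600
        v = np.ones((n, n))
        peaks = [(100_000, 101_000), (300_000, 301_000), (500_000, 501_000)]
        centers = [(s + e) // 2000 for s, e in peaks]
        for i in range(3):
            for j in range(i + 1, 3):
                sep = abs(centers[j] - centers[i]) * 1_000
                if 160_000 <= sep <= 320_000:
                    v[centers[i], centers[j]] = v[centers[j], centers[i]] = 9.0
        res = peak_pileup(oe_matrix(v, resolution=1_000), peaks, window=4)
        assert res.n == 2  # the two 200 kb pairs are in range, 400 kb is not
        assert np.unravel_index(np.nanargmax(res.values),
                                res.values.shape) == (4, 4)
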