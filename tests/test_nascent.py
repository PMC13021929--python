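"""GRO-seq windows, elongation index, tracks, metagene, TES statistics."""

import numpy as np
import pandas as pd
import pytest

import cuttaggro as ctg
from cuttaggro.intervals import GenomicInterval
from cuttaggro.nascent import StrandedReadSet
from cuttaggro.targets import GeneModel

from _oracles import naive_window_counts


def gene(gid, start, end, strand="+", chrom="c"):
    return GeneModel(gid, GenomicInterval(chrom, start, end, strand))


def read_set(positions, strands, sample_id="s", condition="control", replicate=1, chrom="c"):
    pos = np.asarray(positions, dtype=np.int64)
    return StrandedReadSet.from_arrays(
        sample_id, condition, replicate,
        np.full(pos.size, chrom, dtype=object), pos, np.asarray(strands, dtype=object),
    )


class TestGeneWindows:
    def test_plus_strand_layout(self):
        w = ctg.gene_windows(gene("g", 1000, 5000, "+"))
        assert (w.tss_win.start, w.tss_win.end) == (700, 1030)
        assert (w.body_win.start, w.body_win.end) == (1030, 4970)
        assert (w.tes_win.start, w.tes_win.end) == (4970, 5300)

    def test_minus_strand_mirrors_plus(self):
        w = ctg.gene_windows(gene("g", 1000, 5000, "-"))
        assert (w.tss_win.start, w.tss_win.end) == (4970, 5300)
        assert (w.body_win.start, w.body_win.end) == (1030, 4970)
        assert (w.tes_win.start, w.tes_win.end) == (700, 1030)

    def test_windows_tile_contiguously(self):
        for strand in "+-":
            w = ctg.gene_windows(gene("g", 2000, 9000, strand))
            ivs = sorted(
                [w.tss_win, w.body_win, w.tes_win], key=lambda iv: iv.start
            )
            assert ivs[0].end == ivs[1].start and ivs[1].end == ivs[2].start
            assert ivs[0].start == 2000 - 300 and ivs[2].end == 9000 + 300

    def test_short_gene_rejected(self):
        with pytest.raises(ValueError, match="body"):
            ctg.gene_windows(gene("g", 1000, 1060))


class TestWindowCounts:
    def test_sense_only_counting(self):
        g = gene("g", 1000, 5000, "+")
        w = ctg.gene_windows(g)
        rs = read_set([1010, 1010], ["+", "-"])
        counts = ctg.count_window_reads(rs, [w])
        assert counts.loc["g", "tss"] == 1 and counts.loc["g", "body"] == 0

    def test_random_reads_match_membership_oracle(self, rng):
        genes = []
        pos = 1000
        for i in range(50):
            L = int(rng.integers(200, 3000))
            genes.append(gene(f"g{i:02d}", pos, pos + L, "+" if i % 2 else "-"))
            pos += L + 700
        windows = ctg.windows_for_genes(genes)
        positions = rng.integers(0, pos, 5000)
        strands = np.where(rng.random(5000) < 0.5, "+", "-")
        rs = read_set(positions, strands)
        counts = ctg.count_window_reads(rs, windows)
        for w in windows:
            for col, iv in (("tss", w.tss_win), ("body", w.body_win), ("tes", w.tes_win)):
                assert counts.loc[w.gene_id, col] == naive_window_counts(
                    positions, strands, iv.start, iv.end, w.strand
                )


class TestElongationIndex:
    def _wc(self, tss_cpm, tes_cpm):
        return pd.DataFrame(
            {"tss": [0], "body": [0], "tes": [0],
             "tss_cpm": [tss_cpm], "body_cpm": [0.0], "tes_cpm": [tes_cpm]},
            index=pd.Index(["g"], name="gene_id"),
        )

    def test_balanced_conditions_give_zero_delta(self):
        ei = ctg.elongation_index(self._wc(50, 50), self._wc(80, 80))
        assert ei["delta_ei"].iloc[0] == pytest.approx(0.0)

    def test_tes_halving_limit(self):
        ei = ctg.elongation_index(
            self._wc(100, 100), self._wc(100, 50), pseudocount=1e-9
        )
        assert ei["delta_ei"].iloc[0] == pytest.approx(-1.0, abs=1e-6)


class TestTracks:
    sizes = {"c": 10_000}

    def test_identical_tracks_give_zero_and_doubling_near_one(self, rng):
        pos = rng.integers(0, 10_000, 2000)
        strands = np.where(rng.random(2000) < 0.5, "+", "-")
        a = ctg.coverage_track([read_set(pos, strands)], self.sizes)
        z = ctg.log2fc_track(a, a)
        assert np.allclose(z["c"], 0.0)
        doubled = ctg.coverage_track(
            [read_set(np.concatenate([pos, pos]), np.concatenate([strands, strands]))],
            self.sizes,
        )
        # CPM normalization cancels a pure depth doubling
        assert np.allclose(doubled["c"], a["c"])

    def test_group_scale(self):
        tracks = {
            "control": {"c": np.array([1.0, 10.0, 5.0])},
            "treated": {"c": np.array([20.0, 4.0, 0.0])},
        }
        scaled = ctg.group_scale(tracks, "control")
        assert scaled["control"]["c"].max() == 1.0
        assert scaled["treated"]["c"].max() == 2.0
        with pytest.raises(ValueError):
            ctg.group_scale({"control": {"c": np.zeros(3)}}, "control")


class TestScaledMetagene:
    def test_uniform_equal_coverage_gives_zero_matrix(self, rng):
        g = [gene("g1", 20_000, 30_000, "+")]
        pos = rng.integers(10_000, 40_000, 4000)
        rs_c = read_set(pos, ["+"] * 4000, condition="control")
        rs_t = read_set(pos, ["+"] * 4000, condition="treated")
        res = ctg.scaled_metagene([rs_t], [rs_c], g, flank=3000, bin_width=50)
        assert res.matrix.shape == (1, 60 + 100 + 60)
        assert np.allclose(res.matrix, 0.0)

    def test_strand_symmetric_rows(self, rng):
        # identical sense-coverage patterns on a + and a - gene
        gp = gene("gp", 20_000, 30_000, "+")
        gm = gene("gm", 60_000, 70_000, "-")
        offs = rng.integers(-3000, 13_000, 3000)
        pos_p = 20_000 + offs
        pos_m = 70_000 - 1 - offs
        pos = np.concatenate([pos_p, pos_m])
        strands = np.array(["+"] * 3000 + ["-"] * 3000, dtype=object)
        rs_c = read_set(pos, strands, condition="control")
        # treated: double only the downstream half of each gene, sense-wise
        extra = offs[offs > 5000]
        pos_t = np.concatenate([pos, 20_000 + extra, 70_000 - 1 - extra])
        strands_t = np.concatenate([strands, ["+"] * extra.size, ["-"] * extra.size])
        rs_t = read_set(pos_t, strands_t, condition="treated")
        res = ctg.scaled_metagene([rs_t], [rs_c], [gp, gm], flank=3000, bin_width=50)
        assert np.allclose(res.matrix[0], res.matrix[1], atol=1e-9)

    def test_linear_decay_gives_decreasing_body_profile(self):
        g = [gene("g1", 100_000, 200_000, "+")]
        # control flat, treated decaying linearly across the body
        rng = np.random.default_rng(2)
        pos_c = rng.integers(100_000, 200_000, 50_000)
        u = rng.random(100_000)
        pos_t = (200_000 - 100_000 * np.sqrt(u)).astype(np.int64)  # density ~ linear decay
        rs_c = read_set(pos_c, ["+"] * pos_c.size, condition="control")
        rs_t = read_set(pos_t, ["+"] * pos_t.size, condition="treated")
        res = ctg.scaled_metagene([rs_t], [rs_c], g, flank=3000, bin_width=50)
        body = res.profile[res.body_cols]
        # smoothed thirds strictly decrease, and the fitted slope is negative
        thirds = [body[:33].mean(), body[33:66].mean(), body[66:].mean()]
        assert thirds[0] > thirds[1] > thirds[2]
        assert res.body_slope() < -0.5


class TestTesGroupStats:
    def test_values_and_ranksum(self):
        g = gene("g", 1000, 5000, "+")
        w = ctg.windows_for_genes([g])
        targets = pd.DataFrame({"gene_id": ["g"], "target_class": ["induced"]})
        # library of 1e6 reads scaled: put 9 reads in TES window -> CPM 9 -> log10(10)=1
        tes_pos = np.full(9, 5000)
        filler = np.full(10**3 - 9, 100_000)
        rs_c = read_set(
            np.concatenate([tes_pos, filler]), ["+"] * 1000,
            sample_id="c1", condition="control",
        )
        rs_t = read_set(np.full(1000, 100_000), ["+"] * 1000,
                        sample_id="t1", condition="treated")
        out = ctg.tes_group_stats([rs_c], [rs_t], w, targets)
        row = out.set_index("target_class").loc["induced"]
        assert row["median_control"] == pytest.approx(np.log10(9 * 1e6 / 1e3 + 1))
        assert row["median_treated"] == pytest.approx(0.0)


class TestAntisense:
    def test_no_antisense_reads_gives_zero_lfc(self):
        peaks = [("p1", GenomicInterval("c", 4_000, 4_500), "+")]
        rs = read_set([4100, 4200], ["+", "+"])
        out = ctg.antisense_initiation([rs], [rs], peaks)
        assert out["antisense_cpm_control"].iloc[0] == 0.0
        assert out["antisense_log2fc"].iloc[0] == 0.0

    def test_planted_antisense_burst_detected(self, rng):
        peaks = [("p1", GenomicInterval("c", 40_000, 40_500), "+")]
        base = rng.integers(0, 100_000, 2000)
        rs_c = read_set(base, ["+"] * 2000, condition="control")
        burst = np.concatenate([base, rng.integers(39_900, 40_600, 300)])
        rs_t = read_set(burst, ["+"] * 2000 + ["-"] * 300, condition="treated")
        out = ctg.antisense_initiation([rs_c], [rs_t], peaks)
        assert out["antisense_log2fc"].iloc[0] > 1.0
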