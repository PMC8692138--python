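"""CNV caller: normalization, CBS segmentation, MAD rule, gene reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tumorcross import (
    CnvTruth,
    MadContext,
    SegmentCall,
    annotate_genes,
    best_split,
    call_cnv,
    cbs_segment,
    compute_log2_ratio,
    gc_depth_normalize,
    mad,
    make_genome,
    simulate_depth,
)
from tumorcross.genome import GenomeModel

from conftest import make_track


class TestMad:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([3.0, 3.0, 3.0], 0.0),
            ([-1.0, 0.0, 1.0], 1.0),
            # median 3, deviations {2,1,0,1,97} -> median 1
            ([1.0, 2.0, 3.0, 4.0, 100.0], 1.0),
        ],
    )
    def test_hand_computed_values(self, values, expected):
        assert mad(values) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad([])

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=30),
        st.floats(-10, 10),
    )
    def test_translation_invariant_and_nonnegative(self, values, shift):
        assert mad(values) >= 0
        assert mad(np.asarray(values) + shift) == pytest.approx(mad(values), abs=1e-9)


class TestGcDepthNormalize:
    def test_constant_track_becomes_all_ones(self):
        track = make_track(np.full(50, 200), gc=np.linspace(0.3, 0.6, 50))
        out = gc_depth_normalize(track)
        assert np.allclose(out["norm"], 1.0)

    def test_inflated_gc_bin_recentered(self):
        gc = np.concatenate([np.full(100, 0.40), np.full(100, 0.445), np.full(100, 0.455)])
        counts = np.where((gc >= 0.44) & (gc < 0.46), 200, 100)
        out = gc_depth_normalize(make_track(counts, gc=gc))
        inflated = out.loc[(gc >= 0.44) & (gc < 0.46), "norm"]
        assert abs(np.median(inflated) - np.median(out["norm"])) < 1e-9

    def test_single_bin_reduces_to_depth_scaling(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(500, size=80)
        out = gc_depth_normalize(make_track(counts, gc=0.45))
        expected = (counts + 0.5) / np.median(counts + 0.5)
        assert np.allclose(out["norm"], expected)
        assert np.median(out["norm"]) == pytest.approx(1.0)

    def test_all_zero_track_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gc_depth_normalize(make_track(np.zeros(10)))


class TestLog2Ratio:
    def test_identical_tracks_give_zero(self):
        track = make_track(np.random.default_rng(1).poisson(300, 60))
        out = compute_log2_ratio(track, track.copy())
        assert np.allclose(out["log2_ratio"], 0.0)

    def test_doubled_normalized_counts_give_plus_one(self):
        normal = make_track(np.full(20, 100))
        tumor = make_track(np.full(20, 100))
        normal["norm"] = 1.0
        tumor["norm"] = 2.0
        out = compute_log2_ratio(tumor, normal)
        assert np.allclose(out["log2_ratio"], 1.0)

    def test_grid_mismatch_names_first_discordant_window(self):
        a = make_track(np.full(5, 100))
        b = a.copy()
        b.loc[2, "start"] = 99_999
        with pytest.raises(ValueError, match="row 2"):
            compute_log2_ratio(a, b)
        with pytest.raises(ValueError, match="length"):
            compute_log2_ratio(a, a.iloc[:3])

    def test_low_normal_count_masked(self):
        counts = np.full(40, 400)
        normal = make_track(counts.copy())
        normal.loc[7, "count"] = 0
        tumor = make_track(counts)
        out = compute_log2_ratio(tumor, normal, min_normal_count=5)
        assert out["mask"].sum() == 1 and bool(out.loc[7, "mask"])
        segs = cbs_segment(out, n_permutations=120, seed=1)
        assert sum(s.n_windows for s in segs) == 39
        ctx = MadContext.from_ratios(out)
        assert np.isfinite(ctx.global_median)


def brute_force_best_split(x, min_width):
    """Independent O(n^3) exhaustive change-point search."""
    n = len(x)
    best = (-np.inf, None, None)
    for i in range(0, n - min_width + 1):
        for j in range(i + min_width, n + 1):
            if j - i > n - min_width:
                continue
            arc = x[i:j]
            comp = np.concatenate([x[:i], x[j:]])
            stat = abs(arc.mean() - comp.mean()) * np.sqrt(len(arc) * len(comp) / n)
            if stat > best[0] + 1e-12:
                best = (stat, i, j)
    return best[1], best[2], best[0]


class TestCbs:
    def test_constant_sequence_one_segment_per_chromosome(self):
        ratios = pd.DataFrame(
            {
                "chrom": ["chr1"] * 30 + ["chr2"] * 30,
                "start": list(range(0, 30000, 1000)) * 2,
                "end": list(range(1000, 31000, 1000)) * 2,
                "log2_ratio": 0.2,
                "mask": False,
            }
        )
        segs = cbs_segment(ratios, n_permutations=150, seed=2)
        assert len(segs) == 2
        assert all(s.seg_mean == pytest.approx(0.2) for s in segs)

    def test_noiseless_step_recovered_exactly(self):
        x = np.concatenate([np.zeros(30), np.ones(30)])
        ratios = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(60) * 1000,
                "end": (np.arange(60) + 1) * 1000,
                "log2_ratio": x,
                "mask": False,
            }
        )
        segs = cbs_segment(ratios, alpha=0.01, n_permutations=300, seed=3)
        assert [(s.start, s.end) for s in segs] == [(0, 30_000), (30_000, 60_000)]
        assert [s.seg_mean for s in segs] == [0.0, 1.0]

    def test_first_split_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(8, 31))
            x = rng.normal(size=n)
            if rng.random() < 0.5:  # implant a shift so ties are rare and splits real
                a, b = sorted(rng.choice(np.arange(1, n), size=2, replace=False))
                x[a:b] += rng.uniform(1, 3)
            i, j, stat = best_split(x, min_width=3)
            oi, oj, ostat = brute_force_best_split(x, 3)
            assert stat == pytest.approx(ostat)
            assert (i, j) == (oi, oj)

    def test_null_gaussian_rarely_splits(self):
        # permutation test size: the spec'd replicate bound at alpha=0.01
        rng = np.random.default_rng(5)
        extra = 0
        for rep in range(100):
            x = rng.normal(size=60)
            ratios = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": np.arange(60) * 1000,
                    "end": (np.arange(60) + 1) * 1000,
                    "log2_ratio": x,
                    "mask": False,
                }
            )
            segs = cbs_segment(ratios, alpha=0.01, n_permutations=200, seed=100 + rep)
            extra += len(segs) > 1
        assert extra / 100 <= 0.05

    def test_segments_tile_unmasked_windows(self):
        genome = make_genome(1, 200_000, 5, 1000, 2000, seed=6)
        truth = CnvTruth(segments=(("chr1", 60_000, 90_000, 3.0),))
        tumor, normal = simulate_depth(genome, truth, mean_depth_per_window=400, seed=7)
        ratios = compute_log2_ratio(tumor, normal)
        segs = cbs_segment(ratios, n_permutations=200, seed=8)
        assert sum(s.n_windows for s in segs) == int((~ratios["mask"]).sum())
        ordered = sorted(segs, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start

    def test_parameter_validation(self):
        ratios = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(8) * 1000,
             "end": (np.arange(8) + 1) * 1000,
             "log2_ratio": 0.0, "mask": False}
        )
        with pytest.raises(ValueError, match="min_width"):
            cbs_segment(ratios, min_width=1)
        with pytest.raises(ValueError, match="alpha"):
            cbs_segment(ratios, alpha=1.5)
        with pytest.warns(UserWarning, match="n_permutations"):
            cbs_segment(ratios, n_permutations=50, seed=1)


class TestCallCnv:
    @staticmethod
    def _seg(mean):
        return SegmentCall("chr1", 0, 1000, 1, mean)

    def test_rule_on_hand_cases(self):
        ctx = MadContext(global_median=0.0, mad=0.1)
        segs = [self._seg(m) for m in (0.5, -0.31, 0.30, 0.05)]
        labels = [s.label for s in call_cnv(segs, ctx)]
        assert labels == ["amp", "del", "neutral", "neutral"]  # 0.30 is strict

    def test_constant_track_calls_nothing(self):
        ctx = MadContext(global_median=0.2, mad=0.0)
        segs = [self._seg(0.2), self._seg(0.2)]
        assert all(s.label == "neutral" for s in call_cnv(segs, ctx))

    def test_zero_multiplier_calls_every_departing_segment(self):
        ctx = MadContext(global_median=0.0, mad=0.1, threshold_multiplier=0.0)
        segs = [self._seg(m) for m in (0.01, -0.01, 0.0)]
        assert [s.label for s in call_cnv(segs, ctx)] == ["amp", "del", "neutral"]

    @given(st.lists(st.floats(-2, 2), min_size=1, max_size=20))
    def test_raising_multiplier_never_adds_calls(self, means):
        segs = [self._seg(m) for m in means]
        counts = []
        for mult in (0.0, 1.0, 3.0, 5.0):
            ctx = MadContext(global_median=0.0, mad=0.1, threshold_multiplier=mult)
            counts.append(sum(s.label != "neutral" for s in call_cnv(segs, ctx)))
        assert counts == sorted(counts, reverse=True)


class TestAnnotateGenes:
    @staticmethod
    def _genome(genes):
        return GenomeModel(
            chromosomes=(("chr1", 100_000),),
            genes=pd.DataFrame(genes, columns=["name", "chrom", "start", "end", "strand"]),
        )

    def test_gene_inside_amp_is_cna(self):
        genome = self._genome([("Gene1", "chr1", 10_000, 12_000, "+")])
        segs = [SegmentCall("chr1", 5_000, 20_000, 15, 1.0, "amp")]
        out = annotate_genes(segs, genome, "M1")
        assert out[["gene", "cnv_class", "ambiguous"]].values.tolist() == [["Gene1", "CNA", False]]

    def test_single_bp_overlap_with_del_is_cnd(self):
        genome = self._genome([("Gene1", "chr1", 10_000, 12_000, "+")])
        segs = [SegmentCall("chr1", 11_999, 20_000, 8, -1.0, "del")]
        out = annotate_genes(segs, genome, "M1")
        assert list(out["cnv_class"]) == ["CND"]
        # zero-bp abutment does not count
        segs = [SegmentCall("chr1", 12_000, 20_000, 8, -1.0, "del")]
        assert annotate_genes(segs, genome, "M1").empty

    def test_straddling_gene_reported_under_both_with_flag(self):
        genome = self._genome([("Gene1", "chr1", 9_000, 21_000, "+")])
        segs = [
            SegmentCall("chr1", 0, 10_000, 10, 1.2, "amp"),
            SegmentCall("chr1", 20_000, 30_000, 10, -1.2, "del"),
        ]
        out = annotate_genes(segs, genome, "M1")
        assert sorted(out["cnv_class"]) == ["CNA", "CND"]
        assert out["ambiguous"].all()

    def test_neutral_segments_ignored(self):
        genome = self._genome([("Gene1", "chr1", 10_000, 12_000, "+")])
        segs = [SegmentCall("chr1", 0, 100_000, 100, 0.0, "neutral")]
        assert annotate_genes(segs, genome, "M1").empty
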