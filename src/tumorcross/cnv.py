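"""Read-depth CNV calling: GC normalization, CBS segmentation, MAD calls.

The pipeline is the classic window-depth recipe: reads are counted in
fixed 1 kb windows, counts are corrected for GC bias (median-ratio per
GC bin) and sequencing depth (genome-wide median), the per-window
``log2(tumor) - log2(normal)`` ratio is segmented with circular binary
segmentation (CBS), and each segment is labelled ``amp`` or ``del``
when its mean departs from the global median by strictly more than
``threshold_multiplier`` times the (unscaled) median absolute deviation
of the log2 ratios.

CBS here is the permutation-tested variant: for a stretch of windows
the maximal arc-vs-complement standardized mean difference over all
circular change-point pairs is compared against the same statistic on
seeded permutations of the stretch; an accepted split recurses on the
resulting pieces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome import GenomeModel

__all__ = [
    "SegmentCall",
    "MadContext",
    "mad",
    "gc_depth_normalize",
    "compute_log2_ratio",
    "best_split",
    "cbs_segment",
    "call_cnv",
    "annotate_genes",
]

#: pseudo-count added to raw window counts before normalization, so
#: log2 ratios stay finite; negligible at realistic depths.
PSEUDO_COUNT = 0.5


@dataclass(frozen=True)
class SegmentCall:
    """One CBS segment (0-based half-open, window-aligned)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    seg_mean: float
    label: str = "neutral"


@dataclass(frozen=True)
class MadContext:
    """Global location/scale of the log2 ratios used by the call rule."""

    global_median: float
    mad: float
    threshold_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if self.mad < 0:
            raise ValueError("mad must be >= 0")

    @classmethod
    def from_ratios(
        cls, ratios: pd.DataFrame, threshold_multiplier: float = 3.0
    ) -> "MadContext":
        """Compute median and MAD over the unmasked log2 ratios."""
        values = ratios.loc[~ratios["mask"], "log2_ratio"].to_numpy()
        return cls(
            global_median=float(np.median(values)),
            mad=mad(values),
            threshold_multiplier=threshold_multiplier,
        )


def mad(values: Sequence[float] | np.ndarray) -> float:
    """Median absolute deviation, unscaled: ``median(|x - median(x)|)``.

    No Gaussian-consistency factor (1.4826) is applied.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mad of empty input")
    return float(np.median(np.abs(values - np.median(values))))


# ---------------------------------------------------------------------------
# normalization

def gc_depth_normalize(
    track: pd.DataFrame, gc_bin_width: float = 0.01, min_bin_count: int = 10
) -> pd.DataFrame:
    """Correct window counts for GC bias and sequencing depth.

    Each (pseudo-counted) window count is divided by the median count of
    its GC bin, then by the genome-wide median of that ratio, so the
    output ``norm`` column has median exactly 1.  Bins holding fewer
    than ``min_bin_count`` windows fall back to the genome-wide median
    divisor: a sparse bin's median is dominated by the very windows
    being corrected, so "correcting" against it would erase any real
    copy-number signal they carry.
    """
    if gc_bin_width <= 0:
        raise ValueError("gc_bin_width must be > 0")
    required = {"chrom", "start", "end", "gc_fraction", "count"}
    missing = required - set(track.columns)
    if missing:
        raise ValueError(f"window track missing columns: {sorted(missing)}")
    counts = track["count"].to_numpy(dtype=float)
    if counts.sum() == 0:
        raise ValueError("all-zero window track cannot be normalized")
    x = counts + PSEUDO_COUNT
    bins = np.floor(track["gc_fraction"].to_numpy() / gc_bin_width).astype(int)
    grouped = pd.Series(x).groupby(bins)
    bin_median = grouped.transform("median").to_numpy()
    bin_size = grouped.transform("size").to_numpy()
    bin_median = np.where(bin_size >= min_bin_count, bin_median, np.median(x))
    y = x / bin_median
    norm = y / np.median(y)
    out = track.copy()
    out["norm"] = norm
    return out


def compute_log2_ratio(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    min_normal_count: int = 5,
    gc_bin_width: float = 0.01,
) -> pd.DataFrame:
    """Per-window ``log2(tumor_norm) - log2(normal_norm)`` on a shared grid.

    Tracks are normalized first (if a ``norm`` column is absent).
    Windows whose raw normal count falls below ``min_normal_count`` are
    masked; masked windows are excluded from segmentation and from the
    MAD context.
    """
    for key in ("chrom", "start", "end"):
        t = tumor[key].to_numpy()
        n = normal[key].to_numpy()
        if len(t) != len(n) or (t != n).any():
            if len(t) != len(n):
                raise ValueError(
                    f"window grids differ in length ({len(t)} vs {len(n)})"
                )
            i = int(np.nonzero(t != n)[0][0])
            raise ValueError(
                f"window grid mismatch at row {i}: "
                f"tumor {tumor['chrom'].iat[i]}:{tumor['start'].iat[i]}-{tumor['end'].iat[i]} vs "
                f"normal {normal['chrom'].iat[i]}:{normal['start'].iat[i]}-{normal['end'].iat[i]}"
            )
    if "norm" not in tumor.columns:
        tumor = gc_depth_normalize(tumor, gc_bin_width)
    if "norm" not in normal.columns:
        normal = gc_depth_normalize(normal, gc_bin_width)
    out = tumor[["chrom", "start", "end", "gc_fraction"]].copy()
    out["tumor_count"] = tumor["count"].to_numpy()
    out["normal_count"] = normal["count"].to_numpy()
    out["tumor_norm"] = tumor["norm"].to_numpy()
    out["normal_norm"] = normal["norm"].to_numpy()
    out["log2_ratio"] = np.log2(out["tumor_norm"]) - np.log2(out["normal_norm"])
    out["mask"] = out["normal_count"].to_numpy() < min_normal_count
    return out


# ---------------------------------------------------------------------------
# circular binary segmentation

def _arc_stats(x: np.ndarray, k: int) -> np.ndarray:
    """Standardized |mean(arc) - mean(complement)| for all arcs of length k."""
    n = len(x)
    c = np.concatenate(([0.0], np.cumsum(x)))
    s = c[k:] - c[:-k]
    total = c[-1]
    diff = s / k - (total - s) / (n - k)
    return np.abs(diff) * np.sqrt(k * (n - k) / n)


def best_split(x: np.ndarray, min_width: int = 3) -> tuple[int, int, float]:
    """Maximal circular change-point pair for one stretch of windows.

    Returns ``(i, j, stat)`` where the arc is ``x[i:j]`` with
    ``min_width <= j - i <= n - min_width``.  Ties are broken by the
    leftmost ``i``, then the shortest arc.  Arcs ending exactly at the
    right boundary with ``i > 0`` are skipped: they define the same
    single change point as the complementary left-anchored arc and
    would only reintroduce it with float round-off.
    """
    n = len(x)
    if n < 2 * min_width:
        raise ValueError(f"need at least {2 * min_width} windows, got {n}")
    best_stat = -np.inf
    best_i = 0
    best_k = min_width
    for k in range(min_width, n - min_width + 1):
        stats = _arc_stats(x, k)
        if len(stats) > 1:
            stats = stats[:-1]
        i = int(np.argmax(stats))
        s = float(stats[i])
        if s > best_stat or (s == best_stat and (i, k) < (best_i, best_k)):
            best_stat, best_i, best_k = s, i, k
    return best_i, best_i + best_k, best_stat


def _max_stat(x: np.ndarray, min_width: int) -> float:
    n = len(x)
    best = -np.inf
    for k in range(min_width, n - min_width + 1):
        m = float(_arc_stats(x, k).max())
        if m > best:
            best = m
    return best


def _split_p_value(
    x: np.ndarray,
    observed: float,
    min_width: int,
    n_permutations: int,
    rng: np.random.Generator,
    alpha: float,
) -> float:
    """Permutation p-value of the maximal statistic, with early stopping.

    ``p = (1 + #{perm >= observed}) / (1 + B)``.  Once enough
    permutations have met the observed statistic that ``p >= alpha`` is
    guaranteed, remaining permutations are skipped and a conservative
    value is returned; the accept/reject decision is unaffected.
    """
    stop_count = int(np.ceil(alpha * (1 + n_permutations)))  # count+1 > this => p >= alpha
    count = 0
    for b in range(n_permutations):
        if _max_stat(rng.permutation(x), min_width) >= observed:
            count += 1
            if count + 1 > stop_count:
                return max(alpha, (count + 1) / (b + 2))
    return (count + 1) / (n_permutations + 1)


def _segment_one(
    x: np.ndarray,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive CBS on one chromosome; returns half-open index pieces."""

    def recurse(lo: int, hi: int) -> list[tuple[int, int]]:
        n = hi - lo
        if n < 2 * min_width:
            return [(lo, hi)]
        i, j, stat = best_split(x[lo:hi], min_width)
        p = _split_p_value(x[lo:hi], stat, min_width, n_permutations, rng, alpha)
        if p >= alpha:
            return [(lo, hi)]
        cuts = sorted({lo + i, lo + j} - {lo, hi})
        if not cuts:  # arc equals the whole stretch; nothing to split
            return [(lo, hi)]
        bounds = [lo, *cuts, hi]
        pieces: list[tuple[int, int]] = []
        for a, b in zip(bounds, bounds[1:]):
            pieces.extend(recurse(a, b))
        return pieces

    return recurse(0, len(x))


def cbs_segment(
    ratios: pd.DataFrame,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    min_width: int = 3,
    seed: int = 0,
) -> list[SegmentCall]:
    """Segment unmasked log2 ratios chromosome by chromosome.

    Parameters follow DNA-copy conventions: ``alpha`` is the permutation
    significance level for accepting a split, ``min_width`` the minimum
    segment width in windows.  Deterministic for a fixed seed.  Segments
    tile the unmasked windows of each chromosome and carry their mean
    log2 ratio; all labels are ``neutral`` (labelling is
    :func:`call_cnv`'s job).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if min_width < 2:
        raise ValueError("min_width must be >= 2")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations={n_permutations} gives coarse p-values; use >= 100",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    segments: list[SegmentCall] = []
    for chrom in pd.unique(ratios["chrom"]):
        sub = ratios[(ratios["chrom"] == chrom) & (~ratios["mask"])]
        if len(sub) == 0:
            continue
        x = sub["log2_ratio"].to_numpy()
        if len(x) < min_width:
            raise ValueError(
                f"chromosome {chrom!r} has {len(x)} unmasked windows (< min_width={min_width})"
            )
        if len(x) < 2 * min_width:
            pieces = [(0, len(x))]
        else:
            pieces = _segment_one(x, alpha, n_permutations, min_width, rng)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for lo, hi in pieces:
            segments.append(
                SegmentCall(
                    chrom=str(chrom),
                    start=int(starts[lo]),
                    end=int(ends[hi - 1]),
                    n_windows=hi - lo,
                    seg_mean=float(np.mean(x[lo:hi])),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# calling and gene annotation

def call_cnv(segments: Sequence[SegmentCall], context: MadContext) -> list[SegmentCall]:
    """Label segments amp/del by the strict multiplier-times-MAD rule.

    ``amp`` iff ``seg_mean - global_median > multiplier * mad`` and
    ``del`` iff ``seg_mean - global_median < -multiplier * mad``; ties
    at exactly the threshold stay ``neutral``.  A zero MAD over
    non-constant data would call every departing segment; with constant
    data all segments are neutral (their means equal the median).
    """
    threshold = context.threshold_multiplier * context.mad
    out = []
    for seg in segments:
        delta = seg.seg_mean - context.global_median
        if delta > threshold:
            label = "amp"
        elif delta < -threshold:
            label = "del"
        else:
            label = "neutral"
        out.append(replace(seg, label=label))
    return out


def annotate_genes(
    segments: Sequence[SegmentCall],
    genome: GenomeModel,
    tumor_id: str,
) -> pd.DataFrame:
    """Reduce labelled segments to gene-level CNA/CND records.

    A gene is CNA (CND) for the tumor iff it overlaps at least one amp
    (del) segment by >= 1 bp.  Genes overlapping both classes get a
    record under each with ``ambiguous=True``.

    Returns columns ``gene, tumor_id, cnv_class, chrom, gene_start,
    gene_end, seg_mean, ambiguous``.
    """
    trees: dict[str, IntervalTree] = {}
    for seg in segments:
        if seg.label in ("amp", "del"):
            trees.setdefault(seg.chrom, IntervalTree()).addi(seg.start, seg.end, seg)
    rows = []
    for g in genome.genes.itertuples():
        tree = trees.get(g.chrom)
        if tree is None:
            continue
        hits = sorted(tree.overlap(g.start, g.end), key=lambda iv: iv.begin)
        if not hits:
            continue
        labels = {iv.data.label for iv in hits}
        ambiguous = labels == {"amp", "del"}
        for label, cnv_class in (("amp", "CNA"), ("del", "CND")):
            matching = [iv.data for iv in hits if iv.data.label == label]
            if not matching:
                continue
            rows.append(
                {
                    "gene": g.name,
                    "tumor_id": tumor_id,
                    "cnv_class": cnv_class,
                    "chrom": g.chrom,
                    "gene_start": g.start,
                    "gene_end": g.end,
                    "seg_mean": float(np.mean([s.seg_mean for s in matching])),
                    "ambiguous": ambiguous,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "tumor_id",
            "cnv_class",
            "chrom",
            "gene_start",
            "gene_end",
            "seg_mean",
            "ambiguous",
        ],
    )
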