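"""Toy genome models: chromosomes, gene annotations and CNV ground truth.

A :class:`GenomeModel` is the coordinate system every other module works
in -- fixed-width read-counting windows, BED-style 0-based half-open gene
intervals -- and :class:`CnvTruth` records the copy-ratio segments a
simulation implants so recovery can be scored against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "CnvTruth", "make_genome"]

GENE_COLUMNS = ["name", "chrom", "start", "end", "strand"]


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome sizes plus a non-overlapping gene annotation.

    Parameters
    ----------
    chromosomes
        ``[(name, length_bp), ...]`` in genome order.
    genes
        DataFrame with columns ``name, chrom, start, end, strand``;
        coordinates are 0-based half-open.
    window_size
        Width in bp of the read-counting windows (default 1000).
    """

    chromosomes: tuple[tuple[str, int], ...]
    genes: pd.DataFrame = field(repr=False)
    window_size: int = 1000

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        object.__setattr__(self, "chromosomes", tuple((str(c), int(n)) for c, n in self.chromosomes))
        sizes = dict(self.chromosomes)
        g = self.genes
        missing = [c for c in GENE_COLUMNS if c not in g.columns]
        if missing:
            raise ValueError(f"gene table missing columns: {missing}")
        if g["name"].duplicated().any():
            dup = g.loc[g["name"].duplicated(), "name"].iloc[0]
            raise ValueError(f"duplicate gene name: {dup!r}")
        if (g["start"] >= g["end"]).any():
            bad = g.loc[g["start"] >= g["end"]].iloc[0]
            raise ValueError(f"gene {bad['name']!r} has start >= end")
        for _, row in g.iterrows():
            if row["chrom"] not in sizes:
                raise ValueError(f"gene {row['name']!r} on unknown chromosome {row['chrom']!r}")
            if row["start"] < 0 or row["end"] > sizes[row["chrom"]]:
                raise ValueError(f"gene {row['name']!r} extends outside {row['chrom']!r}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def gene_lengths(self) -> pd.Series:
        """Gene length in bp, indexed by gene name."""
        g = self.genes
        return pd.Series((g["end"] - g["start"]).to_numpy(), index=g["name"].to_numpy())

    def windows(self) -> pd.DataFrame:
        """Tile every chromosome with fixed-width windows.

        The final window of a chromosome may be shorter when the length
        is not a multiple of ``window_size``.
        """
        frames = []
        for chrom, length in self.chromosomes:
            starts = np.arange(0, length, self.window_size, dtype=np.int64)
            ends = np.minimum(starts + self.window_size, length)
            frames.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class CnvTruth:
    """Implanted copy-ratio segments used as simulation ground truth.

    ``copy_ratio`` is relative to the normal sample: 1.0 is neutral,
    2.0 a one-copy-equivalent gain in a diploid genome, 0.5 a loss.
    ``purity`` is the tumor-cell fraction of the sample; the observed
    ratio in a window is ``purity * copy_ratio + (1 - purity)``.
    """

    segments: tuple[tuple[str, int, int, float], ...] = ()
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        segs = tuple((str(c), int(s), int(e), float(r)) for c, s, e, r in self.segments)
        object.__setattr__(self, "segments", segs)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, ratio in segs:
            if start >= end:
                raise ValueError(f"segment on {chrom} has start >= end")
            if ratio <= 0:
                raise ValueError("copy_ratio must be > 0")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping truth segments on {chrom}")

    def validate_against(self, genome: GenomeModel) -> None:
        sizes = genome.chrom_sizes
        for chrom, start, end, _ in self.segments:
            if chrom not in sizes:
                raise ValueError(f"truth segment on unknown chromosome {chrom!r}")
            if start < 0 or end > sizes[chrom]:
                raise ValueError(f"truth segment {chrom}:{start}-{end} outside chromosome")

    def copy_ratio_at(self, chrom: np.ndarray, midpoint: np.ndarray) -> np.ndarray:
        """Copy ratio of the segment covering each window midpoint (1.0 elsewhere)."""
        ratio = np.ones(len(midpoint), dtype=float)
        for seg_chrom, start, end, r in self.segments:
            hit = (chrom == seg_chrom) & (midpoint >= start) & (midpoint < end)
            ratio[hit] = r
        return ratio


def make_genome(
    n_chromosomes: int,
    chromosome_length_bp: int,
    n_genes: int,
    min_gene_len: int,
    max_gene_len: int,
    seed: int,
    window_size: int = 1000,
) -> GenomeModel:
    """Build a random genome with non-overlapping genes.

    Genes are spread round-robin across chromosomes; on each chromosome
    the inter-gene gaps are drawn uniformly over the feasible spacings,
    so placement is deterministic for a fixed ``seed``.  When
    ``min_gene_len`` < 1000 at least one sub-kilobase gene is guaranteed
    (short genes matter to deletion-inclusion rules downstream).

    Raises
    ------
    ValueError
        If the requested genes cannot be packed without overlap.
    """
    if min_gene_len < 1:
        raise ValueError("min_gene_len must be >= 1")
    if max_gene_len < min_gene_len:
        raise ValueError("max_gene_len must be >= min_gene_len")
    rng = np.random.default_rng(seed)
    chromosomes = tuple((f"chr{i + 1}", int(chromosome_length_bp)) for i in range(n_chromosomes))

    lengths = rng.integers(min_gene_len, max_gene_len + 1, size=n_genes)
    if min_gene_len < 1000 and n_genes > 0 and not (lengths < 1000).any():
        lengths[0] = int(rng.integers(min_gene_len, min(1000, max_gene_len + 1)))

    # round-robin assignment keeps per-chromosome load balanced
    chrom_of = np.arange(n_genes) % max(n_chromosomes, 1)
    records = []
    for ci, (chrom, clen) in enumerate(chromosomes):
        idx = np.where(chrom_of == ci)[0]
        lens = lengths[idx]
        free = clen - int(lens.sum())
        if free < 0:
            raise ValueError(
                f"cannot pack {len(idx)} genes totalling {int(lens.sum())} bp "
                f"into {chrom} of {clen} bp"
            )
        # k+1 gaps summing to `free`: order statistics of uniform draws
        k = len(idx)
        cuts = np.sort(rng.integers(0, free + 1, size=k)) if k else np.array([], dtype=int)
        pos = 0
        prev_cut = 0
        for order, (gi, cut) in enumerate(zip(idx, cuts)):
            gap = int(cut - prev_cut)
            prev_cut = cut
            start = pos + gap
            end = start + int(lengths[gi])
            pos = end
            records.append(
                {
                    "name": f"Gene{gi + 1:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
    genes = pd.DataFrame(records, columns=GENE_COLUMNS).sort_values(["chrom", "start"]).reset_index(drop=True)
    return GenomeModel(chromosomes=chromosomes, genes=genes, window_size=window_size)
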