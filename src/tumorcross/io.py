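"""Readers, writers and run configuration.

Text formats only: BED6 gene annotations (0-based half-open), IGV-style
SEG segment files (1-based inclusive, per that format's convention),
6-column window TSVs, MAF-like mutation TSVs, long-format cohort TSVs,
two-column ortholog TSVs and GMT gene sets.  Every file this package
writes starts with ``#``-prefixed provenance lines (tool version,
config hash, seed); readers skip them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cnv import SegmentCall

__all__ = [
    "RunConfig",
    "read_bed",
    "write_bed",
    "read_windows",
    "write_windows",
    "write_seg",
    "read_seg",
    "read_gmt",
    "write_gmt",
    "read_mutations",
    "write_mutations",
    "read_cohort",
    "write_cohort",
    "read_orthologs",
    "write_orthologs",
]

WINDOW_COLUMNS = ["chrom", "start", "end", "gc_fraction", "tumor_count", "normal_count"]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_mark", "seg_mean"]


@dataclass(frozen=True)
class RunConfig:
    """Parameters of one full pipeline run.

    Echoed (as a hash) into every output's provenance header so any
    result file identifies the configuration that produced it.
    """

    seed: int = 0
    window_size: int = 1000
    alpha: float = 0.01
    n_permutations: int = 1000
    mad_multiplier: float = 3.0
    consensus_mode: str = "sift_and_polyphen"
    classifier_mode: str = "biallelic"
    min_tumors: int = 2
    min_normal_count: int = 5
    n_mouse_tumors: int = 8
    n_human_tumors: int = 400
    n_chromosomes: int = 2
    chromosome_length_bp: int = 400_000
    n_genes: int = 120
    min_gene_len: int = 600
    max_gene_len: int = 6_000
    mean_depth_per_window: float = 500.0
    dispersion: float = 0.01
    purity: float = 1.0
    mutations_per_tumor: int = 60
    deleterious_fraction: float = 0.5
    category_probs: tuple[float, float, float, float] = (0.166, 0.421, 0.116, 0.297)
    background_gene_alteration_rate: float = 0.05
    paths: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: object) -> "RunConfig":
        """Load a key-value YAML config; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a mapping")
        raw.update(overrides)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "category_probs" in raw:
            raw["category_probs"] = tuple(raw["category_probs"])
        return cls(**raw)  # type: ignore[arg-type]

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance_lines(self) -> list[str]:
        return [
            f"#tumorcross_version={__version__}",
            f"#config_hash={self.config_hash()}",
            f"#seed={self.seed}",
        ]


def _provenance(config: RunConfig | None) -> str:
    if config is None:
        return f"#tumorcross_version={__version__}\n"
    return "".join(line + "\n" for line in config.provenance_lines())


def _read_table(path: str | Path, names: Sequence[str] | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", header=0 if names is None else None,
                       names=names)


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED6 into ``name, chrom, start, end, strand`` (0-based half-open).

    Malformed lines are reported with their 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 BED columns, got {len(parts)}")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end} (start must be < end)"
                )
            strand = parts[5] if len(parts) >= 6 else "+"
            rows.append({"name": parts[3], "chrom": chrom, "start": start, "end": end, "strand": strand})
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end", "strand"])


def write_bed(path: str | Path, genes: pd.DataFrame, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        for g in genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# window tracks

def write_windows(
    path: str | Path,
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    config: RunConfig | None = None,
) -> None:
    """Write the 6-column combined tumor/normal window TSV."""
    df = tumor[["chrom", "start", "end", "gc_fraction"]].copy()
    df["tumor_count"] = tumor["count"].to_numpy()
    df["normal_count"] = normal["count"].to_numpy()
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False)


def read_windows(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a window TSV back into (tumor, normal) count tracks."""
    df = _read_table(path)
    missing = set(WINDOW_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing window columns {sorted(missing)}")
    for col in ("tumor_count", "normal_count"):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric counts in column {col!r}")
    base = df[["chrom", "start", "end", "gc_fraction"]]
    tumor = base.copy()
    tumor["count"] = df["tumor_count"].to_numpy()
    normal = base.copy()
    normal["count"] = df["normal_count"].to_numpy()
    return tumor, normal


# ---------------------------------------------------------------------------
# SEG

def write_seg(
    path: str | Path,
    segments: Sequence[SegmentCall],
    sample: str,
    config: RunConfig | None = None,
    labels: bool = False,
) -> None:
    """Write IGV SEG (1-based inclusive starts; ends already inclusive).

    With ``labels=True`` an extra ``label`` column carries the
    amp/del/neutral call.
    """
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        cols = SEG_COLUMNS + (["label"] if labels else [])
        fh.write("\t".join(cols) + "\n")
        for seg in segments:
            row = [sample, seg.chrom, str(seg.start + 1), str(seg.end), str(seg.n_windows),
                   f"{seg.seg_mean:.6g}"]
            if labels:
                row.append(seg.label)
            fh.write("\t".join(row) + "\n")


def read_seg(path: str | Path) -> list[SegmentCall]:
    df = _read_table(path)
    segs = []
    for r in df.itertuples(index=False):
        if r.start < 1 or r.end < r.start:
            raise ValueError(f"{path}: invalid SEG interval {r.chrom}:{r.start}-{r.end}")
        segs.append(
            SegmentCall(
                chrom=str(r.chrom),
                start=int(r.start) - 1,
                end=int(r.end),
                n_windows=int(r.num_mark),
                seg_mean=float(r.seg_mean),
                label=getattr(r, "label", "neutral"),
            )
        )
    return segs


# ---------------------------------------------------------------------------
# GMT

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT: one set per line, ``name <tab> description <tab> genes...``."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(path: str | Path, gene_sets: Mapping[str, Iterable[str]]) -> None:
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# mutation, cohort, ortholog tables

def write_mutations(path: str | Path, records: pd.DataFrame, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        records.to_csv(fh, sep="\t", index=False)


def read_mutations(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    for col in ("sift_score", "polyphen_score", "provean_score"):
        if col in df.columns and not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"{path}: non-numeric scores in column {col!r}")
    return df


def write_cohort(path: str | Path, frame: pd.DataFrame, config: RunConfig | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        frame.to_csv(fh, sep="\t", index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = _read_table(path)
    df["gene"] = df["gene"].fillna("")
    df["cn_state"] = df["cn_state"].fillna("")
    df["protein_change"] = df["protein_change"].fillna("")
    df["variant_class"] = df["variant_class"].fillna("")
    cn = df[df["cn_state"] != ""]
    dup = cn.duplicated(subset=["tumor_id", "gene"])
    if dup.any():
        r = cn[dup].iloc[0]
        raise ValueError(f"{path}: duplicate CN row for tumor {r['tumor_id']!r}, gene {r['gene']!r}")
    return df


def write_orthologs(path: str | Path, pairs: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("mouse_symbol\thuman_symbol\n")
        for mouse, human in pairs:
            fh.write(f"{mouse}\t{human}\n")


def read_orthologs(path: str | Path) -> list[tuple[str, str]]:
    df = _read_table(path)
    return [(str(m), str(h)) for m, h in zip(df.iloc[:, 0], df.iloc[:, 1])]
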