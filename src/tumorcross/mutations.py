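"""Deleterious-mutation consensus filtering and per-tumor summaries.

Somatic protein-altering mutations arrive with precomputed predictor
scores (SIFT, PolyPhen-2, PROVEAN).  A record is deleterious when the
configured consensus of predictors says so; truncating variants are
deleterious by definition and synonymous ones never are.  Deleterious
records aggregate to a gene -> tumor-set table, from which recurrence
and per-tumor event statistics are computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "ScoreThresholds",
    "GeneMutationTable",
    "classify_deleterious",
    "classify_frame",
    "aggregate_by_gene",
    "recurrent_genes",
    "summarize_per_tumor",
]

logger = logging.getLogger(__name__)

TRUNCATING_CLASSES = frozenset({"nonsense", "frameshift_indel"})
CONSENSUS_MODES = ("sift_and_polyphen", "any", "majority_of_available")


@dataclass(frozen=True)
class ScoreThresholds:
    """Published default cutoffs of the three predictors.

    SIFT calls damaging below 0.05; PolyPhen-2 "possibly damaging" at
    0.446 and above; PROVEAN deleterious at -2.5 and below.
    """

    sift_max: float = 0.05        # damaging iff score < sift_max
    polyphen_min: float = 0.446   # damaging iff score >= polyphen_min
    provean_max: float = -2.5     # damaging iff score <= provean_max


DEFAULT_THRESHOLDS = ScoreThresholds()


def _votes(
    record: Mapping[str, object], thresholds: ScoreThresholds, predictors: Sequence[str]
) -> list[bool]:
    votes = []
    for name in predictors:
        score = record.get(f"{name}_score")
        if score is None or (isinstance(score, float) and np.isnan(score)):
            continue
        score = float(score)  # type: ignore[arg-type]
        if name == "sift":
            votes.append(score < thresholds.sift_max)
        elif name == "polyphen":
            votes.append(score >= thresholds.polyphen_min)
        elif name == "provean":
            votes.append(score <= thresholds.provean_max)
    return votes


def classify_deleterious(
    record: Mapping[str, object],
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    consensus_mode: str = "sift_and_polyphen",
) -> bool:
    """Deleterious verdict for one mutation record.

    Rules, in order: synonymous records are never deleterious;
    truncating variants (nonsense, frameshift) always are, scores or
    not.  Otherwise the predictors vote -- a missing score drops that
    predictor from the vote:

    * ``sift_and_polyphen`` (default): every available vote among SIFT
      and PolyPhen must be damaging (PROVEAN does not participate);
    * ``any``: at least one available predictor damaging;
    * ``majority_of_available``: strictly more than half.

    A missense record with no usable score is non-deleterious (logged).
    """
    if consensus_mode not in CONSENSUS_MODES:
        raise ValueError(f"unknown consensus_mode {consensus_mode!r}")
    vclass = record.get("variant_class", "missense")
    if vclass == "synonymous":
        return False
    if vclass in TRUNCATING_CLASSES:
        return True
    predictors = ("sift", "polyphen") if consensus_mode == "sift_and_polyphen" else (
        "sift",
        "polyphen",
        "provean",
    )
    votes = _votes(record, thresholds, predictors)
    if not votes:
        logger.warning(
            "mutation %s:%s has no usable predictor score; classified non-deleterious",
            record.get("gene", "?"),
            record.get("protein_change") or record.get("pos", "?"),
        )
        return False
    if consensus_mode == "sift_and_polyphen":
        return all(votes)
    if consensus_mode == "any":
        return any(votes)
    return sum(votes) > len(votes) / 2


def classify_frame(
    records: pd.DataFrame,
    thresholds: ScoreThresholds = DEFAULT_THRESHOLDS,
    consensus_mode: str = "sift_and_polyphen",
) -> pd.DataFrame:
    """Apply :func:`classify_deleterious` row-wise, adding ``deleterious``."""
    out = records.copy()
    out["deleterious"] = [
        classify_deleterious(row, thresholds, consensus_mode)
        for row in records.to_dict("records")
    ]
    return out


@dataclass(frozen=True)
class GeneMutationTable:
    """gene -> tumors carrying at least one deleterious record."""

    gene_tumors: Mapping[str, frozenset[str]]
    n_tumors: int
    tumor_ids: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.tumor_ids:
            for gene, tumors in self.gene_tumors.items():
                stray = tumors - self.tumor_ids
                if stray:
                    raise ValueError(f"gene {gene!r} cites unknown tumors {sorted(stray)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_tumors)


def aggregate_by_gene(
    records: pd.DataFrame, n_tumors: int | None = None
) -> GeneMutationTable:
    """Collapse classified records to the deleterious gene/tumor map.

    Only rows with ``deleterious == True`` contribute; a gene hit twice
    in one tumor counts that tumor once.  ``n_tumors`` defaults to the
    number of distinct tumor ids in the input (pass the cohort size
    explicitly if some tumors have no deleterious record).
    """
    if "deleterious" not in records.columns:
        raise ValueError("records must be classified first (no 'deleterious' column)")
    tumor_ids = frozenset(records["tumor_id"].astype(str))
    hits = records[records["deleterious"].astype(bool)]
    gene_tumors = {
        str(gene): frozenset(grp["tumor_id"].astype(str))
        for gene, grp in hits.groupby("gene", sort=True)
    }
    return GeneMutationTable(
        gene_tumors=gene_tumors,
        n_tumors=len(tumor_ids) if n_tumors is None else int(n_tumors),
        tumor_ids=tumor_ids,
    )


def recurrent_genes(table: GeneMutationTable, min_fraction: float) -> list[str]:
    """Genes deleteriously mutated in >= ``min_fraction`` of tumors (inclusive)."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    return sorted(
        gene
        for gene, tumors in table.gene_tumors.items()
        if len(tumors) / table.n_tumors >= min_fraction
    )


def summarize_per_tumor(
    records: pd.DataFrame,
    gene_cnvs: pd.DataFrame | None = None,
    tumor_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tumor event counts with cohort mean +/- SEM.

    Counts per tumor: total mutations, deleterious mutations, distinct
    deleteriously mutated genes, and (when ``gene_cnvs`` is given)
    distinct CNA and CND genes.  The summary carries the raw mean, the
    mean rounded half-up to one decimal, and ``SEM = sd / sqrt(n)``
    (sample sd, ddof=1; 0 for n=1).

    Returns ``(per_tumor, summary)`` DataFrames.
    """
    if "deleterious" not in records.columns:
        raise ValueError("records must be classified first (no 'deleterious' column)")
    ids = list(
        tumor_ids
        if tumor_ids is not None
        else pd.unique(
            pd.concat(
                [
                    records["tumor_id"].astype(str),
                    gene_cnvs["tumor_id"].astype(str)
                    if gene_cnvs is not None and len(gene_cnvs)
                    else pd.Series([], dtype=str),
                ]
            )
        )
    )
    rows = []
    for tid in ids:
        sub = records[records["tumor_id"].astype(str) == tid]
        dele = sub[sub["deleterious"].astype(bool)]
        row = {
            "tumor_id": tid,
            "total_mutations": len(sub),
            "deleterious_mutations": len(dele),
            "mutated_genes": dele["gene"].nunique(),
        }
        if gene_cnvs is not None:
            cn = gene_cnvs[gene_cnvs["tumor_id"].astype(str) == tid]
            row["cna_genes"] = cn.loc[cn["cnv_class"] == "CNA", "gene"].nunique()
            row["cnd_genes"] = cn.loc[cn["cnv_class"] == "CND", "gene"].nunique()
        rows.append(row)
    per_tumor = pd.DataFrame(rows)
    metrics = [c for c in per_tumor.columns if c != "tumor_id"]
    n = len(per_tumor)
    summary_rows = []
    for m in metrics:
        vals = per_tumor[m].to_numpy(dtype=float)
        mean = float(vals.mean())
        sem = float(vals.std(ddof=1) / sqrt(n)) if n > 1 else 0.0
        summary_rows.append(
            {
                "metric": m,
                "mean": mean,
                "mean_1dp": round_half_up(mean, 1),
                "sem": sem,
                "n": n,
            }
        )
    return per_tumor, pd.DataFrame(summary_rows)
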