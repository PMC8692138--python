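"""Cross-species altered-gene comparison and over-representation.

Mouse tumors and a human-style cohort each yield, per alteration class
(deleterious NSPM/InDel, CNA, CND), a set of altered genes with the
tumors carrying each.  Human sets pass recurrence and gene-length
inclusion filters; mouse symbols are mapped to human through an
ortholog table; and the intersection is summarized as the fraction of
the mouse inventory also altered in the human cohort
(``100 * |common| / mouse_total``).  Per-tumor event rates are
contrasted with a Welch t-test, and common-gene lists can be scored for
gene-set over-representation with a hypergeometric tail plus
Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import round_half_up

__all__ = [
    "ALTERATION_CLASSES",
    "AlterationSet",
    "OrthologMap",
    "CommonGeneReport",
    "human_included_genes",
    "mouse_alteration_set",
    "common_genes",
    "frequency_table",
    "compare_event_rates",
    "overrepresentation",
]

ALTERATION_CLASSES = ("NSPM_InDel", "CNA", "CND")

#: minimum human gene length (bp) for a deletion-affected gene to count
MIN_CND_GENE_LENGTH = 1000


@dataclass(frozen=True)
class AlterationSet:
    """Per-class gene inventory: gene -> tumors altered."""

    species: str
    alteration_class: str
    genes: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValueError(f"unknown alteration class {self.alteration_class!r}")

    @property
    def gene_names(self) -> set[str]:
        return set(self.genes)


class OrthologMap:
    """Mouse <-> human symbol pairs.

    Symbols are canonicalized on construction and lookup: mouse symbols
    Title-case, human symbols UPPER-case (the usual nomenclature
    convention).  Duplicate mouse entries are rejected.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self._m2h: dict[str, str] = {}
        for mouse, human in pairs:
            m = self.canonical_mouse(mouse)
            h = self.canonical_human(human)
            if m in self._m2h and self._m2h[m] != h:
                raise ValueError(f"conflicting ortholog entries for mouse symbol {m!r}")
            self._m2h[m] = h

    @staticmethod
    def canonical_mouse(symbol: str) -> str:
        return symbol.strip().capitalize()

    @staticmethod
    def canonical_human(symbol: str) -> str:
        return symbol.strip().upper()

    def to_human(self, mouse_symbol: str) -> str | None:
        return self._m2h.get(self.canonical_mouse(mouse_symbol))

    def __len__(self) -> int:
        return len(self._m2h)

    @classmethod
    def identity_for(cls, mouse_symbols: Iterable[str]) -> "OrthologMap":
        """Symbol-identity map (mouse Gene1 <-> human GENE1)."""
        return cls((s, s.upper()) for s in mouse_symbols)


@dataclass(frozen=True)
class CommonGeneReport:
    """One row of the cross-species comparison table."""

    alteration_class: str
    mouse_total: int
    human_total: int
    common_genes: tuple[str, ...]  # mouse symbols, sorted
    percentage: float = field(init=False)

    def __post_init__(self) -> None:
        pct = (
            round_half_up(100.0 * len(self.common_genes) / self.mouse_total, 1)
            if self.mouse_total
            else 0.0
        )
        object.__setattr__(self, "percentage", pct)


def human_included_genes(
    cohort_alterations: pd.DataFrame,
    alteration_class: str,
    min_tumors: int = 2,
    gene_lengths: Mapping[str, int] | None = None,
) -> AlterationSet:
    """Apply the human inclusion rules to a long-format cohort table.

    * ``CNA``: tumors with cn_state ``amp``; when a ``whole_gene``
      column is present only whole-gene amplifications count (absent
      column means gene-level states, treated as whole-gene).
    * ``CND``: tumors with cn_state ``homdel``; genes must be longer
      than 1000 bp (``gene_lengths`` keyed by the table's symbols;
      genes of unknown length are excluded).
    * ``NSPM_InDel``: rows flagged deleterious.

    A gene is included iff altered in >= ``min_tumors`` tumors.
    """
    if min_tumors < 1:
        raise ValueError("min_tumors must be >= 1")
    df = cohort_alterations
    if alteration_class == "CNA":
        sel = df[df["cn_state"] == "amp"]
        if "whole_gene" in df.columns:
            sel = sel[sel["whole_gene"].astype(bool)]
    elif alteration_class == "CND":
        sel = df[df["cn_state"] == "homdel"]
        if gene_lengths is not None:
            keep = sel["gene"].map(lambda g: gene_lengths.get(g, 0) > MIN_CND_GENE_LENGTH)
            sel = sel[keep]
        else:
            raise ValueError("CND inclusion requires gene_lengths for the >1000 bp rule")
    elif alteration_class == "NSPM_InDel":
        sel = df[df["deleterious_flag"].astype(bool)]
    else:
        raise ValueError(f"unknown alteration class {alteration_class!r}")
    genes = {
        str(gene): frozenset(grp["tumor_id"].astype(str))
        for gene, grp in sel.groupby("gene", sort=True)
    }
    genes = {g: t for g, t in genes.items() if len(t) >= min_tumors}
    return AlterationSet("human", alteration_class, genes)


def mouse_alteration_set(
    gene_records: pd.DataFrame,
    alteration_class: str,
    min_tumors: int = 1,
) -> AlterationSet:
    """Build the mouse inventory from pipeline gene-level outputs.

    ``gene_records`` is either the gene-CNV table (columns ``gene,
    tumor_id, cnv_class``) or a classified mutation table (columns
    ``gene, tumor_id, deleterious``).  The default recurrence threshold
    is one tumor: the two-or-more rule exists to tame the sheer number
    of human CNV genes and is not applied to the mouse side.
    """
    if alteration_class in ("CNA", "CND"):
        sel = gene_records[gene_records["cnv_class"] == alteration_class]
    elif alteration_class == "NSPM_InDel":
        sel = gene_records[gene_records["deleterious"].astype(bool)]
    else:
        raise ValueError(f"unknown alteration class {alteration_class!r}")
    genes = {
        str(gene): frozenset(grp["tumor_id"].astype(str))
        for gene, grp in sel.groupby("gene", sort=True)
    }
    genes = {g: t for g, t in genes.items() if len(t) >= min_tumors}
    return AlterationSet("mouse", alteration_class, genes)


def common_genes(
    mouse_set: AlterationSet,
    human_set: AlterationSet,
    ortholog_map: OrthologMap,
) -> CommonGeneReport:
    """Intersect mouse and human inventories through the ortholog map.

    The percentage is ``100 * |common| / mouse_total`` rounded half-up
    to one decimal.  Mouse genes without an ortholog stay in
    ``mouse_total`` but can never be common.
    """
    if mouse_set.alteration_class != human_set.alteration_class:
        raise ValueError(
            f"alteration classes differ: {mouse_set.alteration_class!r} vs "
            f"{human_set.alteration_class!r}"
        )
    human_genes = {OrthologMap.canonical_human(g) for g in human_set.genes}
    common = sorted(
        m
        for m in mouse_set.genes
        if (h := ortholog_map.to_human(m)) is not None and h in human_genes
    )
    return CommonGeneReport(
        alteration_class=mouse_set.alteration_class,
        mouse_total=len(mouse_set.genes),
        human_total=len(human_set.genes),
        common_genes=tuple(common),
    )


def frequency_table(alteration_set: AlterationSet, n_tumors: int) -> pd.DataFrame:
    """Per-gene alteration frequency as a percentage of the cohort.

    Genes with empty tumor sets are excluded.  Columns: ``gene,
    n_altered, percent`` (half-up, one decimal).
    """
    if n_tumors < 1:
        raise ValueError("n_tumors must be >= 1")
    rows = [
        {
            "gene": gene,
            "n_altered": len(tumors),
            "percent": round_half_up(100.0 * len(tumors) / n_tumors, 1),
        }
        for gene, tumors in sorted(alteration_set.genes.items())
        if tumors
    ]
    return pd.DataFrame(rows, columns=["gene", "n_altered", "percent"])


def compare_event_rates(
    mouse_per_tumor_counts: Sequence[float],
    human_per_tumor_counts: Sequence[float],
) -> dict[str, float]:
    """Welch two-sample t-test on per-tumor event counts.

    Returns means, SEMs, the t statistic and the two-sided p-value.
    Degenerate zero-variance inputs short-circuit to exact equality
    (p=1 when the constant means agree, p=0 otherwise).
    """
    a = np.asarray(mouse_per_tumor_counts, dtype=float)
    b = np.asarray(human_per_tumor_counts, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both cohorts need >= 2 tumors")
    result = {
        "mouse_mean": float(a.mean()),
        "human_mean": float(b.mean()),
        "mouse_sem": float(a.std(ddof=1) / np.sqrt(len(a))),
        "human_sem": float(b.std(ddof=1) / np.sqrt(len(b))),
    }
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        equal = a.mean() == b.mean()
        result["t"] = 0.0 if equal else float(np.inf * np.sign(a.mean() - b.mean()))
        result["p"] = 1.0 if equal else 0.0
        return result
    t, p = stats.ttest_ind(a, b, equal_var=False)
    result["t"] = float(t)
    result["p"] = float(p)
    return result


def overrepresentation(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    For a universe of N genes, a set of K and a list of n with overlap
    k, the p-value is the upper hypergeometric tail P(X >= k).  Sets
    overlapping the list in fewer than ``min_overlap`` genes are
    skipped.  q-values are Benjamini-Hochberg across the tested sets.

    Returns columns ``set_name, set_size, overlap, p, q`` sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(gene_list)
    stray = genes - universe
    if stray:
        raise ValueError(f"gene_list members outside universe: {sorted(stray)[:5]}")
    n_universe = len(universe)
    n_list = len(genes)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        overlap = len(genes & members)
        if overlap < min_overlap:
            continue
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(members), n_list))
        rows.append({"set_name": name, "set_size": len(members), "overlap": overlap, "p": p})
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
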