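"""Rule-based genotype classification of breast-tumor profiles.

Each tumor is assigned to one of four categories from the discrete
copy-number states and mutations of four driver genes:

* ``TP53I``  -- TP53 functionally inactivated;
* ``PPAPA``  -- PTEN-PI3K-AKT pathway activated, via PTEN inactivation
  or a PIK3CA (H1047R / E545K) or AKT1 (E17K) hotspot mutation;
* ``PPAPA_TP53I`` -- both predicates hold;
* ``WT``     -- neither holds.

Two readings of "inactivated" are supported.  The default *biallelic*
mode requires both alleles hit (homozygous deletion, heterozygous loss
plus a deleterious mutation, or two distinct deleterious mutations).
The *any_hit* mode treats a single deleterious mutation or homozygous
deletion as sufficient, the dominant-negative reading.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from ._util import round_half_up

__all__ = [
    "CN_STATES",
    "CATEGORIES",
    "DEFAULT_HOTSPOTS",
    "ProfileMutation",
    "TumorProfile",
    "tp53_inactivated",
    "ppapa_active",
    "classify_tumor",
    "cohort_summary",
]

logger = logging.getLogger(__name__)

CN_STATES = ("homdel", "hetloss", "neutral", "gain", "amp")
CATEGORIES = ("WT", "PPAPA", "TP53I", "PPAPA_TP53I")

#: Activating hotspot protein changes treated as pathway-activating by rule.
DEFAULT_HOTSPOTS: dict[str, frozenset[str]] = {
    "PIK3CA": frozenset({"H1047R", "E545K"}),
    "AKT1": frozenset({"E17K"}),
}

_KNOWN_CHANGE = None  # sentinel docs only


class ProfileMutation(NamedTuple):
    gene: str
    protein_change: str
    variant_class: str
    deleterious: bool


@dataclass
class TumorProfile:
    """Gene-level alteration profile of one tumor.

    ``cn_states`` stores only non-neutral genes; lookups default to
    ``neutral``.  ``mutations`` is the tumor's protein-altering (and
    possibly synonymous) mutation list.
    """

    tumor_id: str
    cn_states: dict[str, str] = field(default_factory=dict)
    mutations: list[ProfileMutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for gene, state in self.cn_states.items():
            if state not in CN_STATES:
                raise ValueError(f"unknown cn_state {state!r} for gene {gene!r}")

    def cn_state(self, gene: str) -> str:
        return self.cn_states.get(gene, "neutral")

    def deleterious_mutations(self, gene: str) -> list[ProfileMutation]:
        # synonymous changes can never be functional hits, whatever the flag says
        return [
            m
            for m in self.mutations
            if m.gene == gene and m.deleterious and m.variant_class != "synonymous"
        ]


def _gene_inactivated(profile: TumorProfile, gene: str, mode: str) -> bool:
    state = profile.cn_state(gene)
    hits = profile.deleterious_mutations(gene)
    n_distinct = len({(m.protein_change or i) for i, m in enumerate(hits)})
    if mode == "biallelic":
        return (
            state == "homdel"
            or (state == "hetloss" and n_distinct >= 1)
            or n_distinct >= 2
        )
    if mode == "any_hit":
        return state == "homdel" or n_distinct >= 1
    raise ValueError(f"unknown mode {mode!r}; expected 'biallelic' or 'any_hit'")


def tp53_inactivated(profile: TumorProfile, mode: str = "biallelic") -> bool:
    """Whether TP53 function is lost under the given inactivation mode."""
    return _gene_inactivated(profile, "TP53", mode)


def ppapa_active(
    profile: TumorProfile,
    mode: str = "biallelic",
    hotspots: Mapping[str, frozenset[str]] | None = None,
) -> bool:
    """Whether the PTEN-PI3K-AKT pathway is activated.

    True on PTEN inactivation (same mode logic as TP53) or a listed
    hotspot protein change in PIK3CA/AKT1.  Synonymous changes never
    count; non-hotspot protein changes in the hotspot genes are ignored
    (logged at debug level).
    """
    hotspots = DEFAULT_HOTSPOTS if hotspots is None else hotspots
    if _gene_inactivated(profile, "PTEN", mode):
        return True
    for m in profile.mutations:
        allowed = hotspots.get(m.gene)
        if allowed is None or m.variant_class == "synonymous":
            continue
        if m.protein_change in allowed:
            return True
        if m.protein_change:
            logger.debug(
                "ignoring non-hotspot change %s:%s in tumor %s",
                m.gene,
                m.protein_change,
                profile.tumor_id,
            )
    return False


def classify_tumor(
    profile: TumorProfile,
    mode: str = "biallelic",
    hotspots: Mapping[str, frozenset[str]] | None = None,
) -> str:
    """Assign one of ``WT, PPAPA, TP53I, PPAPA_TP53I``."""
    p53 = tp53_inactivated(profile, mode)
    ppapa = ppapa_active(profile, mode, hotspots)
    if ppapa and p53:
        return "PPAPA_TP53I"
    if ppapa:
        return "PPAPA"
    if p53:
        return "TP53I"
    return "WT"


def cohort_summary(labels: Sequence[str] | Iterable[str]) -> dict[str, dict[str, float]]:
    """Category counts and half-up one-decimal percentages.

    Returns ``{category: {"count": int, "percent": float}}`` over the
    four categories (zero rows included); percentages are of the cohort
    total.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    unknown = set(labels) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown category labels: {sorted(unknown)}")
    counts = Counter(labels)
    total = len(labels)
    return {
        cat: {
            "count": counts.get(cat, 0),
            "percent": round_half_up(100.0 * counts.get(cat, 0) / total, 1),
        }
        for cat in CATEGORIES
    }
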