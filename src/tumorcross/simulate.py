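"""Synthetic tumor genomics: depth tracks, mutation tables, cohorts.

Everything downstream of raw sequencing is exercised on data made here:
tumor/normal window read counts with a GC bias curve and implanted
copy-number segments, MAF-like mutation tables whose predictor scores
encode a known deleterious fraction, and human-style cohort profiles
drawn from known category frequencies.  Hidden truth (implanted
segments, intended deleterious labels, true categories) is returned
separately from the primary tables so pipelines cannot read it by
accident.

Counts are negative binomial with variance ``mu + dispersion * mu**2``
(Poisson in the ``dispersion = 0`` limit), the standard over-dispersion
model for WGS window depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._util import derive_seed
from .cohort import CATEGORIES, DEFAULT_HOTSPOTS, ProfileMutation, TumorProfile
from .genome import CnvTruth, GenomeModel

__all__ = [
    "CohortSpec",
    "default_gc_curve",
    "simulate_depth",
    "simulate_mutations",
    "simulate_cohort",
]

GcCurve = Callable[[np.ndarray], np.ndarray]


def default_gc_curve(gc: np.ndarray) -> np.ndarray:
    """Quadratic coverage bias peaking at GC 0.45, floored at 0.2."""
    return np.maximum(1.0 - 2.5 * (np.asarray(gc, dtype=float) - 0.45) ** 2, 0.2)


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_depth(
    genome: GenomeModel,
    truth: CnvTruth,
    gc_curve: GcCurve | None = None,
    mean_depth_per_window: float = 1000.0,
    dispersion: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw paired tumor/normal window counts.

    Expected tumor count in window *w* is
    ``mean_depth * gc_curve(GC_w) * (purity * copy_ratio(w) + 1 - purity)``;
    the normal track uses copy ratio 1 everywhere.  Each window's GC
    fraction is drawn once and shared by both tracks.

    Returns
    -------
    (tumor, normal)
        DataFrames with columns ``chrom, start, end, gc_fraction, count``.
    """
    if mean_depth_per_window <= 0:
        raise ValueError("mean_depth_per_window must be > 0")
    truth.validate_against(genome)
    gc_curve = default_gc_curve if gc_curve is None else gc_curve
    rng = np.random.default_rng(seed)

    win = genome.windows()
    gc = np.clip(rng.normal(0.45, 0.06, size=len(win)), 0.25, 0.75).round(4)
    bias = np.asarray(gc_curve(gc), dtype=float)
    if (bias <= 0).any():
        raise ValueError("gc_curve must be positive everywhere")

    mid = ((win["start"] + win["end"]) // 2).to_numpy()
    ratio = truth.copy_ratio_at(win["chrom"].to_numpy(), mid)
    observed_ratio = truth.purity * ratio + (1.0 - truth.purity)

    mu_tumor = mean_depth_per_window * bias * observed_ratio
    mu_normal = mean_depth_per_window * bias
    tumor = win.copy()
    tumor["gc_fraction"] = gc
    tumor["count"] = _draw_counts(rng, mu_tumor, dispersion)
    normal = win.copy()
    normal["gc_fraction"] = gc
    normal["count"] = _draw_counts(rng, mu_normal, dispersion)
    return tumor, normal


# ---------------------------------------------------------------------------
# mutation tables

_BASES = np.array(list("ACGT"))
_AA = list("ARNDCQEGHILKMFPSTWYV")

MUTATION_COLUMNS = [
    "gene",
    "tumor_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "protein_change",
    "variant_class",
    "sift_score",
    "polyphen_score",
    "provean_score",
]


def _random_protein_change(rng: np.random.Generator) -> str:
    a, b = rng.choice(len(_AA), size=2, replace=False)
    return f"{_AA[a]}{int(rng.integers(10, 999))}{_AA[b]}"


def simulate_mutations(
    genome: GenomeModel,
    n_tumors: int,
    mutations_per_tumor: int,
    deleterious_fraction: float,
    seed: int,
    truncating_fraction: float = 0.15,
    synonymous_fraction: float = 0.25,
    tumor_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate a MAF-like table with a controlled deleterious fraction.

    Records intended deleterious are either truncating (nonsense or
    frameshift, no scores) or missense with scores passing all three
    default predictor thresholds; records intended benign fail all
    three (or are synonymous), so any consensus mode recovers the
    intended label exactly.

    Returns the table and a parallel boolean truth array (the sidecar,
    never merged into the table).
    """
    if not 0.0 <= deleterious_fraction <= 1.0:
        raise ValueError("deleterious_fraction must be in [0, 1]")
    if tumor_ids is None:
        tumor_ids = [f"T{t + 1}" for t in range(n_tumors)]
    elif len(tumor_ids) != n_tumors:
        raise ValueError("tumor_ids length must equal n_tumors")
    rng = np.random.default_rng(seed)
    genes = genome.genes
    n = n_tumors * mutations_per_tumor
    gi = rng.integers(0, len(genes), size=n)
    pos = genes["start"].to_numpy()[gi] + (
        rng.random(n) * (genes["end"].to_numpy()[gi] - genes["start"].to_numpy()[gi])
    ).astype(np.int64)
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    deleterious = rng.random(n) < deleterious_fraction

    variant_class = np.empty(n, dtype=object)
    protein_change = np.empty(n, dtype=object)
    sift = np.full(n, np.nan)
    polyphen = np.full(n, np.nan)
    provean = np.full(n, np.nan)
    for k in range(n):
        if deleterious[k]:
            if rng.random() < truncating_fraction:
                variant_class[k] = "nonsense" if rng.random() < 0.5 else "frameshift_indel"
                protein_change[k] = ""
            else:
                variant_class[k] = "missense"
                protein_change[k] = _random_protein_change(rng)
                sift[k] = rng.uniform(0.0, 0.049)
                polyphen[k] = rng.uniform(0.5, 0.999)
                provean[k] = rng.uniform(-8.0, -2.6)
        else:
            if rng.random() < synonymous_fraction:
                variant_class[k] = "synonymous"
                protein_change[k] = ""
            else:
                variant_class[k] = "missense"
                protein_change[k] = _random_protein_change(rng)
                sift[k] = rng.uniform(0.06, 1.0)
                polyphen[k] = rng.uniform(0.0, 0.44)
                provean[k] = rng.uniform(-2.4, 4.0)

    table = pd.DataFrame(
        {
            "gene": genes["name"].to_numpy()[gi],
            "tumor_id": [tumor_ids[t] for t in np.repeat(np.arange(n_tumors), mutations_per_tumor)],
            "chrom": genes["chrom"].to_numpy()[gi],
            "pos": pos,
            "ref": _BASES[ref_i],
            "alt": _BASES[alt_i],
            "protein_change": protein_change,
            "variant_class": variant_class,
            "sift_score": sift,
            "polyphen_score": polyphen,
            "provean_score": provean,
        },
        columns=MUTATION_COLUMNS,
    )
    return table, deleterious


# ---------------------------------------------------------------------------
# human-style cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Mixture weights and noise level for a simulated human cohort."""

    n_tumors: int
    category_probs: tuple[float, float, float, float]  # WT, PPAPA, TP53I, PPAPA_TP53I
    background_gene_alteration_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 1:
            raise ValueError("n_tumors must be >= 1")
        p = self.category_probs
        if len(p) != 4 or any(x < 0 or x > 1 for x in p):
            raise ValueError("category_probs must be four probabilities")
        if abs(sum(p) - 1.0) > 1e-9:
            raise ValueError("category_probs must sum to 1")
        if not 0.0 <= self.background_gene_alteration_rate <= 1.0:
            raise ValueError("background rate must be in [0, 1]")


_DRIVERS = ("TP53", "PTEN", "PIK3CA", "AKT1")


def _inactivate(
    rng: np.random.Generator, profile: TumorProfile, gene: str
) -> None:
    """Apply a biallelic inactivation mechanism (valid under both modes)."""
    mech = rng.choice(["homdel", "hetloss_mut", "two_muts"], p=[0.15, 0.65, 0.20])
    if mech == "homdel":
        profile.cn_states[gene] = "homdel"
    elif mech == "hetloss_mut":
        profile.cn_states[gene] = "hetloss"
        profile.mutations.append(
            ProfileMutation(gene, _random_protein_change(rng), "missense", True)
        )
    else:
        c1 = _random_protein_change(rng)
        c2 = _random_protein_change(rng)
        while c2 == c1:
            c2 = _random_protein_change(rng)
        profile.mutations.append(ProfileMutation(gene, c1, "missense", True))
        profile.mutations.append(
            ProfileMutation(gene, c2, "nonsense" if rng.random() < 0.4 else "missense", True)
        )


def _activate_pathway(rng: np.random.Generator, profile: TumorProfile) -> None:
    mech = rng.choice(
        ["pten", "pik3ca_h1047r", "pik3ca_e545k", "akt1_e17k"],
        p=[0.25, 0.40, 0.20, 0.15],
    )
    if mech == "pten":
        _inactivate(rng, profile, "PTEN")
    elif mech == "pik3ca_h1047r":
        profile.mutations.append(ProfileMutation("PIK3CA", "H1047R", "missense", True))
    elif mech == "pik3ca_e545k":
        profile.mutations.append(ProfileMutation("PIK3CA", "E545K", "missense", True))
    else:
        profile.mutations.append(ProfileMutation("AKT1", "E17K", "missense", True))


def _add_decoys(rng: np.random.Generator, profile: TumorProfile, category: str) -> None:
    """Benign driver-gene noise that no mode may interpret as a hit."""
    # heterozygous TP53 loss alone is not functional inactivation
    if category in ("WT", "PPAPA") and rng.random() < 0.15:
        profile.cn_states.setdefault("TP53", "hetloss")
    # synonymous changes never count
    if rng.random() < 0.10:
        gene = str(rng.choice(_DRIVERS))
        profile.mutations.append(ProfileMutation(gene, "", "synonymous", False))
    # a non-hotspot PIK3CA change is ignored by the hotspot rule
    if category in ("WT", "TP53I") and rng.random() < 0.08:
        change = "E542K"
        if change not in DEFAULT_HOTSPOTS["PIK3CA"]:
            profile.mutations.append(ProfileMutation("PIK3CA", change, "missense", False))


def simulate_cohort(
    spec: CohortSpec, genome: GenomeModel
) -> tuple[list[TumorProfile], list[str]]:
    """Draw tumor profiles from known category frequencies.

    By construction ``classify_tumor(profile)`` returns the tumor's true
    category under either classifier mode: inactivation events always
    hit both alleles, and tumors outside a predicate's category carry
    nothing that could satisfy it.  Background (non-driver) genes are
    altered independently and never influence classification.

    Returns profiles and the parallel true-category list (the sidecar).
    """
    rng = np.random.default_rng(spec.seed)
    background = [
        g.upper() for g in genome.genes["name"].tolist() if g.upper() not in _DRIVERS
    ]
    categories = [
        CATEGORIES[i]
        for i in rng.choice(4, size=spec.n_tumors, p=list(spec.category_probs))
    ]
    profiles: list[TumorProfile] = []
    bg_states = ("amp", "gain", "hetloss", "homdel")
    for t, category in enumerate(categories):
        profile = TumorProfile(tumor_id=f"H{t + 1}")
        if category in ("TP53I", "PPAPA_TP53I"):
            _inactivate(rng, profile, "TP53")
        if category in ("PPAPA", "PPAPA_TP53I"):
            _activate_pathway(rng, profile)
        _add_decoys(rng, profile, category)
        if background and spec.background_gene_alteration_rate > 0:
            hit = np.where(rng.random(len(background)) < spec.background_gene_alteration_rate)[0]
            for bi in hit:
                gene = background[bi]
                if rng.random() < 0.6:
                    profile.cn_states[gene] = str(rng.choice(bg_states))
                else:
                    deleterious = bool(rng.random() < 0.5)
                    profile.mutations.append(
                        ProfileMutation(
                            gene,
                            _random_protein_change(rng),
                            "missense",
                            deleterious,
                        )
                    )
        profiles.append(profile)
    return profiles, categories


def cohort_to_frame(profiles: Sequence[TumorProfile]) -> pd.DataFrame:
    """Long-format cohort table: one row per (tumor, gene) alteration.

    Columns: ``tumor_id, gene, cn_state, protein_change, variant_class,
    deleterious_flag``.  CN rows carry empty mutation fields and vice
    versa; genes with neither are omitted.  A tumor with no alterations
    at all still contributes one empty-gene placeholder row so cohort
    membership survives the round trip.
    """
    rows = []
    for p in profiles:
        for gene, state in sorted(p.cn_states.items()):
            rows.append((p.tumor_id, gene, state, "", "", False))
        for m in p.mutations:
            rows.append((p.tumor_id, m.gene, "", m.protein_change, m.variant_class, m.deleterious))
        if not p.cn_states and not p.mutations:
            rows.append((p.tumor_id, "", "", "", "", False))
    return pd.DataFrame(
        rows,
        columns=["tumor_id", "gene", "cn_state", "protein_change", "variant_class", "deleterious_flag"],
    )


def frame_to_cohort(frame: pd.DataFrame) -> list[TumorProfile]:
    """Inverse of :func:`cohort_to_frame` (CN rows must be unique per gene)."""
    profiles = []
    for tumor_id, grp in frame.groupby("tumor_id", sort=False):
        grp = grp[grp["gene"].astype(str) != ""]  # drop placeholder rows
        cn_rows = grp[grp["cn_state"].astype(str) != ""]
        if cn_rows.duplicated(subset=["gene"]).any():
            gene = cn_rows.loc[cn_rows.duplicated(subset=["gene"]), "gene"].iloc[0]
            raise ValueError(f"duplicate CN row for tumor {tumor_id!r}, gene {gene!r}")
        profile = TumorProfile(
            tumor_id=str(tumor_id),
            cn_states={r.gene: r.cn_state for r in cn_rows.itertuples()},
            mutations=[
                ProfileMutation(r.gene, r.protein_change, r.variant_class, bool(r.deleterious_flag))
                for r in grp[grp["cn_state"].astype(str) == ""].itertuples()
            ],
        )
        profiles.append(profile)
    return profiles
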