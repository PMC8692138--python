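"""Intersect mouse and human altered-gene inventories per alteration class.

Reconstructs the published worked example: per class, the mouse tumors
contribute a gene inventory (360 mutated / 435 amplified / 450 deleted
genes) of which a known number is also altered in the human cohort.
The report computes 100 * |common| / mouse_total after ortholog
mapping -- the headline cross-species percentage.
"""

from tumorcross import AlterationSet, OrthologMap, common_genes

published = {
    "NSPM_InDel": (360, 80),
    "CNA": (435, 330),
    "CND": (450, 123),
}

print(f"{'class':>11} {'mouse':>6} {'common':>7} {'percent':>8}")
for cls, (n_mouse, n_common) in published.items():
    mouse = AlterationSet("mouse", cls, {f"Mg{i}": frozenset({"M1"}) for i in range(n_mouse)})
    human_genes = {f"MG{i}": frozenset({"H1", "H2"}) for i in range(n_common)}
    human_genes.update({f"HONLY{i}": frozenset({"H1", "H2"}) for i in range(50)})
    human = AlterationSet("human", cls, human_genes)
    orthologs = OrthologMap([(f"Mg{i}", f"MG{i}") for i in range(n_mouse)])
    report = common_genes(mouse, human, orthologs)
    print(f"{cls:>11} {report.mouse_total:>6} {len(report.common_genes):>7} "
          f"{report.percentage:>7}%")

print(
    "\nExpected: 22.2% of mutated, 75.9% of amplified and 27.3% of deleted "
    "mouse genes are shared with the human cohort; mouse genes without an "
    "ortholog stay in the denominator."
)
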