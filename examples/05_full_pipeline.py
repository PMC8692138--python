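"""Run the whole chain end to end on synthetic data.

simulate (genome, depth, mutations, cohort) -> CNV calling -> mutation
filtering -> genotype classification -> cross-species comparison ->
over-representation, writing a report directory plus summary.json.
"""

import json
import sys
from pathlib import Path

from tumorcross.io import RunConfig
from tumorcross.pipeline import run_all

outdir = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("pipeline_demo")
config = RunConfig(seed=1, n_mouse_tumors=4, n_human_tumors=150,
                   n_permutations=200, n_genes=80)
summary = run_all(config, outdir)

print(f"report directory: {outdir}/  (SEG files, MAF, cohort TSV, summary.json)\n")
print("per-tumor event means (mouse arm):")
for metric, row in summary["per_tumor_means"].items():
    print(f"  {metric:>22}: {row['mean_1dp']} +/- {row['sem']:.1f}")
print("\nhuman cohort categories:")
for cat, row in summary["category_fractions"].items():
    print(f"  {cat:>12}: {row['count']:>4} ({row['percent']}%)")
print("\ncross-species common genes:")
for cls, rep in summary["common_gene_reports"].items():
    print(f"  {cls:>11}: {rep['n_common']}/{rep['mouse_total']} mouse genes "
          f"({rep['percentage']}%) also altered in the human cohort")
t = summary["deleterious_event_rate_test"]
print(f"\nWelch t-test, deleterious events per tumor (mouse vs human): "
      f"t = {t['t']:.2f}, p = {t['p']:.2g}")
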