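"""Longitudinal statistics: mixed-effects models, per-timepoint group tests,
brain-behavior correlations.

Fits amplitude and shape per network with the mixed model
y = b0 + b1*group + b2*age + b3*group*age + subject intercept, refits each
group separately where the interaction is significant, runs per-timepoint
Kruskal-Wallis tests with BH-FDR (significant < 0.05, tendency < 0.1), and
correlates metrics with the behavioral table (Spearman, p < 0.05).
"""

import shutil

from _common import RESULTS, WORKDIR, study
from rsnlong.pipeline import run_pipeline

design, truth, cfg = study()
man = run_pipeline(WORKDIR, design, truth, cfg, upto="stats")
RESULTS.mkdir(exist_ok=True)
for name in ("lme.tsv", "group_tests.tsv", "behavior_correlations.tsv"):
    shutil.copy(WORKDIR / "tables" / name, RESULTS / name)

import pandas as pd  # noqa: E402

lme = pd.read_csv(RESULTS / "lme.tsv", sep="\t")
full = lme[lme.model == "all_subjects"]
print("group x age interaction p-values (full model):")
print(full.pivot_table(index="network", columns="metric",
                       values="p_group_x_age").round(4))
gt = pd.read_csv(RESULTS / "group_tests.tsv", sep="\t")
flagged = gt[gt.tier != "none"]
print(f"\nper-timepoint group differences flagged: {len(flagged)}")
if not flagged.empty:
    print(flagged[["timepoint", "network", "metric", "p_fdr", "tier"]]
          .to_string(index=False))
beh = pd.read_csv(RESULTS / "behavior_correlations.tsv", sep="\t")
sig = beh[beh.significant]
print(f"\nsignificant brain-behavior correlations: {len(sig)} "
      f"of {len(beh)} strata")
print(sig.groupby(["network", "measure"]).size())
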