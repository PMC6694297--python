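"""Simulate the reference longitudinal cohort.

Two groups (wild-type, transgenic) scanned at five timepoints between ~5 and
~18 months, 84 acquisitions in total, with six planted networks: two
"somatosensory" effect networks (WT amplitude rising with age, Tg falling,
group x age interaction -0.03/month), one stable "sensorimotor" null
network, and three temporally-coupled blobs forming a default-mode-like
parent.  Writes NIfTI volumes and motion tables under scratch/pipeline/raw
and copies the cohort and behavior tables into results/.
"""

import shutil

from _common import RESULTS, WORKDIR, study
from rsnlong.pipeline import run_pipeline

design, truth, cfg = study()
man = run_pipeline(WORKDIR, design, truth, cfg, upto="simulate")

RESULTS.mkdir(exist_ok=True)
for name in ("cohort.tsv", "behavior.tsv"):
    shutil.copy(WORKDIR / "raw" / name, RESULTS / name)

import pandas as pd  # noqa: E402

cohort = pd.read_csv(RESULTS / "cohort.tsv", sep="\t")
print(f"simulated {len(cohort)} acquisitions "
      f"({(cohort.group == 0).sum()} WT, {(cohort.group == 1).sum()} Tg) "
      f"on grid {design.grid_dims}, {design.n_volumes} volumes, TR {design.tr}s")
print(cohort.groupby(['timepoint', 'group']).size().unstack())
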