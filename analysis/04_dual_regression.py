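"""Dual regression of every acquisition against the group maps.

Stage 1 gives each subject's per-network time-series (whose SD is the
amplitude metric), stage 2 the subject-specific spatial z-maps (whose
suprathreshold mean is the shape metric).  Outputs land under
scratch/pipeline/dualreg.
"""

from _common import WORKDIR, study
from rsnlong.pipeline import run_pipeline

design, truth, cfg = study()
man = run_pipeline(WORKDIR, design, truth, cfg, upto="dualreg")
n = len(list((WORKDIR / "dualreg").glob("*_timeseries.tsv")))
print(f"dual regression done for {n} acquisitions "
      f"(variance-normalized stage 2: {cfg.stage2_variance_normalize})")
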