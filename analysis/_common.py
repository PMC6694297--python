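"""Shared setup for the numbered analysis drivers: the reference desk-scale
study conditions and the on-disk workspace layout."""

from pathlib import Path

from rsnlong.cohort import CohortDesign, default_ground_truth
from rsnlong.config import PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
WORKDIR = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def study():
    """Design, ground truth and config of the reference synthetic study."""
    design = CohortDesign()
    cfg = PipelineConfig()
    truth = default_ground_truth(design, beta3=cfg.synthetic.interaction_beta3)
    return design, truth, cfg
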