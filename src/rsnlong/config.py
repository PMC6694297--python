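"""Pipeline configuration.

Every protocol constant with a stated reference value is a default here:
five discarded volumes, 1.2 mm FWHM smoothing, 0.01-0.1 Hz band, model
orders 30 and 150, z threshold 2.3, subnetwork matching r > 0.4 with > 250
shared voxels, significance 0.05 and tendency 0.1.  Desk-scale runs override
the model orders through the ``synthetic`` block (the full orders exceed the
rank of a small phantom).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "SyntheticBlock"]


@dataclass
class SyntheticBlock:
    """Desk-scale synthetic experiment settings."""

    enabled: bool = True
    order_low: int = 4     # desk-scale analog of the order-30 decomposition
    order_high: int = 8    # desk-scale analog of the order-150 decomposition
    behavior_noise_sd: float = 0.3
    interaction_beta3: float = -0.03  # planted group x age slope, per month


@dataclass
class PipelineConfig:
    # preprocessing
    n_discard: int = 5
    fwhm_mm: float = 1.2
    detrend_order: int = 1
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    # ICA
    order30: int = 30
    order150: int = 150
    ica_seed: int = 0
    z_thresh: float = 2.3
    variance_normalize_blocks: bool = True
    # subnetwork matching
    r_thresh: float = 0.4
    overlap_thresh: int = 250
    # statistics
    alpha: float = 0.05
    tendency: float = 0.1
    fisher_z_connectivity: bool = True
    stage2_variance_normalize: bool = False
    synthetic: SyntheticBlock = field(default_factory=SyntheticBlock)

    @property
    def band(self) -> tuple[float, float]:
        return (self.band_low_hz, self.band_high_hz)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        syn = d.pop("synthetic", None)
        cfg = cls(**d)
        if syn:
            cfg.synthetic = SyntheticBlock(**syn)
        return cfg
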