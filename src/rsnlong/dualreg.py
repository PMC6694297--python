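"""Two-stage dual regression: subject time-series and subject spatial maps.

Stage 1 regresses each volume's voxel vector on the group spatial maps
(plus intercept), giving one time-course per network per acquisition.
Stage 2 regresses each voxel's time-series on those time-courses (plus
intercept), giving subject-specific beta maps, which are standardized over
mask voxels into z-maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["SubjectNetworkSet", "stage1", "stage2", "dual_regress"]


@dataclass
class SubjectNetworkSet:
    """Per-acquisition dual-regression output."""

    timeseries: np.ndarray  # (T, K), signal units
    beta_maps: np.ndarray   # (K, V)
    z_maps: np.ndarray      # (K, V), spatially standardized
    subject_id: str = ""
    timepoint: str = ""


def stage1(data: np.ndarray, maps_z: np.ndarray) -> np.ndarray:
    """Spatial regression: ``(V, T)`` data against ``(K, V)`` group maps.

    For each volume, the K values are the multiple-OLS coefficients of the
    group maps plus an intercept fitted to that volume's voxel vector.
    Returns ``(T, K)``.
    """
    data = np.asarray(data, dtype=float)
    maps = np.asarray(maps_z, dtype=float)
    v, _ = data.shape
    if maps.shape[1] != v:
        raise ValueError("maps voxel count does not match data")
    if not np.all((maps != 0).sum(axis=1) >= 1):
        raise ValueError("every map must cover at least one voxel")
    design = np.column_stack([maps.T, np.ones(v)])
    cond = np.linalg.cond(design)
    if cond > 1e8:
        warnings.warn(f"stage-1 design is ill conditioned (cond={cond:.3g})")
    coef, *_ = np.linalg.lstsq(design, data, rcond=None)
    return coef[:-1].T


def stage2(
    data: np.ndarray,
    timeseries: np.ndarray,
    variance_normalize: bool = False,
    z_mode: str = "spatial",
) -> tuple[np.ndarray, np.ndarray]:
    """Temporal regression: each voxel's series on the stage-1 time-courses.

    Returns ``(beta_maps, z_maps)`` of shape ``(K, V)``.  With the default
    ``z_mode="spatial"`` the z-maps standardize each network's beta map over
    mask voxels; ``z_mode="tstat"`` instead converts each voxel's
    coefficient t-statistic to a normal z-score (per-voxel inference
    convention).  With ``variance_normalize`` the time-courses are scaled to
    unit SD before the fit (the design-normalization convention), which
    rescales betas but neither flavour of z-map.  Zero-variance time-courses
    yield zeroed, flagged maps.
    """
    data = np.asarray(data, dtype=float)
    ts = np.asarray(timeseries, dtype=float)
    t, k = ts.shape
    if data.shape[1] != t:
        raise ValueError("timeseries rows must match data time points")
    sd = ts.std(axis=0, ddof=1)
    dead = sd == 0
    if dead.any():
        warnings.warn(f"zero-variance stage-1 time-series for components "
                      f"{np.where(dead)[0].tolist()}; maps zeroed")
    ts_fit = ts.copy()
    if variance_normalize:
        ts_fit[:, ~dead] /= sd[~dead]
    ts_fit[:, dead] = 0.0
    design = np.column_stack([ts_fit, np.ones(t)])
    keep = np.concatenate([~dead, [True]])
    coef = np.zeros((k + 1, data.shape[0]))
    sol, *_ = np.linalg.lstsq(design[:, keep], data.T, rcond=None)
    coef[keep] = sol
    beta_maps = coef[:-1]
    if z_mode == "spatial":
        mu = beta_maps.mean(axis=1, keepdims=True)
        s = beta_maps.std(axis=1, ddof=1, keepdims=True)
        s[s == 0] = 1.0
        z_maps = (beta_maps - mu) / s
    elif z_mode == "tstat":
        from scipy import stats as sps
        dsub = design[:, keep]
        dof = max(t - dsub.shape[1], 1)
        resid = data.T - dsub @ coef[keep]
        mse = (resid ** 2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(dsub.T @ dsub)
        se = np.sqrt(np.outer(np.diag(xtx_inv)[:-1], mse))
        se_full = np.ones_like(beta_maps)
        se_full[~dead] = se[: int((~dead).sum())]
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se_full > 0, beta_maps / se_full, 0.0)
        # t -> z through matched tail probabilities, sign preserved
        z_maps = sps.norm.isf(np.clip(sps.t.sf(np.abs(tval), dof), 1e-300, 1.0))
        z_maps = z_maps * np.sign(tval)
    else:
        raise ValueError(f"unknown z_mode {z_mode!r}")
    z_maps[dead] = 0.0
    beta_maps = beta_maps.copy()
    beta_maps[dead] = 0.0
    return beta_maps, z_maps


def dual_regress(
    data: np.ndarray,
    maps_z: np.ndarray,
    variance_normalize: bool = False,
    subject_id: str = "",
    timepoint: str = "",
) -> SubjectNetworkSet:
    ts = stage1(data, maps_z)
    beta, z = stage2(data, ts, variance_normalize=variance_normalize)
    return SubjectNetworkSet(timeseries=ts, beta_maps=beta, z_maps=z,
                             subject_id=subject_id, timepoint=timepoint)
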