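"""Temporal-concatenation group spatial ICA and component labeling.

All cleaned acquisitions are concatenated along time and decomposed at a
fixed model order by PCA followed by spatial FastICA: the sources are
z-scored spatial maps shared by the whole cohort, the mixing matrix holds the
concatenated component time-courses.  The reference protocol uses order 30
for the main networks and order 150 for the subnetwork decomposition; on
desk-scale phantoms the orders are scaled down (see the pipeline config).

Recovered components are labeled against binary template masks by greedy
Dice overlap of their thresholded (|z| > 2.3) maps, an automated surrogate
for anatomical identification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning
from sklearn.utils.extmath import randomized_svd

__all__ = [
    "ComponentSet",
    "ComponentLabel",
    "concatenate",
    "reduce_and_ica",
    "match_templates",
]


@dataclass
class ComponentSet:
    """Group-level ICA result.

    ``maps_z``: (K, V) spatial maps, z-scored over mask voxels (mean 0, SD 1,
    positive skew).  ``mixing``: (sum of T, K) concatenated component
    time-courses, ordered like the input blocks.  ``explained_variance``:
    fraction of total (centred) variance captured by the retained PCA
    subspace.
    """

    maps_z: np.ndarray
    mixing: np.ndarray
    order: int
    seed: int
    block_ranges: list[tuple[int, int]] = field(default_factory=list)
    explained_variance: float = float("nan")

    def block(self, i: int) -> np.ndarray:
        a, b = self.block_ranges[i]
        return self.mixing[a:b]


@dataclass
class ComponentLabel:
    """Component-index -> label assignment with its Dice match score."""

    labels: dict[int, str]
    scores: dict[int, float]

    def component_of(self, label: str) -> int:
        for idx, lab in self.labels.items():
            if lab == label:
                return idx
        raise KeyError(f"no component labeled {label!r}")

    def components_of(self, label: str) -> list[int]:
        return [idx for idx, lab in self.labels.items() if lab == label]


def concatenate(
    matrices: list[np.ndarray],
    subject_ids: list[str] | None = None,
    variance_normalize: bool = True,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Concatenate per-acquisition ``(V, T_i)`` matrices along time.

    Returns the ``(V, sum T_i)`` matrix and the column ranges of each block.
    With ``variance_normalize`` each voxel row of each block is scaled to
    unit SD first, so no single acquisition dominates the decomposition.
    """
    if not matrices:
        raise ValueError("no matrices to concatenate")
    v = matrices[0].shape[0]
    ids = subject_ids or [str(i) for i in range(len(matrices))]
    ranges: list[tuple[int, int]] = []
    blocks: list[np.ndarray] = []
    start = 0
    for m, sid in zip(matrices, ids):
        if m.shape[0] != v:
            raise ValueError(
                f"acquisition {sid!r} has {m.shape[0]} mask voxels, expected {v}; "
                "all subjects must share one mask")
        b = m
        if variance_normalize:
            sd = b.std(axis=1, ddof=1, keepdims=True)
            sd[sd == 0] = 1.0
            b = b / sd
        blocks.append(b)
        ranges.append((start, start + m.shape[1]))
        start += m.shape[1]
    return np.concatenate(blocks, axis=1), ranges


def _spatial_zscore(maps: np.ndarray) -> np.ndarray:
    out = maps - maps.mean(axis=1, keepdims=True)
    return out / out.std(axis=1, ddof=1, keepdims=True)


def reduce_and_ica(
    concat: np.ndarray,
    order: int,
    seed: int = 0,
    block_ranges: list[tuple[int, int]] | None = None,
    max_iter: int = 2000,
    tol: float = 1e-4,
    n_init: int = 5,
) -> ComponentSet:
    """PCA reduction to ``order`` dimensions followed by spatial FastICA.

    The concatenated data ``(V, sum T)`` are voxel-centred, reduced by
    truncated SVD, and the spatial principal directions are unmixed by
    FastICA so the sources are independent spatial maps.  Maps are z-scored,
    their sign fixed to nonnegative skewness, and components ordered by the
    variance of their mixing time-course.  Deterministic given ``seed``.
    """
    v, t_total = concat.shape
    if order < 1 or order > min(v, t_total):
        raise ValueError(f"order {order} must be in [1, min(V={v}, T={t_total})]")
    # keep float32 inputs in float32: halves memory/time on cohort-scale data
    x = np.asarray(concat.T, dtype=np.result_type(concat.dtype, np.float32))

    x = x - x.mean(axis=0, keepdims=True)
    total_var = float((x ** 2).sum())
    u, s, vt = randomized_svd(x, n_components=order, n_oversamples=10,
                              n_iter=4, random_state=seed)
    explained = float((s ** 2).sum()) / total_var if total_var > 0 else 1.0

    if order == 1:
        maps = vt.copy()
        mixing = u * s
    else:
        # FastICA is a fixed-point iteration with local optima whose basins
        # are extremely sensitive to the representation of the whitened
        # data: restart on randomly rotated copies of the reduced basis
        # (ICA is rotation-equivariant; the mixing rotates back exactly)
        # and keep the converged solution with the highest contrast — the
        # logcosh negentropy proxy FastICA maximizes.
        from scipy.stats import special_ortho_group

        y = np.asarray(vt.T, dtype=np.float64)
        e_g_gauss = 0.3745672075
        best = None
        best_score = -np.inf
        last_exc: Exception | None = None
        for attempt in range(n_init):
            if attempt == 0:
                rot = np.eye(order)
            else:
                rot = special_ortho_group.rvs(
                    order, random_state=seed + attempt * 1000003)
            ica = FastICA(n_components=order, whiten="unit-variance",
                          random_state=seed + attempt * 1000003,
                          max_iter=max_iter, tol=tol)
            with warnings.catch_warnings():
                warnings.filterwarnings("error", category=ConvergenceWarning)
                try:
                    sources = ica.fit_transform(y @ rot)
                except ConvergenceWarning as exc:
                    last_exc = exc
                    continue
            su = sources / sources.std(axis=0, ddof=0, keepdims=True)
            score = float(
                ((np.log(np.cosh(su)).mean(axis=0) - e_g_gauss) ** 2).sum())
            if score > best_score:
                best_score = score
                best = (sources, rot @ ica.mixing_)
        if best is None:
            raise RuntimeError(
                f"FastICA did not converge within {max_iter} iterations at "
                f"tol={tol} ({n_init} restarts): {last_exc}") from last_exc
        sources, mixing_ica = best
        maps = sources.T  # (K, V)
        # vt ~= mixing_ica @ sources.T + mean; fold through the SVD factors
        mixing = (u * s) @ mixing_ica  # (sum T, K)

    maps = _spatial_zscore(maps)
    skew = sps.skew(maps, axis=1)
    flip = np.where(skew < 0, -1.0, 1.0)
    maps *= flip[:, None]
    mixing = mixing * flip[None, :]
    order_idx = np.argsort(mixing.var(axis=0))[::-1]
    maps = maps[order_idx]
    mixing = mixing[:, order_idx]
    return ComponentSet(maps_z=maps, mixing=mixing, order=order, seed=seed,
                        block_ranges=list(block_ranges or []),
                        explained_variance=explained)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def match_templates(
    cs: ComponentSet,
    templates: dict[str, np.ndarray],
    z_thresh: float = 2.3,
    capacity: dict[str, int] | None = None,
) -> ComponentLabel:
    """Greedy Dice labeling of components against binary templates.

    Every (component, template) Dice score between the thresholded map
    (|z| > ``z_thresh``) and the template mask is computed; pairs are
    assigned in descending score order (ties broken toward the lower
    component index), each label accepting up to ``capacity[label]``
    components (default 1).  Components with no assignment are unlabeled.
    """
    cap = {lab: 1 for lab in templates}
    if capacity:
        cap.update(capacity)
    thresholded: dict[int, np.ndarray] = {}
    for k in range(cs.order):
        thr = np.abs(cs.maps_z[k]) > z_thresh
        if not thr.any():
            warnings.warn(f"component {k} has no |z| > {z_thresh} voxels; skipped")
            continue
        thresholded[k] = thr
    pairs = []
    for k, thr in thresholded.items():
        for lab, tpl in templates.items():
            pairs.append((_dice(thr, np.asarray(tpl, dtype=bool)), k, lab))
    pairs.sort(key=lambda p: (-p[0], p[1]))
    labels: dict[int, str] = {}
    scores: dict[int, float] = {}
    used: dict[str, int] = {lab: 0 for lab in templates}
    for score, k, lab in pairs:
        if score <= 0 or k in labels or used[lab] >= cap[lab]:
            continue
        labels[k] = lab
        scores[k] = float(score)
        used[lab] += 1
    return ComponentLabel(labels=labels, scores=scores)
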