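"""Synthetic longitudinal rs-fMRI cohort with known ground truth.

Generates a two-group (wild-type / transgenic), five-timepoint cohort of 4D
volume time-series in which a set of spatial networks is planted with known,
group-dependent linear amplitude-vs-age trajectories, subject-level random
offsets, band-limited source time courses, motion-coupled nuisance signal and
additive Gaussian noise.  Every downstream stage of the pipeline (group ICA,
dual regression, network metrics, mixed-effects statistics) therefore has a
recoverable ground-truth answer.

The voxel signal model for one acquisition is

    x(v, t) = sum_k a_k * m_k(v) * c_k(t) + motion leakage + noise

with per-network amplitude ``a_k = intercept[g, k] + slope[g, k] * age + b_s``
where ``g`` is the genotype group and ``b_s`` a subject random offset shared
across that subject's timepoints — the same structure the longitudinal
mixed-effects model fits downstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "WT",
    "TG",
    "CohortDesign",
    "BlobSpec",
    "GroundTruth",
    "AcquisitionRecord",
    "make_network_maps",
    "make_timecourses",
    "synthesize_subject",
    "simulate_cohort_records",
    "simulate_cohort",
    "simulate_behavior",
    "default_ground_truth",
]

WT = 0
TG = 1

GROUP_NAMES = ("WT", "Tg")

#: Group sizes and ages (months, mean and SD) of the reference longitudinal
#: design: wild-type and transgenic rats scanned at five timepoints between
#: 5 and 18 months of age.  Rows are groups (WT, Tg), columns timepoints.
DEFAULT_GROUP_SIZES = ((6, 10, 9, 9, 9), (8, 9, 9, 9, 6))
DEFAULT_AGE_MEANS = ((5.3, 8.1, 11.3, 14.8, 17.8), (6.3, 8.5, 11.3, 14.9, 18.1))
DEFAULT_AGE_SDS = ((0.3, 0.3, 0.1, 0.3, 0.3), (1.0, 0.3, 0.1, 0.2, 0.5))


@dataclass(frozen=True)
class CohortDesign:
    """Sampling design of a longitudinal cohort.

    ``group_sizes[g][p]`` is the number of subjects of group ``g`` scanned at
    timepoint ``p``; subjects are indexed consistently across timepoints, so a
    group with sizes (6, 10, ...) has 10 subjects of which the last four miss
    the first scan.  Ages are in months.
    """

    group_sizes: tuple[tuple[int, ...], ...] = DEFAULT_GROUP_SIZES
    age_means: tuple[tuple[float, ...], ...] = DEFAULT_AGE_MEANS
    age_sds: tuple[tuple[float, ...], ...] = DEFAULT_AGE_SDS
    grid_dims: tuple[int, int, int] = (26, 26, 16)
    n_volumes: int = 120
    tr: float = 2.0
    voxel_size_mm: float = 1.0
    seed: int = 2019

    def __post_init__(self) -> None:
        if len(self.group_sizes) != 2:
            raise ValueError("exactly two groups (WT, Tg) are supported")
        n_tp = len(self.group_sizes[0])
        for g in range(2):
            if len(self.group_sizes[g]) != n_tp or len(self.age_means[g]) != n_tp:
                raise ValueError("group_sizes and age_means must agree in length")
            if any(n < 1 for n in self.group_sizes[g]):
                raise ValueError("every group/timepoint must have >= 1 subject")
            if any(np.diff(self.age_means[g]) <= 0):
                raise ValueError("timepoint mean ages must be strictly increasing")
            if any(sd < 0 for sd in self.age_sds[g]):
                raise ValueError("age jitter SDs must be nonnegative")
        if self.n_volumes < 20:
            raise ValueError("n_volumes must be >= 20")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def n_timepoints(self) -> int:
        return len(self.group_sizes[0])

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(f"t{p + 1}" for p in range(self.n_timepoints))

    @property
    def n_subjects(self) -> tuple[int, int]:
        return tuple(max(sizes) for sizes in self.group_sizes)

    @property
    def n_acquisitions(self) -> int:
        return int(sum(sum(sizes) for sizes in self.group_sizes))

    def full_protocol(self) -> "CohortDesign":
        """The full-size acquisition protocol (64 x 64 x 34 grid, 600 volumes,
        0.4 mm in-plane voxels) instead of the desk-scale default."""
        return replace(self, grid_dims=(64, 64, 34), n_volumes=600,
                       voxel_size_mm=0.4)


@dataclass(frozen=True)
class BlobSpec:
    """Geometry of the planted network blobs.

    Blobs are flat-topped super-Gaussian ellipsoids
    ``exp(-(d/r)**exponent)`` with ``d`` the (anisotropy-scaled) distance to
    the centre; large exponents give near-binary maps whose z-scored values
    sit well above the downstream ``z > 2.3`` cut.
    """

    radius_xy: float = 4.7
    radius_z: float = 4.0
    exponent: int = 14
    support_level: float = 0.05
    min_support: int = 300
    min_separation: float = 8.0
    max_tries: int = 2000
    restarts: int = 30


def make_network_maps(
    grid_dims: tuple[int, int, int],
    mask: np.ndarray,
    n_networks: int,
    blob_spec: BlobSpec | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Place ``n_networks`` spatially distinct blob maps inside a mask.

    Returns an ``(n_networks, V)`` array over the mask voxels, each map
    nonnegative, peak-normalized to 1 and supported on at least
    ``blob_spec.min_support`` mask voxels; pairwise spatial correlation of the
    maps is below 0.5 by construction (separated centres).
    """
    if n_networks < 1:
        raise ValueError("n_networks must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(grid_dims):
        raise ValueError("mask shape does not match grid_dims")
    if not mask.any():
        raise ValueError("mask is empty")
    spec = blob_spec or BlobSpec()
    rng = np.random.default_rng(seed)

    nx, ny, nz = grid_dims
    xi, yi, zi = np.indices(grid_dims).astype(float)
    # support radius of the profile at the support level
    s_xy = spec.radius_xy * (-np.log(spec.support_level)) ** (1.0 / spec.exponent)
    s_z = spec.radius_z * (-np.log(spec.support_level)) ** (1.0 / spec.exponent)

    # candidate centres on a jittered half-voxel lattice inside the margins,
    # visited in seeded random order and accepted greedily under the
    # minimum-separation constraint: deterministic and robust in tight grids
    def axis_candidates(n: int, margin: float) -> np.ndarray:
        lo, hi = margin, n - 1 - margin
        if lo >= hi:
            return np.array([(n - 1) / 2.0])
        return np.arange(np.ceil(lo * 2) / 2, hi + 1e-9, 0.5)

    cand = np.array(np.meshgrid(
        axis_candidates(nx, s_xy), axis_candidates(ny, s_xy),
        axis_candidates(nz, s_z), indexing="ij")).reshape(3, -1).T
    scale = np.array([1.0, 1.0, spec.radius_xy / spec.radius_z])

    centers: list[np.ndarray] = []
    maps3: list[np.ndarray] = []
    for _restart in range(spec.restarts):
        centers, maps3 = [], []
        order = rng.permutation(len(cand))
        for idx in order[: spec.max_tries]:
            if len(centers) == n_networks:
                break
            c = cand[idx] + rng.uniform(-0.25, 0.25, size=3)
            if centers:
                d = np.linalg.norm((np.array(centers) - c) * scale, axis=1)
                if d.min() < spec.min_separation:
                    continue
            d = np.sqrt(((xi - c[0]) / spec.radius_xy) ** 2
                        + ((yi - c[1]) / spec.radius_xy) ** 2
                        + ((zi - c[2]) / spec.radius_z) ** 2)
            blob = np.exp(-np.clip(d, 0, 3.0) ** spec.exponent)
            blob[~mask] = 0.0
            support = int((blob > spec.support_level).sum())
            if support < spec.min_support:
                continue
            centers.append(c)
            maps3.append(blob)
        if len(centers) == n_networks:
            break
    if len(centers) < n_networks:
        raise ValueError(
            f"could not place {n_networks} blobs of support radius "
            f"~{s_xy:.1f} voxels (min separation {spec.min_separation}) in "
            f"grid {grid_dims}: only {len(centers)} fit; mask too small for "
            "the requested number/size of networks")

    maps = np.stack([b[mask] for b in maps3])
    maps /= maps.max(axis=1, keepdims=True)
    if n_networks > 1:
        r = np.corrcoef(maps)
        off = np.abs(r[~np.eye(n_networks, dtype=bool)])
        if off.max() >= 0.5:  # pragma: no cover - construction guarantees this
            raise ValueError("placed maps violate the pairwise r < 0.5 contract")
    return maps


def make_timecourses(
    n_volumes: int,
    tr: float,
    band: tuple[float, float],
    seed: int | np.random.Generator = 0,
    n_courses: int = 1,
) -> np.ndarray:
    """Band-limited unit-SD source time courses via Fourier synthesis.

    Random complex Gaussian coefficients are placed on the DFT bins inside
    ``band`` (Hz) and inverse-transformed, so essentially all spectral power
    lies inside the band and the sources survive the downstream 0.01-0.1 Hz
    band-pass stage.  Returns ``(n_courses, n_volumes)``.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0.0 < low < high <= nyquist):
        raise ValueError(
            f"band ({low}, {high}) Hz must lie inside (0, Nyquist={nyquist:.4g}) Hz"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_volumes, d=tr)
    in_band = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not in_band.any():
        raise ValueError("no DFT bins inside the requested band; series too short")
    coeffs = np.zeros((n_courses, freqs.size), dtype=complex)
    n_bins = int(in_band.sum())
    coeffs[:, in_band] = rng.standard_normal((n_courses, n_bins)) \
        + 1j * rng.standard_normal((n_courses, n_bins))
    courses = np.fft.irfft(coeffs, n=n_volumes, axis=1)
    courses -= courses.mean(axis=1, keepdims=True)
    courses /= courses.std(axis=1, ddof=1, keepdims=True)
    return courses


@dataclass
class GroundTruth:
    """Generative parameters of a synthetic cohort.

    ``network_maps`` is ``(K, V)`` over mask voxels.  ``amp_intercept`` and
    ``amp_slope`` are ``(2, K)`` (group x network), in signal units and signal
    units per month.  ``dmn_subnets`` lists the network indices that form the
    default-mode-like parent network: their source courses share a common
    latent course with loading ``dmn_course_weight``, so a low-order
    decomposition merges them into one parent component while a high-order
    decomposition resolves them individually.
    """

    network_maps: np.ndarray
    network_names: tuple[str, ...]
    mask: np.ndarray
    amp_intercept: np.ndarray
    amp_slope: np.ndarray
    subject_sd: float = 0.08
    noise_sd: float = 3.0
    motion_coupling: float = 0.2
    cognition_coupling: np.ndarray = field(default_factory=lambda: np.zeros(0))
    band: tuple[float, float] = (0.01, 0.1)
    dmn_subnets: tuple[int, ...] = ()
    dmn_course_weight: float = float(np.sqrt(0.5))
    motion_patterns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.network_maps = np.asarray(self.network_maps, dtype=float)
        self.amp_intercept = np.asarray(self.amp_intercept, dtype=float)
        self.amp_slope = np.asarray(self.amp_slope, dtype=float)
        k, v = self.network_maps.shape
        if len(self.network_names) != k:
            raise ValueError("network_names must match number of maps")
        if self.amp_intercept.shape != (2, k) or self.amp_slope.shape != (2, k):
            raise ValueError("amplitude parameters must have shape (2, K)")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise_sd and subject_sd must be nonnegative")
        if np.asarray(self.cognition_coupling).size == 0:
            self.cognition_coupling = np.zeros(k)
        self.cognition_coupling = np.asarray(self.cognition_coupling, dtype=float)
        if self.cognition_coupling.shape != (k,):
            raise ValueError("cognition_coupling must have one weight per network")
        if int(self.mask.sum()) != v:
            raise ValueError("network_maps second axis must match mask voxel count")

    @property
    def n_networks(self) -> int:
        return self.network_maps.shape[0]

    @property
    def main_networks(self) -> tuple[int, ...]:
        return tuple(k for k in range(self.n_networks) if k not in self.dmn_subnets)

    def templates(self, level: float = 0.5) -> dict[str, np.ndarray]:
        """Binary template masks (over mask voxels) used to label recovered
        components: one per non-DMN network plus a merged ``DMN`` template
        covering the union of the DMN subnetwork blobs."""
        out: dict[str, np.ndarray] = {}
        for k in self.main_networks:
            out[self.network_names[k]] = self.network_maps[k] > level
        if self.dmn_subnets:
            union = np.zeros(self.network_maps.shape[1], dtype=bool)
            for k in self.dmn_subnets:
                union |= self.network_maps[k] > level
            out["DMN"] = union
        return out


def _simulate_motion(rng: np.random.Generator, n_volumes: int) -> np.ndarray:
    """Rigid-body motion parameters as slow random walks: three translations
    (mm) and three rotations (rad)."""
    steps = rng.standard_normal((n_volumes, 6))
    steps[:, :3] *= 0.02
    steps[:, 3:] *= 0.005
    return np.cumsum(steps, axis=0)


def _source_courses(truth: GroundTruth, n_volumes: float, tr: float,
                    rng: np.random.Generator) -> np.ndarray:
    k = truth.n_networks
    courses = make_timecourses(n_volumes, tr, truth.band, rng, n_courses=k)
    if truth.dmn_subnets:
        parent = make_timecourses(n_volumes, tr, truth.band, rng, n_courses=1)[0]
        w = truth.dmn_course_weight
        for idx in truth.dmn_subnets:
            mixed = w * parent + np.sqrt(1.0 - w * w) * courses[idx]
            mixed -= mixed.mean()
            courses[idx] = mixed / mixed.std(ddof=1)
    return courses


def planted_amplitudes(truth: GroundTruth, group: int, age: float,
                       subject_offset: np.ndarray | float) -> np.ndarray:
    """The ground-truth per-network amplitudes of one acquisition."""
    return (truth.amp_intercept[group] + truth.amp_slope[group] * age
            + np.asarray(subject_offset))


def synthesize_subject(
    truth: GroundTruth,
    design: CohortDesign,
    group: int,
    age: float,
    subject_offset: np.ndarray | float = 0.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """One acquisition: ``(V, T)`` float32 voxel time-series plus its
    ``(T, 6)`` motion table.

    The signal is the amplitude-weighted sum of planted map x course outer
    products; the motion table drives a rank-6 nuisance term (scaled by
    ``motion_coupling``) so the downstream nuisance regression has a real
    target; iid Gaussian noise with SD ``noise_sd`` is added on top.
    """
    if group not in (WT, TG):
        raise ValueError("group must be 0 (WT) or 1 (Tg)")
    if age <= 0:
        raise ValueError("age must be positive (months)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = design.n_volumes
    courses = _source_courses(truth, t, design.tr, rng)
    amps = planted_amplitudes(truth, group, age, subject_offset)
    data = (truth.network_maps.T @ (amps[:, None] * courses)).astype(np.float32)

    motion = _simulate_motion(rng, t)
    if truth.motion_coupling > 0 and truth.motion_patterns is not None:
        m = motion - motion.mean(axis=0)
        sd = m.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        m = m / sd
        data += (truth.motion_coupling
                 * (truth.motion_patterns.T @ m.T)).astype(np.float32)
    if truth.noise_sd > 0:
        data += rng.standard_normal(data.shape).astype(np.float32) * np.float32(truth.noise_sd)
    return data, motion


@dataclass
class AcquisitionRecord:
    """One subject x timepoint acquisition with its ground truth."""

    subject_id: str
    group: int
    timepoint: str
    age_months: float
    data: np.ndarray          # (V, T) float32 over mask voxels
    motion: np.ndarray        # (T, 6)
    planted_amp: np.ndarray   # (K,)
    subject_offset: np.ndarray


def simulate_cohort_records(
    design: CohortDesign, truth: GroundTruth
) -> list[AcquisitionRecord]:
    """Generate the whole cohort in memory, deterministically from
    ``design.seed``.  Records are ordered by (group, subject, timepoint)."""
    root = np.random.SeedSequence(design.seed)
    k = truth.n_networks
    records: list[AcquisitionRecord] = []
    subj_seeds = root.spawn(sum(design.n_subjects))
    i_subj = 0
    for g in range(2):
        for s in range(design.n_subjects[g]):
            srng = np.random.default_rng(subj_seeds[i_subj])
            i_subj += 1
            offset = srng.normal(0.0, truth.subject_sd, size=k)
            sid = f"{GROUP_NAMES[g].lower()}{s:02d}"
            for p, tp in enumerate(design.timepoints):
                if s >= design.group_sizes[g][p]:
                    continue
                age = float(design.age_means[g][p]
                            + srng.normal(0.0, design.age_sds[g][p]))
                acq_rng = np.random.default_rng(srng.integers(2**31))
                data, motion = synthesize_subject(
                    truth, design, g, age, offset, acq_rng)
                records.append(AcquisitionRecord(
                    subject_id=sid, group=g, timepoint=tp, age_months=age,
                    data=data, motion=motion,
                    planted_amp=planted_amplitudes(truth, g, age, offset),
                    subject_offset=offset))
    return records


def cohort_table(records: list[AcquisitionRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "group": [r.group for r in records],
        "age_months": [r.age_months for r in records],
        "timepoint": [r.timepoint for r in records],
    })


def planted_amplitude_table(records: list[AcquisitionRecord],
                            names: tuple[str, ...]) -> pd.DataFrame:
    amp = pd.DataFrame(np.stack([r.planted_amp for r in records]),
                       columns=list(names))
    return pd.concat([cohort_table(records), amp], axis=1)


def simulate_behavior(
    truth: GroundTruth,
    amplitude_table: pd.DataFrame,
    noise_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Behavioral scores coupled to planted network amplitudes.

    A latent performance score is the ``cognition_coupling``-weighted sum of
    the planted amplitudes, standardized over the cohort, plus Gaussian noise
    of SD ``noise_sd`` (in standardized units).  It is mapped monotonically to
    a trial count (``n_trials``, capped at the 90-trial session limit) and a
    correct-response ratio in [0, 1].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    amps = amplitude_table[list(truth.network_names)].to_numpy()
    score = amps @ truth.cognition_coupling
    sd = score.std(ddof=1)
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    z = z + rng.normal(0.0, noise_sd, size=z.shape)
    n_trials = np.clip(np.rint(55 + 15 * z), 0, 90).astype(int)
    ratio = np.clip(0.7 + 0.08 * z, 0.0, 1.0)
    return pd.DataFrame({
        "subject_id": amplitude_table["subject_id"],
        "timepoint": amplitude_table["timepoint"],
        "n_trials": n_trials,
        "correct_ratio": ratio,
    })


DEFAULT_NETWORK_NAMES = (
    "somatosensorial_I",
    "somatosensorial_II",
    "sensorimotor",
    "dmn_anterior",
    "dmn_posterior",
    "dmn_prelimbic",
)


def default_ground_truth(design: CohortDesign, seed: int | None = None,
                         beta3: float = -0.03) -> GroundTruth:
    """The reference phantom: six planted networks on the full-grid mask.

    Two "somatosensory" networks carry the group-divergent trajectory (WT
    amplitude rising with age, Tg falling; group x age interaction ``beta3``
    per month), one "sensorimotor" network is a null network with no group or
    age effect, and three mutually temporally-correlated blobs form the
    default-mode-like parent whose amplitude also carries no group effect.
    Behavioral scores couple to the first somatosensory network only.
    """
    if seed is None:
        seed = design.seed + 1
    mask = np.ones(design.grid_dims, dtype=bool)
    maps = make_network_maps(design.grid_dims, mask, len(DEFAULT_NETWORK_NAMES),
                             seed=seed)
    half = abs(beta3) / 2.0
    # equalize group amplitudes near the mid age so neither group dominates
    mid_age = 11.3
    slope = np.array([
        [+half, +half, 0.0, 0.0, 0.0, 0.0],
        [-half, -half, 0.0, 0.0, 0.0, 0.0],
    ])
    intercept = np.ones((2, 6))
    intercept[:, :2] = 1.0 - slope[:, :2] * mid_age
    rng = np.random.default_rng(seed + 1)
    patterns = rng.standard_normal((6, int(mask.sum())))
    patterns /= patterns.std(axis=1, ddof=1, keepdims=True)
    return GroundTruth(
        network_maps=maps,
        network_names=DEFAULT_NETWORK_NAMES,
        mask=mask,
        amp_intercept=intercept,
        amp_slope=slope,
        cognition_coupling=np.array([1.0, 0, 0, 0, 0, 0]),
        dmn_subnets=(3, 4, 5),
        motion_patterns=patterns,
    )


def simulate_cohort(design: CohortDesign, truth: GroundTruth, out_dir) -> dict:
    """Write the cohort to disk (NIfTI volumes, motion/cohort/behavior TSVs,
    JSON ground-truth manifest) and return the manifest dict.

    On any error the files created by this call are removed before
    re-raising, so a partial dataset is never left behind.
    """
    from pathlib import Path

    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    try:
        records = simulate_cohort_records(design, truth)
        manifest = {
            "seed": design.seed,
            "grid_dims": list(design.grid_dims),
            "n_volumes": design.n_volumes,
            "tr": design.tr,
            "voxel_size_mm": design.voxel_size_mm,
            "network_names": list(truth.network_names),
            "dmn_subnets": list(truth.dmn_subnets),
            "acquisitions": [],
        }
        for r in records:
            stem = f"{r.subject_id}_{r.timepoint}"
            img_path = out / f"{stem}_bold.nii"
            mot_path = out / f"{stem}_motion.tsv"
            rio.write_series(img_path, r.data, truth.mask, design.voxel_size_mm)
            rio.write_motion(mot_path, r.motion)
            created += [img_path, mot_path]
            manifest["acquisitions"].append({
                "subject_id": r.subject_id,
                "group": int(r.group),
                "timepoint": r.timepoint,
                "age_months": r.age_months,
                "bold": img_path.name,
                "motion": mot_path.name,
                "planted_amplitudes": [float(a) for a in r.planted_amp],
                "sha256": rio.sha256_of(img_path),
            })
        mask_path = out / "mask.nii"
        rio.write_mask(mask_path, truth.mask, design.voxel_size_mm)
        created.append(mask_path)
        tab_path = out / "cohort.tsv"
        cohort_table(records).to_csv(tab_path, sep="\t", index=False)
        created.append(tab_path)
        beh = simulate_behavior(
            truth, planted_amplitude_table(records, truth.network_names),
            seed=design.seed + 7)
        beh_path = out / "behavior.tsv"
        beh.to_csv(beh_path, sep="\t", index=False)
        created.append(beh_path)
        man_path = out / "manifest.json"
        man_path.write_text(json.dumps(manifest, indent=1))
        created.append(man_path)
        return manifest
    except Exception:
        for p in created:
            try:
                p.unlink()
            except OSError:  # pragma: no cover
                warnings.warn(f"could not remove partial output {p}")
        raise
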