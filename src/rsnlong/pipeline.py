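"""End-to-end experiment orchestration.

``run_experiment`` executes the whole analysis in memory on a synthetic
cohort (simulate -> preprocess -> low/high-order group ICA -> dual
regression -> metrics -> longitudinal statistics) and returns every
intermediate product; the Monte-Carlo recovery checks and the acceptance
script are built on it.  ``run_pipeline`` is the on-disk, checksum-gated
variant behind the numbered analysis scripts: stages whose inputs, config
and outputs are unchanged are skipped on rerun, and a corrupted intermediate
file re-runs exactly the downstream stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .cohort import (AcquisitionRecord, CohortDesign, GroundTruth,
                     cohort_table, planted_amplitude_table,
                     simulate_behavior, simulate_cohort,
                     simulate_cohort_records)
from .config import PipelineConfig
from .dualreg import SubjectNetworkSet, dual_regress, stage1
from .groupica import ComponentLabel, ComponentSet, concatenate, match_templates, \
    reduce_and_ica
from .longstats import analyze_metric, fisher_z, fit_lme, group_tests, \
    spearman_behavior
from .metrics import SubnetworkAssignment, connectivity_rows, match_subnetworks, \
    mean_within_connectivity, metric_rows
from .preprocess import PreprocessParams, preprocess_series

__all__ = ["ExperimentResult", "run_experiment", "run_pipeline"]


@dataclass
class ExperimentResult:
    """Everything one synthetic end-to-end run produces."""

    cohort: pd.DataFrame
    labels: ComponentLabel
    cs_low: ComponentSet
    cs_high: ComponentSet | None
    subject_sets: list[SubjectNetworkSet]
    metric_table: pd.DataFrame
    connectivity: pd.DataFrame
    behavior: pd.DataFrame
    lme: dict = field(default_factory=dict)
    lme_table: pd.DataFrame | None = None
    group_test_table: pd.DataFrame | None = None
    behavior_correlations: pd.DataFrame | None = None
    connectivity_lme: dict = field(default_factory=dict)
    subnetworks: SubnetworkAssignment | None = None
    dmn_connectivity: pd.DataFrame | None = None


def _preprocess_records(records: list[AcquisitionRecord], truth: GroundTruth,
                        design: CohortDesign, cfg: PipelineConfig):
    params = PreprocessParams(n_discard=cfg.n_discard, fwhm_mm=cfg.fwhm_mm,
                              detrend_order=cfg.detrend_order, band=cfg.band)
    cleaned = []
    for r in records:
        vt, _ = preprocess_series(r.data, r.motion, truth.mask, design.tr,
                                  design.voxel_size_mm, params)
        cleaned.append(vt.astype(np.float32))
    return cleaned


def _lme_summary_table(lme: dict) -> pd.DataFrame:
    rows = []
    for (network, metric), res in lme.items():
        d = res["full"].as_dict()
        d.update(network=network, metric=metric, model="all_subjects")
        rows.append(d)
        for g, rg in res["per_group"].items():
            dg = rg.as_dict()
            dg.update(network=network, metric=metric,
                      model=f"group_{g}_age_only")
            rows.append(dg)
    return pd.DataFrame(rows)


def run_experiment(
    design: CohortDesign,
    truth: GroundTruth,
    cfg: PipelineConfig | None = None,
    with_stats: bool = True,
) -> ExperimentResult:
    """Run the full analysis in memory on one synthetic cohort."""
    cfg = cfg or PipelineConfig()
    records = simulate_cohort_records(design, truth)
    cleaned = _preprocess_records(records, truth, design, cfg)
    ids = [f"{r.subject_id}_{r.timepoint}" for r in records]
    concat, ranges = concatenate(cleaned, ids,
                                 variance_normalize=cfg.variance_normalize_blocks)
    order_low = cfg.synthetic.order_low if cfg.synthetic.enabled else cfg.order30
    order_high = cfg.synthetic.order_high if cfg.synthetic.enabled else cfg.order150
    order_high = min(order_high, min(concat.shape) - 1)
    cs_low = reduce_and_ica(concat, order_low, cfg.ica_seed, ranges)
    labels = match_templates(cs_low, truth.templates(), cfg.z_thresh)
    cs_high = reduce_and_ica(concat, order_high, cfg.ica_seed, ranges)

    met_rows, conn_rows, sets = [], [], []
    for r, vt in zip(records, cleaned):
        sns = dual_regress(vt, cs_low.maps_z,
                           variance_normalize=cfg.stage2_variance_normalize,
                           subject_id=r.subject_id, timepoint=r.timepoint)
        sets.append(sns)
        met_rows += metric_rows(sns, labels.labels, r.group, r.age_months,
                                cfg.z_thresh)
        conn_rows += connectivity_rows(sns, labels.labels)
    metric_table = pd.DataFrame(met_rows)
    connectivity = pd.DataFrame(conn_rows)

    behavior = simulate_behavior(
        truth, planted_amplitude_table(records, truth.network_names),
        noise_sd=cfg.synthetic.behavior_noise_sd, seed=design.seed + 7)

    subnets = None
    dmn_conn = None
    if truth.dmn_subnets and "DMN" in labels.labels.values():
        subnets = match_subnetworks("DMN", cs_low, labels, cs_high,
                                    cfg.r_thresh, cfg.overlap_thresh,
                                    cfg.z_thresh)
        if len(subnets.component_ids) >= 2:
            rows = []
            for r, vt in zip(records, cleaned):
                ts = stage1(vt, cs_high.maps_z)
                rows.append({
                    "subject_id": r.subject_id, "group": r.group,
                    "age_months": r.age_months, "timepoint": r.timepoint,
                    "mean_within_r": mean_within_connectivity(
                        ts[:, subnets.component_ids]),
                })
            dmn_conn = pd.DataFrame(rows)

    result = ExperimentResult(
        cohort=cohort_table(records), labels=labels, cs_low=cs_low,
        cs_high=cs_high, subject_sets=sets, metric_table=metric_table,
        connectivity=connectivity, behavior=behavior, subnetworks=subnets,
        dmn_connectivity=dmn_conn)

    if with_stats and not metric_table.empty:
        for network, sub in metric_table.groupby("network"):
            for metric in ("amplitude", "shape"):
                try:
                    result.lme[(network, metric)] = analyze_metric(
                        sub, metric, cfg.alpha)
                except ValueError:
                    continue
        result.lme_table = _lme_summary_table(result.lme)
        result.group_test_table = group_tests(metric_table, alpha=cfg.alpha,
                                              tendency=cfg.tendency)
        result.behavior_correlations = spearman_behavior(
            metric_table, behavior, alpha=cfg.alpha)
        meta = metric_table[["subject_id", "group", "age_months",
                             "timepoint"]].drop_duplicates()
        for (na, nb), sub in connectivity.groupby(["network_a", "network_b"]):
            merged = sub.merge(meta, on=["subject_id", "timepoint"])
            merged = merged.assign(
                conn=fisher_z(merged["pearson_r"])
                if cfg.fisher_z_connectivity else merged["pearson_r"])
            try:
                result.connectivity_lme[(na, nb)] = fit_lme(
                    merged, "conn", response=f"connectivity[{na}~{nb}]")
            except ValueError:
                continue
    return result


# ---------------------------------------------------------------------------
# on-disk, checksum-gated pipeline
# ---------------------------------------------------------------------------

STAGES = ("simulate", "preprocess", "ica", "dualreg", "metrics", "stats")


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _outputs_intact(entry: dict, root: Path) -> bool:
    for rel, digest in entry.get("outputs", {}).items():
        p = root / rel
        if not p.exists() or rio.sha256_of(p) != digest:
            return False
    return True


def _record_outputs(root: Path, paths: list[Path]) -> dict:
    return {str(p.relative_to(root)): rio.sha256_of(p) for p in paths}


def run_pipeline(
    workdir,
    design: CohortDesign,
    truth: GroundTruth,
    cfg: PipelineConfig | None = None,
    upto: str | None = None,
) -> dict:
    """Run the staged pipeline on disk under ``workdir``.

    Returns the run manifest.  Completed stages with unchanged config and
    intact (checksummed) outputs are skipped; any stage that runs forces all
    downstream stages to run too.  ``upto`` stops after the named stage.
    A stage failure raises with the stage name attached.
    """
    cfg = cfg or PipelineConfig()
    root = Path(workdir)
    root.mkdir(parents=True, exist_ok=True)
    man_path = root / "manifest.json"
    manifest = rio.read_json(man_path) if man_path.exists() else {"stages": {}}
    cfg_hash = _hash_obj({"cfg": cfg.__dict__, "syn": cfg.synthetic.__dict__,
                          "design": design.__dict__})
    if manifest.get("config_hash") != cfg_hash:
        manifest = {"stages": {}}
    manifest["config_hash"] = cfg_hash

    if upto is not None and upto not in STAGES:
        raise ValueError(f"unknown stage {upto!r}")
    stages = STAGES[: STAGES.index(upto) + 1] if upto else STAGES
    upstream_ran = False
    executed: list[str] = []
    for stage in stages:
        entry = manifest["stages"].get(stage)
        if (not upstream_ran and entry and entry.get("status") == "done"
                and _outputs_intact(entry, root)):
            continue
        upstream_ran = True
        try:
            outputs = _run_stage(stage, root, design, truth, cfg)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            rio.write_json(man_path, manifest)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "done", "outputs": _record_outputs(root, outputs)}
        executed.append(stage)
        rio.write_json(man_path, manifest)
    manifest["executed"] = executed
    rio.write_json(man_path, manifest)
    return manifest


def _run_stage(stage: str, root: Path, design: CohortDesign,
               truth: GroundTruth, cfg: PipelineConfig) -> list[Path]:
    if stage == "simulate":
        sim = root / "raw"
        simulate_cohort(design, truth, sim)
        return sorted(sim.iterdir())

    raw = rio.read_json(root / "raw" / "manifest.json")
    mask = rio.read_mask(root / "raw" / "mask.nii")

    if stage == "preprocess":
        out = root / "clean"
        out.mkdir(exist_ok=True)
        params = PreprocessParams(n_discard=cfg.n_discard, fwhm_mm=cfg.fwhm_mm,
                                  detrend_order=cfg.detrend_order, band=cfg.band)
        paths = []
        for acq in raw["acquisitions"]:
            data = rio.read_series(root / "raw" / acq["bold"], mask)
            motion = rio.read_motion(root / "raw" / acq["motion"])
            vt, _ = preprocess_series(data, motion, mask, design.tr,
                                      design.voxel_size_mm, params)
            p = out / acq["bold"].replace("_bold", "_clean")
            rio.write_series(p, vt.astype(np.float32), mask,
                             design.voxel_size_mm)
            paths.append(p)
        return paths

    def load_clean():
        mats, ids = [], []
        for acq in raw["acquisitions"]:
            p = root / "clean" / acq["bold"].replace("_bold", "_clean")
            mats.append(rio.read_series(p, mask))
            ids.append(f"{acq['subject_id']}_{acq['timepoint']}")
        return mats, ids

    if stage == "ica":
        mats, ids = load_clean()
        concat, ranges = concatenate(mats, ids,
                                     cfg.variance_normalize_blocks)
        order_low = cfg.synthetic.order_low if cfg.synthetic.enabled else cfg.order30
        order_high = cfg.synthetic.order_high if cfg.synthetic.enabled else cfg.order150
        order_high = min(order_high, min(concat.shape) - 1)
        out = root / "ica"
        out.mkdir(exist_ok=True)
        paths = []
        for name, order in (("low", order_low), ("high", order_high)):
            cs = reduce_and_ica(concat, order, cfg.ica_seed, ranges)
            np.savetxt(out / f"maps_{name}.tsv", cs.maps_z.T, delimiter="\t")
            np.savetxt(out / f"mixing_{name}.tsv", cs.mixing, delimiter="\t")
            rio.write_series(out / f"maps_{name}.nii", cs.maps_z.T, mask,
                             design.voxel_size_mm)
            paths += [out / f"maps_{name}.tsv", out / f"mixing_{name}.tsv",
                      out / f"maps_{name}.nii"]
            if name == "low":
                labels = match_templates(cs, truth.templates(), cfg.z_thresh)
                rio.write_json(out / "labels.json",
                               {str(k): v for k, v in labels.labels.items()})
                paths.append(out / "labels.json")
        return paths

    def load_ica(name):
        maps = np.loadtxt(root / "ica" / f"maps_{name}.tsv", delimiter="\t").T
        mixing = np.loadtxt(root / "ica" / f"mixing_{name}.tsv", delimiter="\t")
        return ComponentSet(maps_z=maps, mixing=mixing, order=maps.shape[0],
                            seed=cfg.ica_seed)

    def load_labels():
        d = rio.read_json(root / "ica" / "labels.json")
        return ComponentLabel(labels={int(k): v for k, v in d.items()},
                              scores={})

    if stage == "dualreg":
        mats, ids = load_clean()
        cs = load_ica("low")
        out = root / "dualreg"
        out.mkdir(exist_ok=True)
        paths = []
        for acq, m in zip(raw["acquisitions"], mats):
            sns = dual_regress(m, cs.maps_z, cfg.stage2_variance_normalize)
            stem = f"{acq['subject_id']}_{acq['timepoint']}"
            rio.write_table(out / f"{stem}_timeseries.tsv",
                            pd.DataFrame(sns.timeseries))
            rio.write_series(out / f"{stem}_zmaps.nii", sns.z_maps.T, mask,
                             design.voxel_size_mm)
            paths += [out / f"{stem}_timeseries.tsv", out / f"{stem}_zmaps.nii"]
        return paths

    if stage == "metrics":
        mats, ids = load_clean()
        cs = load_ica("low")
        labels = load_labels()
        met, conn = [], []
        for acq, m in zip(raw["acquisitions"], mats):
            sns = dual_regress(m, cs.maps_z, cfg.stage2_variance_normalize,
                               subject_id=acq["subject_id"],
                               timepoint=acq["timepoint"])
            met += metric_rows(sns, labels.labels, acq["group"],
                               acq["age_months"], cfg.z_thresh)
            conn += connectivity_rows(sns, labels.labels)
        out = root / "tables"
        rio.write_table(out / "metrics.tsv", pd.DataFrame(met))
        rio.write_table(out / "connectivity.tsv", pd.DataFrame(conn))
        paths = [out / "metrics.tsv", out / "connectivity.tsv"]
        if truth.dmn_subnets and "DMN" in labels.labels.values():
            cs_high = load_ica("high")
            subnets = match_subnetworks("DMN", cs, labels, cs_high,
                                        cfg.r_thresh, cfg.overlap_thresh,
                                        cfg.z_thresh)
            rio.write_json(out / "subnetworks.json",
                           {"parent": subnets.parent,
                            "entries": subnets.entries})
            paths.append(out / "subnetworks.json")
        return paths

    if stage == "stats":
        out = root / "tables"
        table = rio.read_table(out / "metrics.tsv")
        lme: dict = {}
        for network, sub in table.groupby("network"):
            for metric in ("amplitude", "shape"):
                try:
                    lme[(network, metric)] = analyze_metric(sub, metric,
                                                            cfg.alpha)
                except ValueError:
                    continue
        rio.write_table(out / "lme.tsv", _lme_summary_table(lme))
        rio.write_table(out / "group_tests.tsv",
                        group_tests(table, alpha=cfg.alpha,
                                    tendency=cfg.tendency))
        behavior = rio.read_table(root / "raw" / "behavior.tsv")
        rio.write_table(out / "behavior_correlations.tsv",
                        spearman_behavior(table, behavior, alpha=cfg.alpha))
        return [out / "lme.tsv", out / "group_tests.tsv",
                out / "behavior_correlations.tsv"]

    raise ValueError(f"unknown stage {stage!r}")  # pragma: no cover
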