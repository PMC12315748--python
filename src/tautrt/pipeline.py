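"""End-to-end orchestration: cohort -> (optional PVC) -> ROI sampling ->
SUV / SUVR / DVR / R1 -> test-retest report.

The pipeline is config-driven and fully deterministic: identical config and
seed regenerate byte-identical output tables. PVC-corrected and uncorrected
outcomes are kept separate end to end and are never mixed inside a ratio.
Failed kinetic fits yield NaN-marked rows plus an error log entry rather
than aborting the cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinetics as kin
from .phantoms import Cohort
from .pvc import PvcConfig, iterative_yang
from .rois import LabelVolume, RegionSpec, meta_temporal_spec, sample_regions
from .tacs import FrameSchedule, ScanMeta
from .trt_stats import bland_altman, icc_two_way, paired_wilcoxon, trt_percent

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "default_region_specs",
    "reference_region_names",
    "quantify_scan",
    "run_pipeline",
    "trt_report",
    "compare_reference_regions",
    "write_outputs",
]

# The eight candidate reference regions evaluated for normalization.
reference_region_names = (
    "cerebellar_gm",
    "cerebellar_gm_3mm",
    "inferior_cerebellum",
    "cerebellar_wm",
    "cerebral_wm",
    "wm_4mm",
    "whole_cerebellum",
    "pons",
)


@dataclass(frozen=True)
class PipelineConfig:
    reference_region: str = "cerebellar_gm"
    window: tuple[float, float] = (90.0, 110.0)
    t_star: float = 30.0
    k2_prime: float = 0.04
    pvc_enabled: bool = False
    pvc: PvcConfig = field(default_factory=PvcConfig)
    icc_exclude_groups: tuple[str, ...] = ("AD",)

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("invalid SUV window")

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        d["icc_exclude_groups"] = list(self.icc_exclude_groups)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "pvc" in raw:
            raw["pvc"] = PvcConfig(**raw["pvc"])
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        if "icc_exclude_groups" in raw:
            raw["icc_exclude_groups"] = tuple(raw["icc_exclude_groups"])
        return cls(**raw)


@dataclass
class PipelineResult:
    outcomes: pd.DataFrame
    report: pd.DataFrame
    errors: list[dict]
    config: PipelineConfig


def default_region_specs(vol: LabelVolume) -> list[RegionSpec]:
    """Named regions plus the derived reference variants and composites.

    Derived regions: 3-mm eroded cerebellar grey, 4-mm eroded cerebral white
    matter, whole cerebellum (grey + white), inferior cerebellum (grey minus
    the provided superior-cerebellum mask), and the meta-temporal composite.
    """
    specs: list[RegionSpec] = []
    for lid, info in sorted(vol.labels.items()):
        specs.append(RegionSpec(info.name, (lid,), role=info.role))
    cer = vol.id_of("cerebellar_gm")
    cwm = vol.id_of("cerebellar_wm")
    wm = vol.id_of("cerebral_wm")
    specs.append(RegionSpec("cerebellar_gm_3mm", (cer,), erode_mm=3.0, role="reference"))
    specs.append(RegionSpec("wm_4mm", (wm,), erode_mm=4.0, role="reference"))
    specs.append(RegionSpec("whole_cerebellum", (cer, cwm), role="reference"))
    specs.append(RegionSpec("inferior_cerebellum", (cer,), role="reference",
                            subtract_names=("superior_cerebellum",)))
    specs.append(meta_temporal_spec(vol))
    return specs


def _kinetics_feasible(schedule: FrameSchedule, t_star: float) -> bool:
    return (
        schedule.starts[0] <= 2.0
        and schedule.n_frames >= 12
        and int(np.sum(schedule.midpoints >= t_star)) >= 3
    )


def quantify_scan(
    img: np.ndarray,
    vol: LabelVolume,
    schedule: FrameSchedule,
    meta: ScanMeta,
    cfg: PipelineConfig,
    specs: list[RegionSpec] | None = None,
    aux_masks: dict[str, np.ndarray] | None = None,
    pvc_flag: bool = False,
    errors: list[dict] | None = None,
) -> pd.DataFrame:
    """Regional outcome table for one scan (one PVC status).

    Outcomes: SUV for every region; SUVR (vs the configured reference) for
    every non-reference-choice region; DVR (MRTM2) and R1 (SRTM) for target
    regions when the schedule supports dynamic modeling.
    """
    specs = default_region_specs(vol) if specs is None else specs
    tacs = sample_regions(img, vol, specs, schedule, aux_masks)
    t0, t1 = cfg.window
    suvs = {name: kin.suv_window(tac, meta, t0, t1, pvc_applied=pvc_flag)
            for name, tac in tacs.items()}
    ref_suv = suvs[cfg.reference_region]
    ref_tac = tacs[cfg.reference_region]
    do_kinetics = _kinetics_feasible(schedule, cfg.t_star)

    rows = []

    def add(region, outcome, value):
        rows.append(
            {"subject": meta.subject_id, "session": meta.session, "group": meta.group,
             "region": region, "outcome": outcome, "value": value, "pvc": pvc_flag}
        )

    roles = {s.name: s.role for s in specs}
    for name in tacs:
        add(name, "SUV", suvs[name].value)
        if name != cfg.reference_region:
            add(name, "SUVR", kin.suvr(suvs[name], ref_suv))
    for name, tac in tacs.items():
        if roles.get(name) != "target" or not do_kinetics:
            continue
        try:
            fit = kin.mrtm2_fit(tac, ref_tac, t_star=cfg.t_star, k2_prime=cfg.k2_prime)
            add(name, "DVR", fit.dvr)
        except (ValueError, np.linalg.LinAlgError) as exc:
            add(name, "DVR", np.nan)
            if errors is not None:
                errors.append({"subject": meta.subject_id, "session": meta.session,
                               "region": name, "outcome": "DVR", "error": str(exc)})
        try:
            params, _ = kin.srtm_fit(tac, ref_tac)
            add(name, "R1", params.r1)
        except (ValueError, np.linalg.LinAlgError) as exc:
            add(name, "R1", np.nan)
            if errors is not None:
                errors.append({"subject": meta.subject_id, "session": meta.session,
                               "region": name, "outcome": "R1", "error": str(exc)})
    return pd.DataFrame(rows)


def run_pipeline(cohort: Cohort, cfg: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Quantify a cohort and build its test-retest report.

    Subjects without a retest session contribute to per-scan outcomes but
    are dropped from the paired statistics. When PVC is enabled, both the
    uncorrected and corrected outcome sets are produced.
    """
    errors: list[dict] = []
    frames: list[pd.DataFrame] = []
    for subject in cohort.subjects:
        test, retest, (meta_t, meta_r) = cohort.realize(subject)
        vol = subject.phantom.labels
        aux = {"superior_cerebellum": subject.phantom.superior_cerebellum}
        specs = default_region_specs(vol)
        scans = [(test, meta_t)] + ([(retest, meta_r)] if retest is not None else [])
        for img, meta in scans:
            frames.append(quantify_scan(img, vol, cohort.schedule, meta, cfg,
                                        specs, aux, pvc_flag=False, errors=errors))
            if cfg.pvc_enabled:
                img_pvc = iterative_yang(img, vol.data, vol.voxel_size_mm, cfg.pvc)
                frames.append(quantify_scan(img_pvc, vol, cohort.schedule, meta, cfg,
                                            specs, aux, pvc_flag=True, errors=errors))
    outcomes = pd.concat(frames, ignore_index=True)
    outcomes = outcomes.sort_values(
        ["pvc", "outcome", "region", "subject", "session"]
    ).reset_index(drop=True)
    report = trt_report(outcomes, icc_exclude_groups=cfg.icc_exclude_groups)
    return PipelineResult(outcomes, report, errors, cfg)


def _pairs(df: pd.DataFrame) -> pd.DataFrame:
    wide = df.pivot_table(index=["subject", "group"], columns="session",
                          values="value", aggfunc="first")
    if "test" not in wide or "retest" not in wide:
        return pd.DataFrame(columns=["test", "retest"])
    return wide.dropna(subset=["test", "retest"])


def trt_report(outcomes: pd.DataFrame,
               icc_exclude_groups: tuple[str, ...] = ("AD",)) -> pd.DataFrame:
    """Per region x outcome x PVC status: T-RT% (mean +/- SD), ICC (+CI and
    band, computed with the listed groups excluded), Bland-Altman bias and
    limits of agreement, and the paired Wilcoxon p-value."""
    rows = []
    for (region, outcome, pvc), df in outcomes.groupby(["region", "outcome", "pvc"]):
        pairs = _pairs(df)
        if len(pairs) == 0:
            continue
        t = pairs["test"].to_numpy()
        r = pairs["retest"].to_numpy()
        finite = np.isfinite(t) & np.isfinite(r)
        t, r = t[finite], r[finite]
        if t.size == 0:
            continue
        row = {"region": region, "outcome": outcome, "pvc": pvc, "n_pairs": int(t.size)}
        trt = trt_percent(t, r)
        row["trt_mean"] = float(np.mean(trt))
        row["trt_sd"] = float(np.std(trt, ddof=1)) if t.size > 1 else np.nan
        groups = pairs.index.get_level_values("group").to_numpy()[finite]
        keep = ~np.isin(groups, list(icc_exclude_groups))
        if keep.sum() >= 3:
            icc = icc_two_way(t[keep], r[keep])
            row.update(icc=icc.icc, icc_lo=icc.ci_low, icc_hi=icc.ci_high,
                       icc_band=icc.band, icc_n=icc.n_subjects)
        else:
            row.update(icc=np.nan, icc_lo=np.nan, icc_hi=np.nan,
                       icc_band="n/a", icc_n=int(keep.sum()))
        if t.size >= 2:
            ba = bland_altman(t, r)
            row.update(ba_bias=ba.bias, ba_loa_low=ba.loa_low, ba_loa_high=ba.loa_high)
        else:
            row.update(ba_bias=np.nan, ba_loa_low=np.nan, ba_loa_high=np.nan)
        wil = paired_wilcoxon(t, r)
        row["wilcoxon_p"] = wil.p_value
        rows.append(row)
    rep = pd.DataFrame(rows)
    return rep.sort_values(["pvc", "outcome", "region"]).reset_index(drop=True)


def compare_reference_regions(
    outcomes: pd.DataFrame,
    references: tuple[str, ...] = reference_region_names,
    pvc: bool = False,
) -> pd.DataFrame:
    """SUVR and SUVR T-RT% for each candidate reference region.

    SUVRs are rebuilt from the SUV table (same windows by construction), so
    a single pipeline pass supports every normalization choice. The returned
    table carries, per reference, the group-mean SUVR per target region, its
    T-RT%, and the target rank (1 = highest mean SUVR) so rank-order
    stability across references can be checked.
    """
    suv = outcomes[(outcomes.outcome == "SUV") & (outcomes.pvc == pvc)]
    wide = suv.pivot_table(index=["subject", "group", "session"],
                           columns="region", values="value", aggfunc="first")
    targets = sorted(
        set(outcomes.loc[(outcomes.outcome == "SUVR") & (outcomes.pvc == pvc), "region"])
        - set(references)
    )
    rows = []
    for ref in references:
        if ref not in wide.columns:
            raise KeyError(f"reference region {ref!r} missing from outcomes")
        for target in targets:
            suvr_vals = wide[target] / wide[ref]
            df = suvr_vals.rename("value").reset_index()
            df["region"] = target
            pairs = _pairs(df)
            mean_suvr = float(suvr_vals.groupby("subject").mean().mean())
            if len(pairs) >= 1:
                trt = trt_percent(pairs["test"].to_numpy(), pairs["retest"].to_numpy())
                trt_mean = float(np.mean(trt))
            else:
                trt_mean = np.nan
            rows.append({"reference": ref, "region": target,
                         "mean_suvr": mean_suvr, "trt_mean": trt_mean})
    out = pd.DataFrame(rows)
    out["rank"] = out.groupby("reference")["mean_suvr"].rank(ascending=False, method="min").astype(int)
    return out.sort_values(["reference", "rank"]).reset_index(drop=True)


def write_outputs(result: PipelineResult, out_dir, cohort_seed: int | None = None) -> None:
    """Write outcome/report TSVs, the resolved config, and the error log.

    Fixed column order, row sort, and float format make reruns
    byte-identical under the same config and seed.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.outcomes.to_csv(out / "outcomes.tsv", sep="\t", index=False, float_format="%.8g")
    result.report.to_csv(out / "trt_report.tsv", sep="\t", index=False, float_format="%.8g")
    resolved = result.config.resolved()
    resolved["package_version"] = __version__
    if cohort_seed is not None:
        resolved["cohort_seed"] = cohort_seed
    (out / "config_resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
    (out / "errors.json").write_text(json.dumps(result.errors, indent=1, sort_keys=True))
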