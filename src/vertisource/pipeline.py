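"""End-to-end cohort analysis: preprocess -> localize -> connect -> nest -> stats.

One call reproduces the full resting-state analysis surface for a cohort
of recordings plus a behavioral table:

(a) voxelwise group-contrast maps (patients vs controls) for the eight
    activity bands, on log power, with max-statistic permutation FWER
    correction;
(b) voxelwise correlation maps against VAS intensity, VAS discomfort and
    DHI (patients only), same correction;
(c) per-band, per-ROI one-way ANOVA on log-fractional ROI power;
(d) inter-ROI lagged-phase-synchronization matrices per connectivity
    band, with a max-statistic-corrected group comparison over ROI pairs;
(e) alpha-gamma nesting for the frontal eye fields and vestibular
    cortices, plus Pearson correlations of nesting strength |r| with VAS
    intensity among patients.

Nesting strength |r| is used for the behavioral correlation because the
sign of the first-principal-component alpha waveform is a convention,
not a physiological quantity, and is not comparable across subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bands import ACTIVITY8, CONNECTIVITY6
from .connectivity import LPSMatrix, roi_connectivity
from .headmodel import (
    DEFAULT_CONDUCTIVITIES,
    DEFAULT_SHELL_RADII,
    ROIAtlas,
    SourceGrid,
    assign_rois,
    build_montage,
    build_source_grid,
    compute_leadfield,
    default_roi_spec,
)
from .inverse import (
    compute_inverse_operator,
    estimate_band_power,
    extract_roi_timeseries,
    roi_log_power,
)
from .io import Recording, load_recording
from .nesting import compute_nesting
from .preprocess import preprocess
from .stats import (
    StatMap,
    pearson_with_p,
    roi_band_anova,
    snpm_group_compare,
    voxelwise_correlation,
)

NESTING_ROIS = ("FEF_L", "FEF_R", "VC_L", "VC_R")
BEHAVIOR_COLUMNS = ("vas_intensity", "vas_discomfort", "dhi")


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the end-to-end run, with the defaults it logs."""

    seed: int
    grid_spacing: float = 11.0
    roi_radius: float = 18.0
    shell_radii: tuple[float, float, float] = DEFAULT_SHELL_RADII
    conductivities: tuple[float, float, float] = DEFAULT_CONDUCTIVITIES
    alpha_frac: float = 0.05
    target_rate: float = 128.0
    band: tuple[float, float] = (2.0, 44.0)
    amp_thresh: float = 100.0
    var_factor: float = 4.0
    min_duration: float = 60.0
    n_perm: int = 5000
    alpha: float = 0.05
    nesting_rois: tuple[str, ...] = NESTING_ROIS

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    """The five result families plus the geometry they were computed on."""

    grid: SourceGrid
    atlas: ROIAtlas
    group_maps: dict[str, StatMap]              # (a) per activity band
    corr_maps: dict[str, dict[str, StatMap]]    # (b) behavior -> band -> map
    anova: pd.DataFrame                         # (c) band x roi
    lps_subjects: list[LPSMatrix]               # (d) one matrix per subject
    lps_group: pd.DataFrame                     # (d) pairwise group contrast
    nesting: pd.DataFrame                       # (e) subject x roi scores
    nesting_behavior: pd.DataFrame              # (e) |r| vs VAS intensity
    table: pd.DataFrame
    flagged_subjects: list[str]
    config: PipelineConfig


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _stage(stage):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
        return wrapped
    return deco


def run_pipeline(recordings: list[Recording], table: pd.DataFrame,
                 config: PipelineConfig,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis over a cohort.

    ``table`` needs columns ``subject``, ``group`` (patient/control) and
    the behavioral scores; row order matches ``recordings``.
    """
    if len(recordings) != len(table):
        raise PipelineError("config", "recordings and table rows disagree")
    groups = table["group"].to_numpy()
    pat = groups == "patient"
    montage = build_montage()
    grid = build_source_grid(config.grid_spacing, config.shell_radii)
    lf = compute_leadfield(montage, grid, config.shell_radii, config.conductivities)
    inv = compute_inverse_operator(lf, config.alpha_frac)
    atlas = assign_rois(grid, default_roi_spec(config.roi_radius))

    log_maps = np.empty((len(recordings), grid.n_voxels, len(ACTIVITY8)))
    roi_logs: list[pd.DataFrame] = []
    lps_all: list[LPSMatrix] = []
    nest_rows = []
    flagged: list[str] = []
    for i, rec in enumerate(recordings):
        sid = str(table["subject"].iloc[i])
        clean, segs = _preprocess_one(rec, config)
        if segs.flagged:
            flagged.append(sid)
        power = estimate_band_power(clean, inv)
        log_maps[i] = np.log(np.maximum(power.power, 1e-300))
        roi_logs.append(roi_log_power(power, atlas))
        rts = extract_roi_timeseries(clean, inv, atlas)
        lps_all.append(roi_connectivity(rts, clean.rate))
        for roi in config.nesting_rois:
            score = compute_nesting(rts[roi], clean.rate, roi)
            nest_rows.append({"subject": sid, "roi": roi, "r": score.r,
                              "abs_r": abs(score.r), "n_samples": score.n_samples})

    group_maps = _group_maps(log_maps, pat, config)
    corr_maps = _corr_maps(log_maps, table, pat, config)
    anova = _anova_table(roi_logs, groups)
    lps_group = _lps_group(lps_all, pat, config)
    nesting = pd.DataFrame(nest_rows)
    nesting_behavior = _nesting_behavior(nesting, table, pat, config)

    result = PipelineResult(
        grid=grid, atlas=atlas, group_maps=group_maps, corr_maps=corr_maps,
        anova=anova, lps_subjects=lps_all, lps_group=lps_group,
        nesting=nesting, nesting_behavior=nesting_behavior, table=table,
        flagged_subjects=flagged, config=config)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


@_stage("preprocess")
def _preprocess_one(rec: Recording, config: PipelineConfig):
    return preprocess(rec, target_rate=config.target_rate, band=config.band,
                      amp_thresh=config.amp_thresh, var_factor=config.var_factor,
                      min_duration=config.min_duration)


@_stage("group_maps")
def _group_maps(log_maps, pat, config) -> dict[str, StatMap]:
    out = {}
    for bi, band in enumerate(ACTIVITY8):
        out[band] = snpm_group_compare(
            log_maps[pat, :, bi], log_maps[~pat, :, bi],
            n_perm=config.n_perm, alpha=config.alpha,
            seed=config.seed + bi)
    return out


@_stage("correlation_maps")
def _corr_maps(log_maps, table, pat, config) -> dict[str, dict[str, StatMap]]:
    out: dict[str, dict[str, StatMap]] = {}
    for ci, col in enumerate(BEHAVIOR_COLUMNS):
        behavior = table.loc[pat, col].to_numpy(float)
        per_band = {}
        for bi, band in enumerate(ACTIVITY8):
            per_band[band] = voxelwise_correlation(
                log_maps[pat, :, bi], behavior, n_perm=config.n_perm,
                alpha=config.alpha, seed=config.seed + 100 + 10 * ci + bi)
        out[col] = per_band
    return out


@_stage("roi_anova")
def _anova_table(roi_logs: list[pd.DataFrame], groups) -> pd.DataFrame:
    frames = []
    for band in ACTIVITY8:
        values = pd.DataFrame([rl[band].to_dict() for rl in roi_logs])
        res = roi_band_anova(values, groups)
        res.insert(0, "band", band)
        frames.append(res.reset_index())
    return pd.concat(frames, ignore_index=True)


@_stage("lps_group")
def _lps_group(lps_all: list[LPSMatrix], pat, config) -> pd.DataFrame:
    names = lps_all[0].roi_names
    iu = np.triu_indices(len(names), 1)
    frames = []
    for k, band in enumerate(CONNECTIVITY6):
        vals = np.stack([m.values[:, :, k][iu] for m in lps_all])  # subj x pairs
        sm = snpm_group_compare(vals[pat], vals[~pat], n_perm=config.n_perm,
                                alpha=config.alpha, seed=config.seed + 500 + k)
        frames.append(pd.DataFrame({
            "band": band,
            "roi_a": [names[i] for i in iu[0]],
            "roi_b": [names[j] for j in iu[1]],
            "t": sm.stat, "p_corrected": sm.p_corrected,
            "significant": sm.significant,
        }))
    return pd.concat(frames, ignore_index=True)


@_stage("nesting_behavior")
def _nesting_behavior(nesting: pd.DataFrame, table: pd.DataFrame, pat,
                      config) -> pd.DataFrame:
    vas = table.loc[pat, "vas_intensity"].to_numpy(float)
    pat_ids = set(table.loc[pat, "subject"].astype(str))
    rows = []
    for roi in config.nesting_rois:
        sub = nesting[(nesting["roi"] == roi)
                      & nesting["subject"].isin(pat_ids)]
        sub = sub.set_index("subject").loc[
            table.loc[pat, "subject"].astype(str)]
        r, p = pearson_with_p(sub["abs_r"].to_numpy(), vas)
        rows.append({"roi": roi, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Serialization


def _statmap_frame(sm: StatMap) -> pd.DataFrame:
    return pd.DataFrame({"voxel": np.arange(sm.stat.size), "stat": sm.stat,
                         "p_corrected": sm.p_corrected,
                         "significant": sm.significant})


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write the result bundle as TSV files plus a metadata JSON."""
    out = Path(out_dir)
    group_dir = out / "group"
    group_dir.mkdir(parents=True, exist_ok=True)
    for band, sm in result.group_maps.items():
        _statmap_frame(sm).to_csv(group_dir / f"contrast_{band}.tsv",
                                  sep="\t", index=False, float_format="%.6g")
    for col, per_band in result.corr_maps.items():
        for band, sm in per_band.items():
            _statmap_frame(sm).to_csv(group_dir / f"corr_{col}_{band}.tsv",
                                      sep="\t", index=False, float_format="%.6g")
    result.anova.to_csv(group_dir / "roi_anova.tsv", sep="\t", index=False,
                        float_format="%.6g")
    result.lps_group.to_csv(group_dir / "lps_group.tsv", sep="\t", index=False,
                            float_format="%.6g")
    result.nesting.to_csv(group_dir / "nesting.tsv", sep="\t", index=False,
                          float_format="%.6g")
    result.nesting_behavior.to_csv(group_dir / "nesting_vs_vas.tsv", sep="\t",
                                   index=False, float_format="%.6g")
    result.table.to_csv(out / "cohort.tsv", sep="\t", index=False)
    meta = {
        "version": __version__,
        "config": asdict(result.config),
        "n_voxels": result.grid.n_voxels,
        "rois": {k: int(v.size) for k, v in result.atlas.rois.items()},
        "flagged_subjects": result.flagged_subjects,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1, default=str))


def run_from_manifest(manifest_path: str | Path,
                      out_dir: str | Path | None = None) -> PipelineResult:
    """Run from a JSON manifest on disk.

    The manifest holds ``subjects`` (list of objects with ``id``,
    ``file``, ``group`` and behavioral fields) and optional ``params``
    overriding :class:`PipelineConfig` fields (``seed`` is required).
    Relative file paths resolve against the manifest's directory.
    """
    path = Path(manifest_path)
    spec = json.loads(path.read_text())
    params = dict(spec.get("params", {}))
    for key in ("shell_radii", "conductivities", "band", "nesting_rois"):
        if key in params:
            params[key] = tuple(params[key])
    config = PipelineConfig(**params)
    rows, recs = [], []
    for sub in spec["subjects"]:
        fpath = Path(sub["file"])
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        recs.append(load_recording(fpath))
        rows.append({"subject": sub["id"], "group": sub["group"],
                     **{k: sub.get(k, np.nan) for k in
                        ("vas_intensity", "vas_discomfort", "dhi",
                         "hads_a", "hads_d")}})
    table = pd.DataFrame(rows)
    return run_pipeline(recs, table, config, out_dir=out_dir)
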