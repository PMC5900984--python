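"""End-to-end orchestration: load -> segment -> noise -> ADC maps ->
ROI-averaged microstructure fits -> bootstrap -> reports.

The pipeline mirrors the analysis sequence used for the microsphere phantom:
per-Delta ML ADC maps (phantom and free-water control), then whole-ROI
averaged signals normalized per Delta, filtered at 2 * S_noise, fitted with
all parameters free and with D fixed to the median free-water ADC at the
shortest diffusion time, each followed by a Delta-stratified residual
bootstrap.  Every random draw flows from the config seed; reports carry the
seeds, thresholds and exclusions so a run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .estimation import (
    ModelFitResult,
    NoiseEstimate,
    estimate_noise,
    filter_low_signals,
    fit_adc_ml,
    fit_microstructure,
    fit_microstructure_voxelwise,
    normalize_per_delta,
    roi_average_signals,
)
from .phantom import LABELS, SyntheticDataset
from .protocol import Protocol, read_protocol_table, validate_protocol
from .segment import segment_phantom
from .uncertainty import (
    BootstrapResult,
    StabilityReport,
    cov_percent,
    repeatability_metrics,
    residual_bootstrap,
    two_sample_ttest,
)

__all__ = ["PipelineConfig", "run_full_pipeline", "run_stability_analysis"]

log = logging.getLogger("dwiphantom.pipeline")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_full_pipeline`.

    Either pass a :class:`SyntheticDataset` to the runner or set the input
    paths.  ``normalize_order`` selects whether ROI signals are averaged
    before per-Delta normalization (default) or normalized per voxel first.
    """

    volume_path: str | None = None
    protocol_path: str | None = None
    labels_path: str | None = None
    output_dir: str | None = None
    n_starts: int = 100
    bootstrap_B: int = 1000
    bootstrap_starts: int = 10
    seed: int = 0
    drop_longest_delta: bool = False
    voxelwise: bool = False
    voxelwise_n_starts: int = 10
    normalize_order: str = "average-then-normalize"
    background_erosion: int = 3

    def __post_init__(self) -> None:
        if self.normalize_order not in ("average-then-normalize", "normalize-then-average"):
            raise ValueError(f"unknown normalize_order {self.normalize_order!r}")


def _load_inputs(cfg: PipelineConfig) -> tuple[np.ndarray, Protocol, np.ndarray | None]:
    import nibabel as nib

    if cfg.volume_path is None or cfg.protocol_path is None:
        raise ValueError("config must provide volume_path and protocol_path (or pass a dataset)")
    volume = np.asarray(nib.load(cfg.volume_path).dataobj, dtype=float)
    protocol = read_protocol_table(cfg.protocol_path)
    labels = None
    if cfg.labels_path is not None:
        labels = np.asarray(nib.load(cfg.labels_path).dataobj).astype(np.int8)
    return volume, protocol, labels


def _roi_signal_vector(
    volume: np.ndarray, mask: np.ndarray, protocol: Protocol, order: str
):
    """ROI signal vector, honoring the configured average/normalize order."""
    if order == "average-then-normalize":
        mean_raw = roi_average_signals(volume, mask)
        return normalize_per_delta(mean_raw, protocol)
    # normalize each voxel first, then average the normalized values; keep the
    # averaged raw magnitudes for the 2*S_noise exclusion rule
    voxels = volume[mask]
    normalized = np.stack(
        [normalize_per_delta(v, protocol).values for v in voxels]
    ).mean(axis=0)
    nset = normalize_per_delta(roi_average_signals(volume, mask), protocol)
    return type(nset)(
        measurements=nset.measurements,
        values=normalized,
        raw=nset.raw,
        fit_mask=nset.fit_mask,
        gamma=nset.gamma,
    )


def _fit_and_bootstrap(
    nset, mode: str, fixed_D: float | None, cfg: PipelineConfig, seed_offset: int
) -> tuple[ModelFitResult, BootstrapResult]:
    fit = fit_microstructure(
        nset, mode=mode, fixed_D=fixed_D, n_starts=cfg.n_starts,
        seed=cfg.seed + seed_offset,
    )
    boot = residual_bootstrap(
        fit, nset, B=cfg.bootstrap_B, seed=cfg.seed + seed_offset + 1,
        n_starts=cfg.bootstrap_starts,
    )
    return fit, boot


def _fit_record(fit: ModelFitResult, boot: BootstrapResult | None) -> dict[str, Any]:
    rec: dict[str, Any] = {
        "mode": fit.mode,
        "R": fit.params.R,
        "f_i": fit.params.f_i,
        "D": fit.params.D,
        "objective": fit.objective,
        "r_squared": fit.r_squared,
        "at_bound": fit.at_bound,
        "n_starts": fit.n_starts,
        "seed": fit.seed,
    }
    if boot is not None:
        rec["ci_lower"] = boot.ci_lower
        rec["ci_upper"] = boot.ci_upper
        rec["correlations"] = {
            f"{a}_{b}": float(boot.correlations[i, j])
            for i, a in enumerate(boot.param_names)
            for j, b in enumerate(boot.param_names)
            if j > i
        }
        rec["bootstrap_B"] = boot.B
        rec["bootstrap_dropped"] = boot.n_dropped
    return rec


def run_full_pipeline(
    cfg: PipelineConfig, dataset: SyntheticDataset | None = None
) -> dict[str, Any]:
    """Run the complete analysis; return (and optionally write) the output bundle.

    The bundle maps stage names to results: ``noise`` (NoiseEstimate),
    ``adc`` (per-region, per-Delta median ADC + maps), ``fits`` (point
    estimates, CIs, correlations for each mode), ``exclusions``, and
    ``voxelwise`` when enabled.  With ``cfg.output_dir`` set, CSV/JSON reports
    and NIfTI maps are written under ``maps/`` and ``reports/``.
    """
    if dataset is not None:
        volume, protocol, labels = dataset.volume, dataset.protocol, dataset.label_map
    else:
        volume, protocol, labels = _load_inputs(cfg)
    validate_protocol(protocol, n_volumes=volume.shape[-1], require_normalization=True)

    # --- masks -----------------------------------------------------------
    if labels is None:
        b0_idx = int(np.nonzero(protocol.G_values == 0)[0][0])
        seg = segment_phantom(volume[..., b0_idx])
        labels = seg.label_map
        log.info("segmented phantom: thresholds %.3g / %.3g",
                 seg.foreground_threshold, seg.water_threshold)
    phantom_mask = labels == LABELS["phantom"]
    control_mask = labels == LABELS["control_water"]
    water_mask = (labels >= 2)
    if not control_mask.any():
        control_mask = water_mask  # segmentation does not tell tubes apart
    if not phantom_mask.any():
        raise RuntimeError("stage masks: empty phantom ROI")
    background = labels == LABELS["background"]
    if cfg.background_erosion:
        # erode in-plane only (slices are thin); keeps tube-edge partial
        # volumes out of the noise ROI
        structure = np.ones((3, 3, 1), dtype=bool)
        background = ndimage.binary_erosion(
            background, structure=structure, iterations=cfg.background_erosion
        )
    if not background.any():
        raise RuntimeError("stage masks: background ROI empty after erosion")

    # --- noise -----------------------------------------------------------
    noise = estimate_noise(volume, background, phantom_mask, protocol)
    log.info("noise: sigma=%.4g SNR=%.3g", noise.sigma, noise.SNR)

    # --- per-Delta ADC maps ---------------------------------------------
    adc_region = phantom_mask | water_mask
    b = protocol.b_values
    adc_maps: dict[float, np.ndarray] = {}
    adc_median: dict[str, dict[float, float]] = {"phantom": {}, "control_water": {}}
    for Delta, idx in protocol.delta_groups().items():
        if np.unique(b[idx]).size < 3:
            continue  # not an ADC ladder (e.g. single non-zero G)
        sub = volume[..., idx]
        fitres = fit_adc_ml(sub[adc_region], b[idx], noise.sigma)
        amap = np.full(labels.shape, np.nan)
        amap[adc_region] = np.where(fitres.converged, fitres.ADC, np.nan)
        adc_maps[Delta] = amap
        adc_median["phantom"][Delta] = float(np.nanmedian(amap[phantom_mask]))
        adc_median["control_water"][Delta] = float(np.nanmedian(amap[control_mask]))
    if not adc_maps:
        raise RuntimeError("stage adc: no Delta group has >= 3 distinct b-values")

    # --- fixed D from the water control at the shortest diffusion time ---
    shortest = min(adc_median["control_water"])
    fixed_D = adc_median["control_water"][shortest]

    # --- ROI-averaged microstructure fits --------------------------------
    nset_full = _roi_signal_vector(volume, phantom_mask, protocol, cfg.normalize_order)
    nset, exclusions = filter_low_signals(nset_full, noise.S_noise)
    log.info("exclusions: %d of %d entries below 2*S_noise",
             len(exclusions.excluded), exclusions.total)

    fits: dict[str, dict[str, Any]] = {}
    fit_free, boot_free = _fit_and_bootstrap(nset, "all-free", None, cfg, 10)
    fits["all-free"] = _fit_record(fit_free, boot_free)
    fit_fixed, boot_fixed = _fit_and_bootstrap(nset, "fixed-D", fixed_D, cfg, 20)
    fits["fixed-D"] = _fit_record(fit_fixed, boot_fixed)
    if cfg.drop_longest_delta:
        nsub = nset.drop_longest_delta()
        fit_sub = fit_microstructure(
            nsub, mode="all-free", n_starts=cfg.n_starts, seed=cfg.seed + 30
        )
        rec = _fit_record(fit_sub, None)
        rec["subset"] = sorted({m.Delta for m in nsub.measurements})
        fits["all-free-short-deltas"] = rec

    bundle: dict[str, Any] = {
        "noise": noise,
        "adc": {"maps": adc_maps, "median": adc_median},
        "fixed_D": fixed_D,
        "fits": fits,
        "exclusions": exclusions,
        "fit_objects": {"all-free": (fit_free, boot_free), "fixed-D": (fit_fixed, boot_fixed)},
        "masks": {"phantom": phantom_mask, "water": water_mask, "control": control_mask},
    }

    # --- optional voxelwise microstructure fitting -----------------------
    if cfg.voxelwise:
        maps, summary = fit_microstructure_voxelwise(
            volume, phantom_mask, protocol, mode="all-free",
            n_starts=cfg.voxelwise_n_starts, seed=cfg.seed + 40,
            S_noise=noise.S_noise,
        )
        bundle["voxelwise"] = {"maps": maps, "summary": summary}
        log.info("voxelwise: at-bound fractions %s", summary.at_bound_fraction)

    if cfg.output_dir is not None:
        _write_outputs(Path(cfg.output_dir), cfg, bundle, protocol)
    return bundle


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_outputs(
    out_dir: Path, cfg: PipelineConfig, bundle: dict[str, Any], protocol: Protocol
) -> None:
    import nibabel as nib

    maps_dir = out_dir / "maps"
    reports_dir = out_dir / "reports"
    maps_dir.mkdir(parents=True, exist_ok=True)
    reports_dir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    # uncompressed NIfTI keeps outputs byte-stable across runs
    for Delta, amap in bundle["adc"]["maps"].items():
        nib.save(
            nib.Nifti1Image(amap.astype(np.float32), affine),
            maps_dir / f"adc_delta{Delta:g}.nii",
        )
    if "voxelwise" in bundle:
        for name, vmap in bundle["voxelwise"]["maps"].items():
            nib.save(
                nib.Nifti1Image(np.asarray(vmap, dtype=np.float32), affine),
                maps_dir / f"{name}.nii",
            )

    rows = []
    for mode, rec in bundle["fits"].items():
        row = {"mode": mode}
        for key in ("R", "f_i", "D", "objective", "r_squared", "n_starts", "seed"):
            row[key] = rec[key]
        rows.append(row)
    pd.DataFrame(rows).to_csv(reports_dir / "fit_summary.csv", index=False, float_format="%.10g")

    noise: NoiseEstimate = bundle["noise"]
    report = {
        # analysis parameters only; input/output paths vary across hosts and
        # would break byte-level reproducibility of the report
        "config": {
            k: v
            for k, v in asdict(cfg).items()
            if not k.endswith(("_path", "_dir"))
        },
        "noise": {
            "sigma": noise.sigma,
            "S_bg": noise.S_bg,
            "S_noise": noise.S_noise,
            "SNR": noise.SNR,
            "snr_per_delta": noise.snr_per_delta,
        },
        "adc_median": bundle["adc"]["median"],
        "fixed_D": bundle["fixed_D"],
        "fits": bundle["fits"],
        "exclusions": {
            "threshold": bundle["exclusions"].threshold,
            "excluded_G_Delta": list(bundle["exclusions"].excluded),
            "retained": bundle["exclusions"].retained,
            "total": bundle["exclusions"].total,
        },
    }
    if "voxelwise" in bundle:
        s = bundle["voxelwise"]["summary"]
        report["voxelwise"] = {
            "at_bound_fraction": s.at_bound_fraction,
            "median_iqr_all": s.median_iqr_all,
            "median_iqr_excluding_bound": s.median_iqr_excluding_bound,
            "n_voxels": s.n_voxels,
        }
    (reports_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def run_stability_analysis(sessions: Sequence[dict[str, Any]]) -> StabilityReport:
    """Longitudinal stability statistics over per-session summaries.

    Each session dict may carry ``median_adc`` ({Delta: ADC} for the phantom),
    ``median_adc_water``, per-mode parameter estimates under ``params`` (e.g.
    {"all-free": {"R": ..., "f_i": ..., "D": ...}}), and ``repeat_adc`` as a
    (first, repeat) pair for the short-term repeat scan.  Returns per-quantity
    CoVs, a shortest-vs-longest-Delta ADC t-test (phantom and water), and the
    mean absolute percentage difference over repeat pairs.
    """
    if len(sessions) < 2:
        raise ValueError("need at least 2 sessions for a stability analysis")
    rows = []
    for i, s in enumerate(sessions):
        row: dict[str, Any] = {"session": i}
        for Delta, v in s.get("median_adc", {}).items():
            row[f"adc_phantom_{Delta:g}"] = v
        for Delta, v in s.get("median_adc_water", {}).items():
            row[f"adc_water_{Delta:g}"] = v
        for mode, params in s.get("params", {}).items():
            for name, v in params.items():
                row[f"{name}_{mode}"] = v
        if "repeat_adc" in s:
            row["repeat_first"], row["repeat_second"] = s["repeat_adc"]
        rows.append(row)
    table = pd.DataFrame(rows)

    cov: dict[str, float] = {}
    for col in table.columns:
        if col in ("session", "repeat_first", "repeat_second"):
            continue
        vals = table[col].dropna().to_numpy()
        if vals.size >= 2 and vals.mean() != 0:
            cov[col] = cov_percent(vals)

    ttests: dict[str, tuple[float, float]] = {}
    for region in ("phantom", "water"):
        cols = sorted(
            (float(c.rsplit("_", 1)[1]), c)
            for c in table.columns
            if c.startswith(f"adc_{region}_")
        )
        if len(cols) >= 2:
            a = table[cols[0][1]].dropna().to_numpy()
            z = table[cols[-1][1]].dropna().to_numpy()
            if a.size >= 2 and z.size >= 2:
                ttests[f"adc_{region}_shortest_vs_longest"] = two_sample_ttest(a, z)

    repeat = None
    if {"repeat_first", "repeat_second"} <= set(table.columns):
        pairs = table[["repeat_first", "repeat_second"]].dropna().to_numpy()
        if len(pairs):
            repeat = repeatability_metrics(pairs)
            if len(pairs) >= 2:
                ttests["repeat_first_vs_second"] = two_sample_ttest(pairs[:, 0], pairs[:, 1])
    return StabilityReport(table=table, cov=cov, ttests=ttests, repeatability=repeat)
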