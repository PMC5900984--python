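"""Synthetic DW-MRI phantom generator and ground-truth bookkeeping.

Emulates a hollow-microsphere tumor-mimicking phantom imaged in a water-filled
NMR tube alongside a water-only control tube: on axial slices the phantom
material appears as an annulus (hollow cylinder) with free water in its core,
and the control tube is a disjoint water disc.  Phantom voxels follow the
two-compartment restricted/hindered model; water voxels decay
mono-exponentially; magnitudes are Rician-corrupted.

Defaults mirror the acquisition geometry the package targets: 30 x 30 mm FOV,
128 x 128 matrix, 10 x 1 mm axial slices, annulus inner/outer diameters
1.8/3 mm.  Amplitude differences between Delta acquisitions (TE grows with
Delta) are emulated with a mono-exponential T2 amplitude factor, which is what
the per-Delta normalization in the estimation pipeline is designed to remove.
Ground truth defaults are homogeneous (R = 5.2 um, f_i = 0.35,
D = 2.0 um^2/ms); optional truncated-Gaussian jitter on (R, f_i) supports
voxelwise-fitting experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .protocol import Protocol, write_protocol_table
from .signals import FIT_BOUNDS, MicrostructureParams, TwoCompartmentModel

__all__ = [
    "LABELS",
    "PhantomGeometry",
    "SyntheticDataset",
    "build_geometry",
    "add_rician_noise",
    "simulate_dataset",
    "simulate_roi_signals",
    "save_dataset",
]

#: Label-map codes.
LABELS = {"background": 0, "phantom": 1, "core_water": 2, "control_water": 3}


@dataclass(frozen=True)
class PhantomGeometry:
    """Discretized phantom cross-section with annulus, core and control tube."""

    matrix: int
    fov: float                      # mm
    n_slices: int
    slice_thickness: float          # mm
    inner_diameter: float           # mm, annulus
    outer_diameter: float           # mm, annulus
    annulus_center: tuple[float, float]   # mm, in-plane
    control_center: tuple[float, float]   # mm
    control_radius: float           # mm
    label_map: np.ndarray = field(repr=False)   # (matrix, matrix, n_slices) int8

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        d = self.fov / self.matrix
        return (d, d, self.slice_thickness)

    def mask(self, name: str) -> np.ndarray:
        return self.label_map == LABELS[name]


def build_geometry(
    matrix: int = 128,
    fov: float = 30.0,
    n_slices: int = 10,
    slice_thickness: float = 1.0,
    inner_diameter: float = 1.8,
    outer_diameter: float = 3.0,
    annulus_center: tuple[float, float] = (-7.0, 0.0),
    control_center: tuple[float, float] = (7.0, 0.0),
    control_radius: float = 2.1,
) -> PhantomGeometry:
    """Build the label map for the annular phantom plus a water control tube.

    The annulus (phantom material) spans ``inner_diameter``..``outer_diameter``
    around ``annulus_center``; its interior is free core water.  The control
    tube is a disjoint water disc (default radius matches the inner bore of a
    5 mm NMR tube).  A voxel is labelled by its center position.
    """
    if matrix <= 0 or fov <= 0 or n_slices <= 0 or slice_thickness <= 0:
        raise ValueError("geometry dimensions must be positive")
    if inner_diameter >= outer_diameter:
        raise ValueError(
            f"inner diameter {inner_diameter} must be < outer diameter {outer_diameter}"
        )
    sep = np.hypot(
        control_center[0] - annulus_center[0], control_center[1] - annulus_center[1]
    )
    if sep < outer_diameter / 2.0 + control_radius:
        raise ValueError("control tube overlaps the phantom tube")
    half = fov / 2.0
    coords = (np.arange(matrix) + 0.5) * (fov / matrix) - half
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    r_phantom = np.hypot(X - annulus_center[0], Y - annulus_center[1])
    r_control = np.hypot(X - control_center[0], Y - control_center[1])
    plane = np.zeros((matrix, matrix), dtype=np.int8)
    plane[r_phantom <= inner_diameter / 2.0] = LABELS["core_water"]
    ring = (r_phantom > inner_diameter / 2.0) & (r_phantom <= outer_diameter / 2.0)
    plane[ring] = LABELS["phantom"]
    plane[r_control <= control_radius] = LABELS["control_water"]
    label_map = np.repeat(plane[:, :, None], n_slices, axis=2)
    return PhantomGeometry(
        matrix=matrix,
        fov=fov,
        n_slices=n_slices,
        slice_thickness=slice_thickness,
        inner_diameter=inner_diameter,
        outer_diameter=outer_diameter,
        annulus_center=annulus_center,
        control_center=control_center,
        control_radius=control_radius,
        label_map=label_map,
    )


def add_rician_noise(
    signal: np.ndarray | float,
    sigma: float,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray | float:
    """Rician-corrupt noiseless magnitudes: sqrt((S + n1)^2 + n2^2).

    ``n1``, ``n2`` are independent zero-mean Gaussians of SD ``sigma`` from a
    seeded stream; ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma}")
    if sigma == 0:
        return signal
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = np.asarray(signal, dtype=float)
    n1 = rng.normal(0.0, sigma, s.shape)
    n2 = rng.normal(0.0, sigma, s.shape)
    out = np.sqrt((s + n1) ** 2 + n2**2)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class SyntheticDataset:
    """4D magnitude volume with its protocol, ground truth and masks."""

    volume: np.ndarray              # (nx, ny, nz, K)
    protocol: Protocol
    geometry: PhantomGeometry
    truth: dict[str, np.ndarray]    # parameter maps over non-background voxels
    sigma: float
    seed: int

    @property
    def label_map(self) -> np.ndarray:
        return self.geometry.label_map


def _te_scales(protocol: Protocol, t2: float | None) -> np.ndarray:
    """Per-measurement amplitude factors exp(-(TE - TE_min)/T2); 1 where TE absent."""
    scales = np.ones(len(protocol))
    if t2 is None:
        return scales
    tes = [m.TE for m in protocol]
    known = [te for te in tes if te is not None]
    if not known:
        return scales
    te_min = min(known)
    for i, te in enumerate(tes):
        if te is not None:
            scales[i] = np.exp(-(te - te_min) / t2)
    return scales


def simulate_dataset(
    geometry: PhantomGeometry,
    protocol: Protocol,
    params: MicrostructureParams = MicrostructureParams(R=5.2, f_i=0.35, D=2.0),
    D_free: float = 2.0,
    S0: float = 100.0,
    phantom_s0_fraction: float = 0.65,
    snr: float = 25.0,
    sigma: float | None = None,
    t2_ms: float | None = 85.0,
    jitter_R: float = 0.0,
    jitter_fi: float = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a 4D magnitude dataset over the phantom geometry.

    Phantom voxels follow ``S0 * phantom_s0_fraction * scale(TE) * S/S0(model)``;
    water voxels (core and control) follow ``S0 * scale(TE) * exp(-b D_free)``;
    background is zero before noise.  ``phantom_s0_fraction`` < 1 reflects the
    reduced water content of the sphere-packed material, which is also what
    lets intensity-based segmentation separate phantom from free water on the
    b = 0 image.

    The noise SD defaults to ``S0 * phantom_s0_fraction / snr`` so that the
    phantom-ROI SNR at the shortest TE equals ``snr``; with the default T2
    amplitude model the SNR at the longest Delta of the reference protocols
    falls to about 0.68 * snr.  Pass ``sigma`` to override directly.

    ``jitter_R``/``jitter_fi`` add per-voxel Gaussian spread (SD in the
    parameter's units) truncated to the fit constraint box, for voxelwise
    experiments; defaults are homogeneous truth.
    """
    rng = np.random.default_rng(seed)
    labels = geometry.label_map
    nx, ny, nz = labels.shape
    K = len(protocol)
    scales = _te_scales(protocol, t2_ms)
    b = protocol.b_values
    if sigma is None:
        sigma = S0 * phantom_s0_fraction / snr
    model = TwoCompartmentModel(protocol, gamma=protocol.gamma)

    phantom_mask = labels == LABELS["phantom"]
    water_mask = (labels == LABELS["core_water"]) | (labels == LABELS["control_water"])
    n_phantom = int(phantom_mask.sum())
    if n_phantom == 0:
        raise ValueError("geometry has no phantom voxels")

    truth: dict[str, np.ndarray] = {}
    R_map = np.full(labels.shape, np.nan)
    f_map = np.full(labels.shape, np.nan)
    D_map = np.full(labels.shape, np.nan)
    if jitter_R > 0 or jitter_fi > 0:
        lo_R, hi_R = FIT_BOUNDS["R"]
        lo_f, hi_f = FIT_BOUNDS["f_i"]
        R_vox = np.clip(rng.normal(params.R, jitter_R, n_phantom), lo_R, hi_R)
        f_vox = np.clip(rng.normal(params.f_i, jitter_fi, n_phantom), lo_f, hi_f)
    else:
        R_vox = np.full(n_phantom, params.R)
        f_vox = np.full(n_phantom, params.f_i)
    R_map[phantom_mask] = R_vox
    f_map[phantom_mask] = f_vox
    D_map[phantom_mask] = params.D
    D_map[water_mask] = D_free
    truth["R"] = R_map
    truth["f_i"] = f_map
    truth["D"] = D_map

    volume = np.zeros((nx, ny, nz, K))
    # phantom: evaluate the model once per distinct (R, f_i) pair
    distinct, inverse = np.unique(
        np.column_stack([R_vox, f_vox]), axis=0, return_inverse=True
    )
    preds = np.array([model.predict(R, f, params.D) for R, f in distinct])
    volume[phantom_mask] = S0 * phantom_s0_fraction * scales * preds[inverse]
    volume[water_mask] = S0 * scales * np.exp(-b * D_free * 1e-3)
    noisy = add_rician_noise(volume, sigma, rng)
    return SyntheticDataset(
        volume=noisy,
        protocol=protocol,
        geometry=geometry,
        truth=truth,
        sigma=float(sigma),
        seed=seed,
    )


def simulate_roi_signals(
    protocol: Protocol,
    params: MicrostructureParams = MicrostructureParams(R=5.2, f_i=0.35, D=2.0),
    snr: float = 25.0,
    S0: float = 1.0,
    t2_ms: float | None = 85.0,
    seed: int = 0,
) -> np.ndarray:
    """One noisy realization of ROI-level raw signals for a protocol.

    Amplitudes are ``S0 * scale(TE) * S/S0(model)`` with Rician noise of SD
    ``S0 / snr``; the SNR therefore equals ``snr`` at the shortest TE and
    decreases with the T2 amplitude factor at longer Delta, matching the 4D
    generator's convention.
    """
    rng = np.random.default_rng(seed)
    model = TwoCompartmentModel(protocol, gamma=protocol.gamma)
    scales = _te_scales(protocol, t2_ms)
    clean = S0 * scales * model.predict(params.R, params.f_i, params.D)
    return np.asarray(add_rician_noise(clean, S0 / snr, rng))


def save_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic dataset as NIfTI volumes + protocol table + truth JSON."""
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(dataset.geometry.voxel_size) + [1.0])
    paths = {}
    vol = nib.Nifti1Image(dataset.volume.astype(np.float32), affine)
    paths["volume"] = out_dir / "dwi.nii.gz"
    nib.save(vol, paths["volume"])
    lab = nib.Nifti1Image(dataset.label_map.astype(np.int16), affine)
    paths["labels"] = out_dir / "labels.nii.gz"
    nib.save(lab, paths["labels"])
    paths["protocol"] = out_dir / "protocol.csv"
    write_protocol_table(dataset.protocol, paths["protocol"])
    g = dataset.geometry
    record = {
        "sigma": dataset.sigma,
        "seed": dataset.seed,
        "geometry": {
            "matrix": g.matrix,
            "fov": g.fov,
            "n_slices": g.n_slices,
            "slice_thickness": g.slice_thickness,
            "inner_diameter": g.inner_diameter,
            "outer_diameter": g.outer_diameter,
        },
        "truth_median": {
            k: float(np.nanmedian(v)) for k, v in dataset.truth.items()
        },
    }
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(record, indent=2, sort_keys=True))
    return paths
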