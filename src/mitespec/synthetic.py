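"""Seeded generator of synthetic hyperspectral leaf scenes.

The raw greenhouse images behind leaf-level mite-detection studies are
rarely released, so this module fabricates scenes with the statistical
structure the analysis pipeline assumes:

* a typical leaf reflectance curve -- low visible floor, local green
  maximum near 550 nm, chlorophyll absorption trough near 680 nm, a
  steep red-edge rise between 690 and 740 nm and a high NIR plateau;
* infestation as small additive reflectance increases confined to the
  green and NIR regions (band deltas on the order of 0.002-0.025),
  applied in spatial hotspots whose coverage grows with severity;
* per-pixel multiplicative illumination variation, additive band noise,
  mild leaf-to-leaf variability of the spectral shape, and a flat dark
  background whose NDVI stays far below any leaf threshold.

All randomness flows from one master seed through
``numpy.random.SeedSequence`` spawning, so every fixture is
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cube_io import HyperCube, WavelengthGrid, make_grid, write_envi
from .segmentation import SegmentationParams, make_roi, mask_to_png
from .signatures import (
    LabeledDataset,
    SpectralSignature,
    extract_rss,
    mean_signature,
    smooth_spectrum,
    snv,
)

__all__ = [
    "HealthySpectrumParams",
    "InfestationParams",
    "SceneParams",
    "DEFAULT_GRID",
    "DEFAULT_SEVERITY_SCHEDULE",
    "healthy_signature",
    "infested_signature",
    "make_leaf_mask",
    "render_cube",
    "cube_to_mnss",
    "generate_dataset",
    "dataset_from_envi_manifest",
]

#: the camera band grid: 502-950 nm at a 4 nm step (113 bands)
DEFAULT_GRID = make_grid(502.0, 950.0, 4.0)

#: severity levels emulating a steady symptom progression over 14 days
DEFAULT_SEVERITY_SCHEDULE: tuple[float, ...] = tuple(0.6 + 0.4 * d / 14.0 for d in range(1, 15))


def _smoothstep(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    t = np.clip((np.asarray(x, dtype=np.float64) - lo) / (hi - lo), 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


@dataclass(frozen=True)
class HealthySpectrumParams:
    """Shape parameters of the healthy-leaf reflectance curve (all nm / reflectance units)."""

    floor: float = 0.05            # visible baseline reflectance
    green_amp: float = 0.05        # green peak height above the floor
    green_center: float = 550.0
    green_width: float = 30.0      # Gaussian sigma
    trough_depth: float = 0.02     # chlorophyll absorption dip
    trough_center: float = 680.0
    trough_width: float = 12.0
    red_edge_center: float = 715.0
    red_edge_width: float = 8.0    # logistic scale of the red-edge rise
    nir_amp: float = 0.40          # NIR plateau height above the floor
    nir_tilt: float = 0.0          # relative plateau slope over the NIR span


def healthy_signature(
    grid: WavelengthGrid = DEFAULT_GRID,
    params: HealthySpectrumParams = HealthySpectrumParams(),
) -> SpectralSignature:
    """Healthy-leaf reflectance spectrum on the grid.

    ``r(l) = floor + green bump - absorption trough + plateau * logistic``;
    parameter combinations that push any band outside (0, 1) are rejected.
    """
    lam = grid.centers.astype(np.float64)
    green = params.green_amp * np.exp(
        -0.5 * ((lam - params.green_center) / params.green_width) ** 2
    )
    trough = params.trough_depth * np.exp(
        -0.5 * ((lam - params.trough_center) / params.trough_width) ** 2
    )
    edge = params.nir_amp / (
        1.0 + np.exp(-(lam - params.red_edge_center) / params.red_edge_width)
    )
    if params.nir_tilt:
        # mild linear tilt of the plateau, pivoting at the NIR midpoint
        edge *= 1.0 + params.nir_tilt * (lam - 845.0) / 105.0
    values = params.floor + green - trough + edge
    if values.min() <= 0 or values.max() >= 1:
        raise ValueError("spectrum parameters produce reflectance outside (0, 1)")
    return SpectralSignature(grid, values, "RSS")


@dataclass(frozen=True)
class InfestationParams:
    """Additive reflectance increase caused by mite feeding.

    The green component is a Gaussian bump tapered to exactly zero above
    ``green_cut_hi``; the NIR component is a smooth ramp that switches on
    between ``nir_ramp_lo`` and ``nir_ramp_hi``.  Both are scaled by the
    severity in [0, 1], and neither touches the 680 nm absorption band.
    Hotspot parameters control the spatial symptom coverage.
    """

    green_delta: float = 0.032     # peak green increase inside a hotspot at severity 1
    green_center: float = 550.0
    green_width: float = 20.0
    green_cut_lo: float = 600.0    # taper window upper green boundary
    green_cut_hi: float = 640.0
    nir_delta: float = 0.035       # NIR plateau increase inside a hotspot at severity 1
    nir_ramp_lo: float = 740.0
    nir_ramp_hi: float = 780.0
    # hotspot geometry: coverage fraction grows with severity
    base_fraction: float = 0.20
    fraction_slope: float = 0.60
    radius_min: float = 2.0
    radius_growth: float = 8.0

    def __post_init__(self) -> None:
        if self.green_delta < 0 or self.nir_delta < 0:
            raise ValueError("infestation deltas must be non-negative")

    def delta(self, grid: WavelengthGrid, severity: float) -> np.ndarray:
        """Per-band additive reflectance increase at the given severity."""
        if not 0.0 <= severity <= 1.0:
            raise ValueError("severity must lie in [0, 1]")
        lam = grid.centers.astype(np.float64)
        green = self.green_delta * np.exp(
            -0.5 * ((lam - self.green_center) / self.green_width) ** 2
        ) * (1.0 - _smoothstep(lam, self.green_cut_lo, self.green_cut_hi))
        nir = self.nir_delta * _smoothstep(lam, self.nir_ramp_lo, self.nir_ramp_hi)
        return severity * (green + nir)

    def target_fraction(self, severity: float) -> float:
        """Leaf-area fraction covered by symptom hotspots."""
        return min(0.95, self.base_fraction + self.fraction_slope * severity)


def infested_signature(
    healthy: SpectralSignature,
    params: InfestationParams = InfestationParams(),
    severity: float = 1.0,
) -> SpectralSignature:
    """Healthy spectrum plus the severity-scaled infestation delta."""
    return SpectralSignature(
        healthy.grid, healthy.values + params.delta(healthy.grid, severity), "RSS"
    )


@dataclass(frozen=True)
class SceneParams:
    """Geometry and noise of one 50 x 50 synthetic snapshot."""

    width: int = 50
    height: int = 50
    ellipse_a: float = 17.0        # semi-axes of the leaf ellipse (pixels)
    ellipse_b: float = 12.0
    ellipse_jitter: float = 0.08   # relative sd of the per-leaf axis jitter
    center_jitter: float = 2.0     # uniform center displacement (pixels)
    rotate: bool = True
    notch_radius: float = 4.0      # stem notch cut out of the ellipse edge
    background_reflectance: float = 0.05
    illumination_sigma: float = 0.05   # per-pixel multiplicative gain sd
    noise_sigma: float = 0.005         # per-band additive noise sd
    leaf_variability: float = 0.06     # leaf-to-leaf amplitude jitter (relative sd)
    shape_jitter_nm: float = 3.0       # sd of per-leaf green-peak / red-edge shifts
    nir_tilt_sd: float = 0.05          # sd of the per-leaf NIR plateau tilt


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def make_leaf_mask(params: SceneParams = SceneParams(), seed=0) -> np.ndarray:
    """Boolean mask of a randomly placed, optionally notched leaf ellipse."""
    rng = _as_rng(seed)
    a = params.ellipse_a * (1.0 + params.ellipse_jitter * rng.standard_normal())
    b = params.ellipse_b * (1.0 + params.ellipse_jitter * rng.standard_normal())
    cy = (params.height - 1) / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    cx = (params.width - 1) / 2.0 + rng.uniform(-params.center_jitter, params.center_jitter)
    theta = rng.uniform(0.0, np.pi) if params.rotate else 0.0
    r = max(a, b)
    if cy - r < -0.5 or cy + r > params.height - 0.5 or cx - r < -0.5 or cx + r > params.width - 0.5:
        raise ValueError("leaf ellipse does not fit the frame")
    yy, xx = np.mgrid[0:params.height, 0:params.width]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if params.notch_radius > 0:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        ny = cy + b * np.sin(phi - theta)
        nx = cx + a * np.cos(phi - theta)
        mask &= (yy - ny) ** 2 + (xx - nx) ** 2 > params.notch_radius ** 2
    if not mask.any():
        raise ValueError("leaf mask is empty")
    return mask


def _hotspot_mask(
    leaf: np.ndarray,
    inf_params: InfestationParams,
    severity: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Union of symptom disks covering about ``target_fraction`` of the leaf."""
    target = inf_params.target_fraction(severity)
    leaf_px = np.argwhere(leaf)
    hot = np.zeros_like(leaf)
    yy, xx = np.mgrid[0:leaf.shape[0], 0:leaf.shape[1]]
    for _ in range(200):
        cy, cx = leaf_px[rng.integers(leaf_px.shape[0])]
        radius = rng.uniform(
            inf_params.radius_min,
            inf_params.radius_min + inf_params.radius_growth * severity,
        )
        hot |= ((yy - cy) ** 2 + (xx - cx) ** 2 <= radius ** 2) & leaf
        if hot.sum() >= target * leaf_px.shape[0]:
            break
    return hot


def render_cube(
    mask: np.ndarray,
    healthy_sig: SpectralSignature,
    infested_sig: SpectralSignature | None,
    inf_params: InfestationParams = InfestationParams(),
    scene_params: SceneParams = SceneParams(),
    seed=0,
    severity: float = 0.0,
) -> tuple[HyperCube, dict]:
    """Render one snapshot from a leaf mask and its spectral signatures.

    Leaf pixels carry the healthy signature -- or, inside symptom
    hotspots, the infested one -- scaled by a per-pixel illumination gain
    ~ Normal(1, sigma_ill); background pixels carry a flat spectrum.
    Band-wise Normal(0, sigma_noise) noise is added everywhere and the
    result is clipped at zero.  Returns the cube plus a ground-truth
    dict with the leaf and hotspot masks.
    """
    grid = healthy_sig.grid
    rng = _as_rng(seed)
    h, w = mask.shape
    if severity > 0:
        if infested_sig is None:
            raise ValueError("severity > 0 requires an infested signature")
        hotspots = _hotspot_mask(mask, inf_params, severity, rng)
    else:
        hotspots = np.zeros_like(mask)

    values = np.empty((h, w, grid.n_bands), dtype=np.float64)
    values[:] = scene_params.background_reflectance
    values[mask] = healthy_sig.values
    values[hotspots] = infested_sig.values if infested_sig is not None else healthy_sig.values

    gain = np.ones((h, w))
    if scene_params.illumination_sigma > 0:
        gain += scene_params.illumination_sigma * rng.standard_normal((h, w))
    values[mask] *= gain[mask, None]
    if scene_params.noise_sigma > 0:
        values += scene_params.noise_sigma * rng.standard_normal(values.shape)
    np.clip(values, 0.0, None, out=values)
    cube = HyperCube(values.astype(np.float32), grid)
    return cube, {"leaf_mask": mask.copy(), "hotspot_mask": hotspots}


def cube_to_mnss(
    cube: HyperCube,
    seg_params: SegmentationParams = SegmentationParams(),
    smoothing_window: int = 7,
    smoothing_polyorder: int = 2,
) -> SpectralSignature:
    """Full per-snapshot pipeline: segment, extract, smooth, average, SNV."""
    roi = make_roi(cube, seg_params)
    rss = extract_rss(cube, roi)
    if smoothing_window > 1:
        rss = smooth_spectrum(rss, smoothing_window, smoothing_polyorder)
    mrss = mean_signature(rss, cube.grid)
    return snv(mrss)


def _leaf_params(
    base: HealthySpectrumParams, scene: SceneParams, rng: np.random.Generator
) -> HealthySpectrumParams:
    """Per-leaf jitter of the spectral shape.

    Component amplitudes get multiplicative jitter; the green peak and
    red-edge positions shift by a few nm (pigment-content variation) and
    the NIR plateau receives a small random tilt (leaf structure/water),
    so leaves differ in shape -- not just scale -- and the differences
    survive SNV normalization.
    """
    def jitter(x: float) -> float:
        return x * max(0.2, 1.0 + scene.leaf_variability * rng.standard_normal())

    return replace(
        base,
        floor=jitter(base.floor),
        green_amp=jitter(base.green_amp),
        trough_depth=jitter(base.trough_depth),
        nir_amp=jitter(base.nir_amp),
        green_center=base.green_center + scene.shape_jitter_nm * rng.standard_normal(),
        red_edge_center=base.red_edge_center + scene.shape_jitter_nm * rng.standard_normal(),
        nir_tilt=base.nir_tilt + scene.nir_tilt_sd * rng.standard_normal(),
    )


def generate_dataset(
    n_healthy: int = 220,
    n_infested: int = 220,
    severity_schedule: Sequence[float] = DEFAULT_SEVERITY_SCHEDULE,
    scene_params: SceneParams = SceneParams(),
    seed: int = 0,
    *,
    grid: WavelengthGrid = DEFAULT_GRID,
    healthy_params: HealthySpectrumParams = HealthySpectrumParams(),
    infestation_params: InfestationParams = InfestationParams(),
    seg_params: SegmentationParams = SegmentationParams(),
    smoothing_window: int = 7,
    smoothing_polyorder: int = 2,
    save_dir: str | Path | None = None,
) -> LabeledDataset:
    """Simulate snapshots and run them through the full signature pipeline.

    Produces ``n_healthy + n_infested`` SNV-normalized (MNSS) leaf
    signatures; infested leaves draw a severity from the schedule.
    Per-sample seeds are spawned deterministically from the master seed,
    so the same seed yields a bit-identical dataset.  With ``save_dir``
    each snapshot is also written as an ENVI cube (plus ground-truth
    PNGs and a ``manifest.csv``).
    """
    if n_healthy < 1 or n_infested < 1:
        raise ValueError("both classes need at least one sample")
    if not severity_schedule:
        raise ValueError("severity schedule must not be empty")
    schedule = np.asarray(severity_schedule, dtype=np.float64)

    n_total = n_healthy + n_infested
    children = np.random.SeedSequence(seed).spawn(n_total)
    labels = ["healthy"] * n_healthy + ["infested"] * n_infested
    ids = [f"H{i:04d}" for i in range(n_healthy)] + [f"I{i:04d}" for i in range(n_infested)]

    save_dir = Path(save_dir) if save_dir is not None else None
    if save_dir is not None:
        save_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []

    rows = np.empty((n_total, grid.n_bands))
    for i, (label, sample_id) in enumerate(zip(labels, ids)):
        rng = np.random.default_rng(children[i])
        leaf_hp = _leaf_params(healthy_params, scene_params, rng)
        h_sig = healthy_signature(grid, leaf_hp)
        if label == "infested":
            severity = float(schedule[rng.integers(schedule.size)])
            i_sig = infested_signature(h_sig, infestation_params, severity)
        else:
            severity, i_sig = 0.0, None
        mask = make_leaf_mask(scene_params, rng)
        cube, truth = render_cube(
            mask, h_sig, i_sig, infestation_params, scene_params, rng, severity
        )
        mnss = cube_to_mnss(cube, seg_params, smoothing_window, smoothing_polyorder)
        rows[i] = mnss.values
        if save_dir is not None:
            hdr, _ = write_envi(cube, save_dir / f"{sample_id}.hdr")
            mask_to_png(truth["leaf_mask"], save_dir / f"{sample_id}_leaf.png")
            mask_to_png(truth["hotspot_mask"], save_dir / f"{sample_id}_hotspots.png")
            manifest_rows.append(
                dict(sample_id=sample_id, label=label, severity=severity,
                     header=hdr.name)
            )

    if save_dir is not None:
        pd.DataFrame(manifest_rows).to_csv(save_dir / "manifest.csv", index=False)
    return LabeledDataset(rows, np.array(labels, dtype=object), grid, "MNSS", ids)


def dataset_from_envi_manifest(
    manifest_csv: str | Path,
    seg_params: SegmentationParams = SegmentationParams(),
    smoothing_window: int = 7,
    smoothing_polyorder: int = 2,
) -> LabeledDataset:
    """Rebuild an MNSS dataset from ENVI cubes listed in a manifest CSV.

    The manifest needs ``sample_id``, ``label`` and ``header`` columns
    (header paths relative to the manifest).  Because cubes are stored
    as float32 -- the same precision used in memory -- this path
    reproduces the in-memory pipeline exactly.
    """
    from .cube_io import read_envi

    manifest_csv = Path(manifest_csv)
    table = pd.read_csv(manifest_csv)
    rows, labels, ids, grid = [], [], [], None
    for rec in table.itertuples():
        cube = read_envi(manifest_csv.parent / rec.header)
        grid = cube.grid
        rows.append(cube_to_mnss(cube, seg_params, smoothing_window,
                                 smoothing_polyorder).values)
        labels.append(rec.label)
        ids.append(str(rec.sample_id))
    if grid is None:
        raise ValueError("manifest lists no cubes")
    return LabeledDataset(np.vstack(rows), np.array(labels, dtype=object), grid,
                          "MNSS", ids)
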