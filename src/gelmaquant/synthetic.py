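"""Synthetic micrographs and assay tables with exact ground truth.

Every downstream stage of the package is validated against data whose content
is known by construction.  A simulated scene mimics a three-channel live/dead
micrograph of adherent cells:

* blue (Hoechst 33342): one bright nuclear disk per cell — the stain is
  membrane-permeable, so all cells appear;
* green (calcein): a filled cytoplasm disk, concentric with and larger than
  the nucleus, for viable cells only;
* red (propidium iodide): a bright nuclear disk for dead cells only.

Cells are placed by rejection sampling with a configurable minimum
center-to-center separation.  Separations below twice the nucleus radius
deliberately produce touching nuclei, which is exactly the situation the
watershed splitting step exists for.  Noise is additive Gaussian background
plus optional Poisson shot noise on stained pixels; defaults keep the
foreground/background contrast high enough that global Otsu thresholding is
well-posed.  All geometry is in pixels (no magnification or pixel-size model).

The module also generates tabular assay data — TNBS absorbances on a known
Beer–Lambert line, swollen/dry mass pairs around a known swelling ratio, and
near-flat frequency sweeps — so the characterization math has oracles too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assays import FrequencySweep

__all__ = [
    "PlacementError",
    "CellGroundTruth",
    "SceneSpec",
    "ChannelStack",
    "generate_micrograph",
    "render_truth_masks",
    "ground_truth_frame",
    "generate_tnbs_dataset",
    "generate_swelling_dataset",
    "generate_frequency_sweep",
]

#: Glycine standard concentrations used for TNBS calibration, µg/mL.
STANDARD_CONCENTRATIONS = (3.0, 5.0, 8.0, 10.0, 20.0)
#: Protein dilutions at which gelatin/GelMA samples are read, mg/mL.
SAMPLE_PROTEIN_CONCENTRATIONS = (0.1, 0.3, 0.5, 0.8)


class PlacementError(RuntimeError):
    """Rejection sampling could not place all cells at the requested density."""


@dataclass(frozen=True)
class CellGroundTruth:
    """One simulated cell: geometry plus true viability class."""

    cell_id: int
    centroid: tuple[float, float]  # (row, col), pixels, 0-based
    nucleus_radius: float
    cytoplasm_radius: float
    is_viable: bool

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if self.cytoplasm_radius < self.nucleus_radius:
            raise ValueError("cytoplasm_radius must be >= nucleus_radius")


@dataclass(frozen=True)
class ChannelStack:
    """Registered blue/green/red intensity images of one field of view."""

    blue: np.ndarray
    green: np.ndarray
    red: np.ndarray
    pixel_size: float | None = None  # length units per pixel, if known

    def __post_init__(self) -> None:
        for name in ("blue", "green", "red"):
            arr = np.asarray(getattr(self, name))
            object.__setattr__(self, name, arr)
            if arr.ndim != 2:
                raise ValueError(f"{name} channel must be a 2-D array")
            if np.any(arr < 0):
                raise ValueError(f"{name} channel contains negative intensities")
        if not (self.blue.shape == self.green.shape == self.red.shape):
            raise ValueError(
                f"channel shapes differ: blue {self.blue.shape}, "
                f"green {self.green.shape}, red {self.red.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one scene deterministically.

    ``min_center_separation`` may be smaller than twice the nucleus radius;
    that is how touching nuclei are produced on purpose.  With
    ``bernoulli_viability=False`` exactly ``round(n_cells * true_viability)``
    cells are viable, so the ground-truth viability is exactly controllable;
    the Bernoulli mode draws each cell independently instead (replicate-level
    sampling noise, as in a real study).  ``leaky_fraction`` makes that
    fraction of viable cells additionally PI-positive, to exercise the
    classifier's dead-over-viable tie-break.
    """

    image_shape: tuple[int, int] = (768, 768)
    n_cells: int = 200
    true_viability: float = 0.95
    radius_range: tuple[float, float] = (9.0, 11.0)
    min_center_separation: float = 14.0
    cytoplasm_scale: float = 1.8
    foreground_means: tuple[float, float, float] = (110.0, 130.0, 140.0)  # blue, green, red
    background_mean: float = 8.0
    gaussian_sd: float = 3.0
    poisson_scale: float = 1.0
    leaky_fraction: float = 0.0
    bernoulli_viability: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.true_viability <= 1.0:
            raise ValueError("true_viability must lie in [0, 1]")
        lo, hi = self.radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("radius_range must be positive and ascending")
        if self.cytoplasm_scale < 1.0:
            raise ValueError("cytoplasm_scale must be >= 1 (cytoplasm contains nucleus)")
        if self.min_center_separation < 0:
            raise ValueError("min_center_separation must be >= 0")
        for fg in self.foreground_means:
            if fg <= self.background_mean:
                raise ValueError("foreground means must exceed the background mean")
        if not 0.0 <= self.leaky_fraction <= 1.0:
            raise ValueError("leaky_fraction must lie in [0, 1]")


def _paint_disk(img: np.ndarray, center: tuple[float, float], radius: float, value: float) -> None:
    """Set pixels within ``radius`` of ``center`` to at least ``value`` (in place)."""
    rows, cols = img.shape
    cr, cc = center
    r0 = max(int(math.floor(cr - radius)), 0)
    r1 = min(int(math.ceil(cr + radius)) + 1, rows)
    c0 = max(int(math.floor(cc - radius)), 0)
    c1 = min(int(math.ceil(cc + radius)) + 1, cols)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    inside = (yy - cr) ** 2 + (xx - cc) ** 2 <= radius**2
    patch = img[r0:r1, c0:c1]
    patch[inside] = np.maximum(patch[inside], value)


def _place_centers(
    rng: np.random.Generator, spec: SceneSpec, margins: np.ndarray
) -> np.ndarray:
    """Rejection-sample cell centers with the requested minimum separation."""
    rows, cols = spec.image_shape
    n = spec.n_cells
    centers = np.empty((n, 2), dtype=float)
    min_sep_sq = spec.min_center_separation**2
    attempts_left = max(10_000, 500 * n)
    for i in range(n):
        m = margins[i]
        if rows - 1 - 2 * m <= 0 or cols - 1 - 2 * m <= 0:
            raise PlacementError(
                f"cell radius {m:.1f} px does not fit inside a {rows}x{cols} image"
            )
        while True:
            if attempts_left <= 0:
                raise PlacementError(
                    f"could not place {n} cells with min_center_separation "
                    f"{spec.min_center_separation:g} px in a {rows}x{cols} image; "
                    f"requested density is too high (placed {i})"
                )
            attempts_left -= 1
            cand = rng.uniform((m, m), (rows - 1 - m, cols - 1 - m))
            if i == 0:
                centers[0] = cand
                break
            d2 = ((centers[:i] - cand) ** 2).sum(axis=1)
            if d2.min() >= min_sep_sq:
                centers[i] = cand
                break
    return centers


def _assign_viability(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    n = spec.n_cells
    if n == 0:
        return np.zeros(0, dtype=bool)
    if spec.bernoulli_viability:
        return rng.random(n) < spec.true_viability
    n_viable = int(n * spec.true_viability + 0.5)  # round half up, exact by count
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:n_viable]] = True
    return flags


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = img.copy()
    if spec.poisson_scale > 0:
        stained = img > spec.background_mean
        if stained.any():
            lam = out[stained] * spec.poisson_scale
            out[stained] = rng.poisson(lam) / spec.poisson_scale
    if spec.gaussian_sd > 0:
        out += spec.gaussian_sd * rng.standard_normal(out.shape, dtype=np.float32)
    np.clip(out, 0, 65535, out=out)
    return np.rint(out).astype(np.uint16)


def generate_micrograph(spec: SceneSpec) -> tuple[ChannelStack, list[CellGroundTruth]]:
    """Render one three-channel scene together with its exact ground truth.

    Identical ``spec`` (including ``rng_seed``) yields bit-identical output.
    Raises :class:`PlacementError` when the requested cell density cannot be
    achieved by bounded rejection sampling.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_cells
    radii = rng.uniform(spec.radius_range[0], spec.radius_range[1], size=n)
    cyto = radii * spec.cytoplasm_scale
    centers = _place_centers(rng, spec, cyto)
    viable = _assign_viability(rng, spec)
    leaky = viable & (rng.random(n) < spec.leaky_fraction) if n else np.zeros(0, bool)

    fg_blue, fg_green, fg_red = spec.foreground_means
    blue = np.full(spec.image_shape, float(spec.background_mean))
    green = blue.copy()
    red = blue.copy()
    for i in range(n):
        center = (centers[i, 0], centers[i, 1])
        _paint_disk(blue, center, radii[i], fg_blue)
        if viable[i]:
            _paint_disk(green, center, cyto[i], fg_green)
        if (not viable[i]) or leaky[i]:
            _paint_disk(red, center, radii[i], fg_red)

    stack = ChannelStack(
        _apply_noise(blue, spec, rng),
        _apply_noise(green, spec, rng),
        _apply_noise(red, spec, rng),
    )
    truths = [
        CellGroundTruth(
            cell_id=i + 1,
            centroid=(float(centers[i, 0]), float(centers[i, 1])),
            nucleus_radius=float(radii[i]),
            cytoplasm_radius=float(cyto[i]),
            is_viable=bool(viable[i]),
        )
        for i in range(n)
    ]
    return stack, truths


def render_truth_masks(
    truths: list[CellGroundTruth], shape: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Noise-free boolean masks implied by the ground truth.

    Returns ``{'nuclei': all nucleus disks, 'viable': cytoplasm disks of viable
    cells, 'dead': nucleus disks of dead cells}``.
    """
    masks = {k: np.zeros(shape, dtype=float) for k in ("nuclei", "viable", "dead")}
    for t in truths:
        _paint_disk(masks["nuclei"], t.centroid, t.nucleus_radius, 1.0)
        if t.is_viable:
            _paint_disk(masks["viable"], t.centroid, t.cytoplasm_radius, 1.0)
        else:
            _paint_disk(masks["dead"], t.centroid, t.nucleus_radius, 1.0)
    return {k: v.astype(bool) for k, v in masks.items()}


def ground_truth_frame(truths: list[CellGroundTruth]) -> pd.DataFrame:
    """Ground truth as a table (one row per cell, (row, col) 0-based)."""
    return pd.DataFrame(
        {
            "cell_id": [t.cell_id for t in truths],
            "row": [t.centroid[0] for t in truths],
            "col": [t.centroid[1] for t in truths],
            "nucleus_radius": [t.nucleus_radius for t in truths],
            "cytoplasm_radius": [t.cytoplasm_radius for t in truths],
            "is_viable": [t.is_viable for t in truths],
        }
    )


def generate_tnbs_dataset(
    true_slope: float = 0.05,
    true_intercept: float = 0.02,
    amine_content_gelatin: float = 0.025,
    amine_content_gelma: float = 0.0025,
    protein_concs: tuple[float, ...] = SAMPLE_PROTEIN_CONCENTRATIONS,
    standard_concs: tuple[float, ...] = STANDARD_CONCENTRATIONS,
    noise_sd: float = 0.0,
    n_batches: int = 3,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a TNBS assay: glycine standards plus gelatin/GelMA dilutions.

    Absorbance follows the Beer–Lambert-linear model
    ``A = slope * c_amine + intercept`` with additive Gaussian noise of
    ``noise_sd``.  Amine contents are mass fractions (µg amine per µg protein);
    a sample at protein concentration ``P`` mg/mL therefore contributes
    ``P * 1000 * fraction`` µg/mL of glycine-equivalent amines.  Negative
    generated absorbances are clipped at zero and flagged in the ``clipped``
    column.  The true degree of functionalization is stored in
    ``table.attrs['true_dof']``.
    """
    if true_slope <= 0:
        raise ValueError("true_slope must be positive")
    if any(p <= 0 for p in protein_concs):
        raise ValueError("protein concentrations must be positive")
    if amine_content_gelatin <= 0:
        raise ValueError("gelatin amine content must be positive")
    rng = np.random.default_rng(rng_seed)
    rows = []

    def emit(batch: int, sample_type: str, concentration: float, amine_conc: float) -> None:
        a = true_slope * amine_conc + true_intercept
        if noise_sd > 0:
            a += rng.normal(0.0, noise_sd)
        clipped = a < 0
        rows.append(
            {
                "batch": batch,
                "sample_type": sample_type,
                "concentration": concentration,
                "absorbance": max(a, 0.0),
                "clipped": bool(clipped),
            }
        )

    for batch in range(1, n_batches + 1):
        for c in standard_concs:
            emit(batch, "glycine_standard", c, c)
        for p in protein_concs:
            emit(batch, "gelatin", p, p * 1000.0 * amine_content_gelatin)
        for p in protein_concs:
            emit(batch, "gelma", p, p * 1000.0 * amine_content_gelma)

    table = pd.DataFrame(rows)
    table.attrs["true_dof"] = (
        amine_content_gelatin - amine_content_gelma
    ) / amine_content_gelatin
    table.attrs["true_slope"] = true_slope
    table.attrs["true_intercept"] = true_intercept
    return table


def generate_swelling_dataset(
    true_ratio: float,
    n_samples: int = 9,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    dry_mass_mean: float = 10.0,
    dry_mass_sd: float = 1.0,
) -> pd.DataFrame:
    """Swollen/dry mass pairs (mg) whose ratio scatters around ``true_ratio``.

    Dry masses vary between samples (truncated normal); the per-sample ratio is
    ``true_ratio`` plus Gaussian noise of ``noise_sd``.  ``noise_sd=0`` yields
    exact ratios.
    """
    if true_ratio < 1:
        raise ValueError("true_ratio must be >= 1 (swollen gels weigh at least their dry mass)")
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = np.random.default_rng(rng_seed)
    m_dry = np.clip(rng.normal(dry_mass_mean, dry_mass_sd, size=n_samples), 0.1, None)
    ratios = true_ratio + (rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0)
    ratios = np.clip(ratios, 1.0, None)
    return pd.DataFrame(
        {
            "sample_id": [f"gel{i + 1}" for i in range(n_samples)],
            "m_swollen_mg": m_dry * ratios,
            "m_dry_mg": m_dry,
        }
    )


def generate_frequency_sweep(
    prefactor_pa: float = 11200.0,
    exponent: float = 0.02,
    loss_tangent: float = 0.1,
    n_points: int = 21,
    freq_range: tuple[float, float] = (0.5, 50.0),
    noise_sd_fraction: float = 0.0,
    rng_seed: int = 0,
) -> FrequencySweep:
    """Near-flat power-law sweep ``G'(ω) = prefactor * ω**exponent``, log-spaced.

    ``loss_tangent`` sets G'' = tan(δ) · G'; multiplicative Gaussian noise of
    relative size ``noise_sd_fraction`` can be added to both moduli.
    """
    rng = np.random.default_rng(rng_seed)
    w = np.logspace(np.log10(freq_range[0]), np.log10(freq_range[1]), n_points)
    g_storage = prefactor_pa * w**exponent
    g_loss = g_storage * loss_tangent
    if noise_sd_fraction > 0:
        g_storage = g_storage * (1 + rng.normal(0, noise_sd_fraction, n_points))
        g_loss = g_loss * (1 + rng.normal(0, noise_sd_fraction, n_points))
    return FrequencySweep(w, np.clip(g_storage, 0, None), np.clip(g_loss, 0, None))
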