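"""Hydrogel characterization math: TNBS amine assay, swelling ratio, plateau modulus.

The TNBS (trinitrobenzenesulfonic acid) assay quantifies free primary amines
colorimetrically at 335 nm.  A glycine standard curve converts absorbance to a
glycine-equivalent amine concentration; normalizing to the protein
concentration of each dilution gives an amine content per mass of protein.
The degree of functionalization (DoF) of gelatin methacryloyl (GelMA) is the
fraction of gelatin's free amines consumed by the methacryloyl modification::

    DoF = (c_NH2,gelatin - c_NH2,GelMA) / c_NH2,gelatin

Swelling of a crosslinked hydrogel is summarized by the ratio of swollen to
lyophilized (dry) mass, and stiffness by the elastic plateau of the storage
modulus G' over the linear-viscoelastic frequency window.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "AmineMeasurement",
    "DoFResult",
    "SwellingMeasurement",
    "FrequencySweep",
    "PlateauResult",
    "fit_standard_curve",
    "amine_content",
    "degree_of_functionalization",
    "swelling_ratio",
    "plateau_modulus",
    "tnbs_pipeline",
]


class CalibrationError(ValueError):
    """Raised when a standard curve cannot be fit or is not a valid calibration."""


@dataclass(frozen=True)
class StandardCurve:
    """Linear glycine calibration: absorbance = slope * concentration + intercept.

    Concentrations are in µg/mL glycine equivalents; absorbance is dimensionless.
    """

    slope: float
    intercept: float
    r_squared: float
    calibration_points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(
                f"calibration failed: non-positive slope {self.slope:g} "
                "(absorbance must increase with amine concentration)"
            )

    @property
    def concentration_range(self) -> tuple[float, float]:
        concs = [c for c, _ in self.calibration_points]
        return (min(concs), max(concs))

    def concentration(self, absorbance: float | np.ndarray) -> float | np.ndarray:
        """Invert the calibration: concentration = (A - intercept) / slope."""
        return (np.asarray(absorbance, dtype=float) - self.intercept) / self.slope


@dataclass
class AmineMeasurement:
    """One TNBS reading of a protein sample dilution."""

    sample_id: str
    protein_concentration: float  # mg/mL
    absorbance: float  # at 335 nm
    normalized_amine_content: float | None = None  # µg amine per mg protein

    def __post_init__(self) -> None:
        if self.protein_concentration <= 0:
            raise ValueError(
                f"protein concentration must be positive, got {self.protein_concentration}"
            )


@dataclass(frozen=True)
class DoFResult:
    """Degree of functionalization with the amine contents it was derived from."""

    c_nh2_gelatin: float
    c_nh2_gelma: float
    dof: float
    dof_sd: float | None = None


@dataclass(frozen=True)
class SwellingMeasurement:
    sample_id: str
    m_swollen: float
    m_dry: float

    @property
    def ratio(self) -> float:
        return swelling_ratio(self.m_swollen, self.m_dry)


@dataclass(frozen=True)
class FrequencySweep:
    """Oscillatory frequency sweep: storage and loss moduli vs angular frequency.

    Frequencies are rad/s, strictly increasing; moduli are Pa, nonnegative.
    """

    angular_frequencies: np.ndarray
    storage_modulus: np.ndarray
    loss_modulus: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "angular_frequencies", np.asarray(self.angular_frequencies, float)
        )
        object.__setattr__(self, "storage_modulus", np.asarray(self.storage_modulus, float))
        object.__setattr__(self, "loss_modulus", np.asarray(self.loss_modulus, float))
        n = self.angular_frequencies.size
        if self.storage_modulus.size != n or self.loss_modulus.size != n:
            raise ValueError("frequency and modulus arrays must have equal length")
        if n and np.any(np.diff(self.angular_frequencies) <= 0):
            raise ValueError("angular frequencies must be strictly increasing")
        if np.any(self.storage_modulus < 0) or np.any(self.loss_modulus < 0):
            raise ValueError("moduli must be nonnegative")


PlateauResult = namedtuple("PlateauResult", ["modulus_pa", "flatness"])


def fit_standard_curve(
    points: Iterable[tuple[float, float]], through_origin: bool = False
) -> StandardCurve:
    """Fit the glycine standard curve by ordinary least squares.

    Parameters
    ----------
    points
        (concentration µg/mL, absorbance) pairs; at least two distinct
        concentrations are required.
    through_origin
        Force a zero intercept (no reagent blank).  Default fits a free
        intercept.

    Returns
    -------
    StandardCurve
        Slope, intercept, coefficient of determination and the points used.
    """
    pts = tuple((float(c), float(a)) for c, a in points)
    if len(pts) < 2:
        raise CalibrationError("at least two calibration points are required")
    x = np.array([c for c, _ in pts])
    y = np.array([a for _, a in pts])
    if np.ptp(x) == 0:
        raise CalibrationError("all calibration concentrations are identical; cannot fit a line")
    if through_origin:
        slope = float(x @ y / (x @ x))
        intercept = 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
    residuals = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - float((residuals**2).sum()) / ss_tot
    return StandardCurve(slope, intercept, min(max(r_squared, 0.0), 1.0), pts)


def amine_content(
    measurements: Sequence[AmineMeasurement] | pd.DataFrame,
    curve: StandardCurve,
) -> pd.DataFrame:
    """Convert TNBS absorbances to normalized amine contents, averaged per sample.

    Each absorbance is inverted through the standard curve to a glycine-equivalent
    amine concentration (µg/mL) and divided by the protein concentration (mg/mL)
    of that dilution, giving µg amine per mg protein.  Replicate dilutions of a
    sample are averaged to one value per sample with a standard deviation.

    Returns a frame indexed by ``sample_id`` with columns ``mean``, ``sd``, ``n``.
    Absorbances outside the calibration range and negative back-calculated
    concentrations trigger warnings (never silent clipping).
    """
    if isinstance(measurements, pd.DataFrame):
        df = measurements[["sample_id", "protein_concentration", "absorbance"]].copy()
    else:
        df = pd.DataFrame(
            {
                "sample_id": [m.sample_id for m in measurements],
                "protein_concentration": [m.protein_concentration for m in measurements],
                "absorbance": [m.absorbance for m in measurements],
            }
        )
    if (df["protein_concentration"] <= 0).any():
        raise ValueError("protein concentrations must be positive")

    conc = curve.concentration(df["absorbance"].to_numpy())
    lo, hi = curve.concentration_range
    outside = (conc < lo) | (conc > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} absorbance(s) fall outside the calibration range "
            f"[{lo:g}, {hi:g}] µg/mL; values are extrapolated",
            stacklevel=2,
        )
    if (conc < 0).any():
        warnings.warn(
            f"{int((conc < 0).sum())} absorbance(s) below the calibration intercept "
            "yield negative amine concentrations",
            stacklevel=2,
        )
    df["normalized_amine_content"] = conc / df["protein_concentration"].to_numpy()
    if not isinstance(measurements, pd.DataFrame):
        for m, v in zip(measurements, df["normalized_amine_content"]):
            m.normalized_amine_content = float(v)
    grouped = df.groupby("sample_id")["normalized_amine_content"]
    out = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
    out["n"] = out["n"].astype(int)
    return out


def degree_of_functionalization(
    c_gelatin: float,
    c_gelma: float,
    sd_gelatin: float | None = None,
    sd_gelma: float | None = None,
) -> DoFResult:
    """Degree of functionalization from normalized amine contents.

    ``dof = (c_gelatin - c_gelma) / c_gelatin``; both contents must be in the
    same units.  When replicate standard deviations are supplied the DoF
    standard deviation is propagated to first order (delta method).  A negative
    DoF (GelMA apparently richer in amines than gelatin) is flagged with a
    warning, never clipped.
    """
    if c_gelatin <= 0:
        raise ValueError(f"gelatin amine content must be positive, got {c_gelatin}")
    dof = (c_gelatin - c_gelma) / c_gelatin
    if dof < 0:
        warnings.warn(
            f"negative degree of functionalization ({dof:.4g}); the GelMA sample "
            "shows more free amines than the gelatin reference",
            stacklevel=2,
        )
    dof_sd = None
    if sd_gelatin is not None or sd_gelma is not None:
        sg = 0.0 if sd_gelatin is None else float(sd_gelatin)
        sm = 0.0 if sd_gelma is None else float(sd_gelma)
        # d(dof)/dc_gelatin = c_gelma / c_gelatin^2 ; d(dof)/dc_gelma = -1 / c_gelatin
        dof_sd = float(
            np.sqrt((c_gelma / c_gelatin**2) ** 2 * sg**2 + (1.0 / c_gelatin) ** 2 * sm**2)
        )
    return DoFResult(float(c_gelatin), float(c_gelma), float(dof), dof_sd)


def swelling_ratio(m_swollen, m_dry):
    """Equilibrium swelling ratio ``m_swollen / m_dry`` (dimensionless).

    Accepts scalars or arrays.  The dry mass must be positive and the swollen
    mass nonnegative.
    """
    m_swollen = np.asarray(m_swollen, dtype=float)
    m_dry = np.asarray(m_dry, dtype=float)
    if np.any(m_dry <= 0):
        raise ValueError("dry mass must be positive")
    if np.any(m_swollen < 0):
        raise ValueError("swollen mass must be nonnegative")
    ratio = m_swollen / m_dry
    return float(ratio) if ratio.ndim == 0 else ratio


def plateau_modulus(
    sweep: FrequencySweep,
    freq_window: tuple[float, float] = (0.5, 50.0),
    method: str = "geometric",
) -> PlateauResult:
    """Summarize a frequency sweep as one elastic plateau modulus.

    The plateau estimate is the geometric mean of G' over the window (moduli
    span decades between hydrogel formulations, so the geometric mean is the
    scale-appropriate reduction; ``method='arithmetic'`` is available).  The
    flatness metric is max/min of G' in the window; values above 1.5 indicate
    the sweep is not plateau-like and raise a warning.
    """
    lo, hi = freq_window
    if lo >= hi:
        raise ValueError("frequency window must satisfy low < high")
    w = sweep.angular_frequencies
    # tolerate logspace endpoint rounding when the window touches the sweep limits
    eps = 1e-9
    if w.size == 0 or lo < w[0] * (1 - eps) or hi > w[-1] * (1 + eps):
        raise ValueError(
            f"window [{lo:g}, {hi:g}] rad/s lies outside the measured range "
            f"[{w[0] if w.size else float('nan'):g}, {w[-1] if w.size else float('nan'):g}]"
        )
    sel = (w >= lo * (1 - eps)) & (w <= hi * (1 + eps))
    g = sweep.storage_modulus[sel]
    if g.size < 3:
        raise ValueError(f"need at least 3 points inside the window, found {g.size}")
    if method == "geometric":
        if np.any(g <= 0):
            raise ValueError("geometric mean requires strictly positive moduli")
        plateau = float(np.exp(np.mean(np.log(g))))
    elif method == "arithmetic":
        plateau = float(np.mean(g))
    else:
        raise ValueError(f"unknown method {method!r}")
    flatness = float(g.max() / g.min()) if g.min() > 0 else float("inf")
    if flatness > 1.5:
        warnings.warn(
            f"storage modulus varies {flatness:.2f}-fold across the window; "
            "this is not a plateau",
            stacklevel=2,
        )
    return PlateauResult(plateau, flatness)


def tnbs_pipeline(
    table: pd.DataFrame,
    gelatin_id: str = "gelatin",
    gelma_id: str = "gelma",
    standard_id: str = "glycine_standard",
    through_origin: bool = False,
) -> pd.DataFrame:
    """Run the full TNBS analysis on a tidy assay table, batch by batch.

    The table needs columns ``batch``, ``sample_type``, ``concentration``
    (µg/mL glycine for standards, mg/mL protein for samples) and
    ``absorbance``.  Per batch: fit the standard curve, back-calculate
    normalized amine contents for the gelatin reference and the GelMA sample
    (dilution replicates averaged within batch), then the batch DoF.

    Returns one row per batch (slope, intercept, r_squared, amine contents,
    dof); the across-batch summary is stored in ``result.attrs['dof_mean']``
    and ``result.attrs['dof_sd']``.
    """
    required = {"batch", "sample_type", "concentration", "absorbance"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"assay table is missing columns: {sorted(missing)}")
    rows = []
    for batch, sub in table.groupby("batch"):
        std = sub[sub["sample_type"] == standard_id]
        curve = fit_standard_curve(zip(std["concentration"], std["absorbance"]), through_origin)
        contents = {}
        for sid in (gelatin_id, gelma_id):
            sample = sub[sub["sample_type"] == sid]
            if sample.empty:
                raise ValueError(f"batch {batch!r} has no {sid!r} measurements")
            meas = sample.rename(
                columns={"concentration": "protein_concentration"}
            ).assign(sample_id=sid)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # extrapolation is routine for high-DoF GelMA
                contents[sid] = amine_content(meas, curve)
        res = degree_of_functionalization(
            contents[gelatin_id].loc[gelatin_id, "mean"],
            contents[gelma_id].loc[gelma_id, "mean"],
            contents[gelatin_id].loc[gelatin_id, "sd"],
            contents[gelma_id].loc[gelma_id, "sd"],
        )
        rows.append(
            {
                "batch": batch,
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
                "c_nh2_gelatin": res.c_nh2_gelatin,
                "c_nh2_gelma": res.c_nh2_gelma,
                "dof": res.dof,
                "dof_sd_propagated": res.dof_sd,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["dof_mean"] = float(out["dof"].mean())
    out.attrs["dof_sd"] = float(out["dof"].std(ddof=1)) if len(out) > 1 else 0.0
    return out
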