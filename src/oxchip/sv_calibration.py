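"""Stern-Volmer phosphorescence oximetry: ROI reduction, calibration, inversion.

Oxygen tension in the gel channel is read out from oxygen-sensitive
nanoparticles that phosphoresce more brightly at low oxygen.  Raw
phosphorescence is normalized ratiometrically against the particles'
oxygen-insensitive fluorescence to cancel illumination drift,

    I'(x) = I_P(x) * I_F0(x) / I_F(x),

then converted to oxygen tension with the (background-offset) Stern-Volmer
relation, fitted per 100 um section across the gel:

    I'(c) = I_BG + (I_A - I_BG) / (1 + K_q c / 100)
    c(x)  = [ (I_A(x) - I_BG(x)) / (I'(x) - I_BG(x)) - 1 ] / K_q(x) * 100

where I_A is the normalized intensity under anoxia (c = 0), I_BG the
background from device materials and medium, and K_q the quenching
constant.  I_A is pinned to the measured anoxia point; I_BG and K_q are
fitted by least squares on the nonlinear form (the linearized
Stern-Volmer plot only seeds the optimizer, to avoid variance distortion
at low intensities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ROI_WIDTH_UM",
    "ROI_HEIGHT_UM",
    "SECTION_WIDTH_UM",
    "PIXEL_SIZE_UM",
    "IntensityRecord",
    "CalibrationModel",
    "InversionResult",
    "normalize_intensity",
    "fit_calibration",
    "intensity_to_oxygen",
    "reduce_roi",
    "sv_forward",
]

# Imaging geometry: a 1024 x 50 px ROI spanning 1331 um x 65 um across the
# gel channel, split into 100 um x 65 um averaging sections.
ROI_WIDTH_UM = 1331.0
ROI_HEIGHT_UM = 65.0
SECTION_WIDTH_UM = 100.0
PIXEL_SIZE_UM = ROI_WIDTH_UM / 1024.0  # ~1.3 um/px


@dataclass(frozen=True)
class IntensityRecord:
    """Section-averaged intensities at one time point.

    I_F0 is the fluorescence of the same section at the experiment's first
    time point (the drift-free normalization anchor).
    """

    section_x: float  # um, section center in device coordinates
    I_F: float
    I_P: float
    I_F0: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.I_F <= 0 or self.I_F0 <= 0:
            raise ValueError("fluorescence intensities must be positive")


def normalize_intensity(rec_or_IP, I_F=None, I_F0=None):
    """Ratiometric normalization I' = I_P * I_F0 / I_F.

    A multiplicative illumination drift g(t) scales I_P and I_F alike and
    cancels; I_F0, taken at the drift-free first frame, restores the
    original intensity scale.  Accepts an IntensityRecord or three
    array-likes.
    """
    if isinstance(rec_or_IP, IntensityRecord):
        rec = rec_or_IP
        return rec.I_P * rec.I_F0 / rec.I_F
    I_P = np.asarray(rec_or_IP, dtype=float)
    I_F = np.asarray(I_F, dtype=float)
    I_F0 = np.asarray(I_F0, dtype=float)
    if np.any(I_F <= 0) or np.any(I_F0 <= 0):
        raise ValueError("fluorescence intensities must be positive")
    return I_P * I_F0 / I_F


def sv_forward(c, I_A, I_BG, K_q):
    """Noise-free Stern-Volmer intensity at oxygen tension c (%O2)."""
    return I_BG + (I_A - I_BG) / (1.0 + K_q * np.asarray(c, dtype=float) / 100.0)


@dataclass
class CalibrationModel:
    """Fitted per-section Stern-Volmer parameters.

    ``params`` has one row per section with columns
    (section_x, I_A, I_BG, K_q, rms_residual).
    """

    params: pd.DataFrame

    def __post_init__(self) -> None:
        p = self.params
        if np.any(p["K_q"] <= 0):
            raise ValueError("K_q must be positive")
        if np.any(p["I_A"] <= p["I_BG"]) or np.any(p["I_BG"] < 0):
            raise ValueError("require I_A > I_BG >= 0")

    def _row(self, section_x: float) -> pd.Series:
        i = (self.params["section_x"] - section_x).abs().idxmin()
        return self.params.loc[i]

    def forward(self, c, section_x: float):
        """Expected normalized phosphorescence at oxygen tension c."""
        r = self._row(section_x)
        return sv_forward(c, r["I_A"], r["I_BG"], r["K_q"])

    def invert(self, I_norm, section_x: float) -> "InversionResult":
        r = self._row(section_x)
        return intensity_to_oxygen(I_norm, r["I_A"], r["I_BG"], r["K_q"])


@dataclass
class InversionResult:
    """Oxygen values with quality flags.

    ``undefined`` marks inputs at or below the background (no oxygen value
    exists; the output there is NaN, not clamped).  ``clamped`` marks
    inputs brighter than the anoxia intensity, whose formally negative
    oxygen was clamped to 0.
    """

    oxygen: np.ndarray
    undefined: np.ndarray
    clamped: np.ndarray


def intensity_to_oxygen(I_norm, I_A, I_BG, K_q) -> InversionResult:
    """Invert the Stern-Volmer relation: c = [(I_A-I_BG)/(I'-I_BG) - 1]/K_q*100.

    Strictly decreasing in I' on (I_BG, I_A]; I' = I_A maps to exactly 0.
    """
    I = np.atleast_1d(np.asarray(I_norm, dtype=float))
    undefined = I <= I_BG
    with np.errstate(divide="ignore", invalid="ignore"):
        c = ((I_A - I_BG) / (I - I_BG) - 1.0) / K_q * 100.0
    c = np.where(undefined, np.nan, c)
    clamped = ~undefined & (c < 0)
    c = np.where(clamped, 0.0, c)
    return InversionResult(oxygen=c, undefined=undefined, clamped=clamped)


def fit_calibration(points: pd.DataFrame) -> CalibrationModel:
    """Fit per-section Stern-Volmer parameters from calibration exposures.

    ``points`` columns: section_x, I_norm (normalized phosphorescence),
    oxygen (known supply %O2).  Each section needs >= 3 oxygen levels; the
    anoxia (0%) point pins I_A, so it must be present (21% should be too —
    its absence only warns, since it merely widens the extrapolation).
    """
    required = {"section_x", "I_norm", "oxygen"}
    if not required.issubset(points.columns):
        raise ValueError(f"points must have columns {sorted(required)}")
    rows = []
    for section_x, grp in points.groupby("section_x", sort=True):
        c = grp["oxygen"].to_numpy(dtype=float)
        I = grp["I_norm"].to_numpy(dtype=float)
        if len(grp) < 3:
            raise ValueError(
                f"section {section_x}: need >= 3 calibration points, got {len(grp)}"
            )
        if np.ptp(I) == 0:
            raise ValueError(f"section {section_x}: degenerate (identical) intensities")
        if not np.any(c == 0):
            raise ValueError(
                f"section {section_x}: anoxia (0%) point required to pin I_A"
            )
        if not np.any(c == 21):
            warnings.warn(
                f"section {section_x}: no 21% point; extrapolating the fit",
                stacklevel=2,
            )
        I_A = float(np.mean(I[c == 0]))

        # Linearized Stern-Volmer seed: (I_A - BG)/(I - BG) - 1 = K_q c/100,
        # evaluated at a rough background guess.
        bg0 = max(0.0, 0.5 * float(I.min()))
        denom = np.clip(I - bg0, 1e-12, None)
        ratio = (I_A - bg0) / denom - 1.0
        pos = c > 0
        kq0 = float(np.clip(np.sum(ratio[pos] * c[pos] / 100.0)
                            / max(np.sum((c[pos] / 100.0) ** 2), 1e-12), 1e-3, None))

        def resid(theta):
            bg, kq = theta
            return sv_forward(c, I_A, bg, kq) - I

        sol = least_squares(
            resid,
            x0=[bg0, kq0],
            bounds=([0.0, 1e-9], [I_A * (1 - 1e-9), np.inf]),
        )
        bg, kq = sol.x
        if kq <= 0:
            raise ValueError(f"section {section_x}: fit yielded K_q <= 0")
        rows.append(
            {
                "section_x": float(section_x),
                "I_A": I_A,
                "I_BG": float(bg),
                "K_q": float(kq),
                "rms_residual": float(np.sqrt(np.mean(sol.fun**2))),
            }
        )
    return CalibrationModel(params=pd.DataFrame(rows))


def reduce_roi(
    fluorescence,
    phosphorescence,
    times=None,
    pixel_size_um: float = PIXEL_SIZE_UM,
    section_width_um: float = SECTION_WIDTH_UM,
    roi_x0_um: float | None = None,
    roi=None,
) -> pd.DataFrame:
    """Section-average an image-pair stack into an intensity table.

    ``fluorescence`` / ``phosphorescence`` are (ny, nx) frames or
    (nt, ny, nx) stacks.  The ROI (default: the whole frame) is tiled into
    ``section_width_um``-wide sections along x; a partial trailing section
    (1331 = 13 x 100 + 31 um) is dropped rather than averaged short.
    Section centers are reported in device coordinates, with the ROI
    centered on the gel channel unless ``roi_x0_um`` (left edge) is given.

    Returns a tidy frame with columns (t, section_x, I_F, I_P, I_F0);
    I_F0 is each section's fluorescence at the first time point.
    """
    F = np.asarray(fluorescence, dtype=float)
    P = np.asarray(phosphorescence, dtype=float)
    if F.shape != P.shape:
        raise ValueError("fluorescence and phosphorescence shapes differ")
    if F.ndim == 2:
        F = F[None]
        P = P[None]
    nt, ny, nx = F.shape
    if roi is not None:
        y0, y1, x0, x1 = roi
        if not (0 <= y0 < y1 <= ny and 0 <= x0 < x1 <= nx):
            raise ValueError("ROI outside image bounds")
        F = F[:, y0:y1, x0:x1]
        P = P[:, y0:y1, x0:x1]
        nx = x1 - x0
    if times is None:
        times = np.arange(nt, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.shape != (nt,):
        raise ValueError("times length must match the stack")

    px_per_section = section_width_um / pixel_size_um
    n_sections = int(nx * pixel_size_um // section_width_um)
    if n_sections == 0:
        raise ValueError("ROI narrower than one section")
    roi_width_um = nx * pixel_size_um
    if roi_x0_um is None:
        roi_x0_um = -roi_width_um / 2.0

    bounds_px = np.round(np.arange(n_sections + 1) * px_per_section).astype(int)
    records = []
    F0_means = None
    for it in range(nt):
        for s in range(n_sections):
            lo, hi = bounds_px[s], bounds_px[s + 1]
            mean_F = float(F[it, :, lo:hi].mean())
            mean_P = float(P[it, :, lo:hi].mean())
            center = roi_x0_um + (s + 0.5) * section_width_um
            records.append(
                {"t": times[it], "section_x": center, "I_F": mean_F, "I_P": mean_P}
            )
        if it == 0:
            F0_means = {r["section_x"]: r["I_F"] for r in records}
    table = pd.DataFrame(records)
    table["I_F0"] = table["section_x"].map(F0_means)
    return table
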