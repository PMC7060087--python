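"""Synthetic oxygen fields, calibration image stacks, and cell tracks.

Forward models that generate inputs with the statistical structure the
analysis modules assume, so every pipeline stage is exercisable without
laboratory data:

* analytic oxygen fields over the gel (uniform, linear, or taken from the
  transport solver);
* a camera model rendering paired fluorescence/phosphorescence stacks by
  running the Stern-Volmer relation forward, with illumination drift and
  additive plus signal-dependent noise;
* oxygen-dependent persistent random walks with division events, emulating
  the breast-cancer-cell experiments: a slow subpopulation whose typical
  speed does not depend on oxygen, a fast subpopulation whose speed scales
  with an oxygen response curve peaking at ~5 %O2, division probabilities
  over 24 h higher under hypoxia (~0.7-0.8) than normoxia (~0.4), and a
  several-hour adaptation lag after an oxygen switch.

Absolute speed values are free parameters — only the ordinal structure
(local maximum near 5 %O2, hypoxia faster than normoxia, 10 %O2 on par
with 21 %O2) is meaningful and enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sv_calibration import PIXEL_SIZE_UM, SECTION_WIDTH_UM, sv_forward
from .transport import OxygenField, gel_gradient_profile

__all__ = [
    "GelOxygenProfile",
    "uniform_field",
    "linear_field",
    "from_solver",
    "make_oxygen_field",
    "IntermittentSchedule",
    "CameraModel",
    "render_calibration_stack",
    "WalkModel",
    "simulate_tracks",
]

GEL_HALF_UM = 650.0
SEEDING_DENSITY_PER_ML = 2.0e5
CHANNEL_HEIGHT_UM = 150.0


@dataclass(frozen=True)
class GelOxygenProfile:
    """Analytic oxygen tension across the gel ROI: phi(x) in %O2.

    ``kind`` is uniform or linear; evaluation clamps x to the defined span
    so that wall-adjacent samples stay in range.
    """

    kind: str
    c_left: float
    c_right: float
    x_min_um: float = -GEL_HALF_UM
    x_max_um: float = GEL_HALF_UM

    def __post_init__(self) -> None:
        for val in (self.c_left, self.c_right):
            if not (0.0 <= val <= 21.0):
                raise ValueError(f"oxygen value {val} outside [0, 21] %O2")

    def __call__(self, x_um, t_h: float = 0.0):
        x = np.clip(np.asarray(x_um, dtype=float), self.x_min_um, self.x_max_um)
        frac = (x - self.x_min_um) / (self.x_max_um - self.x_min_um)
        return self.c_left + (self.c_right - self.c_left) * frac


def uniform_field(c: float) -> GelOxygenProfile:
    return GelOxygenProfile("uniform", c, c)


def linear_field(
    c_left: float,
    c_right: float,
    x_min_um: float = -GEL_HALF_UM,
    x_max_um: float = GEL_HALF_UM,
) -> GelOxygenProfile:
    return GelOxygenProfile("linear", c_left, c_right, x_min_um, x_max_um)


def from_solver(fld: OxygenField) -> GelOxygenProfile:
    """Linear fit of a solved steady field's gel profile."""
    prof = gel_gradient_profile(fld)
    slope_um = prof["slope_per_mm"] / 1000.0
    return GelOxygenProfile(
        "linear",
        c_left=float(np.clip(prof["intercept"] - slope_um * GEL_HALF_UM, 0, 21)),
        c_right=float(np.clip(prof["intercept"] + slope_um * GEL_HALF_UM, 0, 21)),
    )


def make_oxygen_field(kind: str, *args) -> GelOxygenProfile:
    """Dispatch constructor: 'uniform'(c), 'linear'(c_left, c_right),
    'from_solver'(OxygenField)."""
    if kind == "uniform":
        return uniform_field(*args)
    if kind == "linear":
        return linear_field(*args)
    if kind == "from_solver":
        return from_solver(*args)
    raise ValueError(f"unknown field kind {kind!r}")


@dataclass(frozen=True)
class IntermittentSchedule:
    """Oxygen alternating between two profiles with a fixed period.

    Default mirrors intermittent hypoxia: 21% and 0% alternating every 8 h,
    starting on ``first``.
    """

    first: GelOxygenProfile = field(default_factory=lambda: uniform_field(21.0))
    second: GelOxygenProfile = field(default_factory=lambda: uniform_field(0.0))
    period_h: float = 8.0

    def __call__(self, x_um, t_h: float = 0.0):
        phase = int(np.floor(t_h / self.period_h)) % 2
        return (self.second if phase else self.first)(x_um, t_h)


# ---------------------------------------------------------------------------
# camera forward model


@dataclass
class CameraModel:
    """Forward imaging model for the ratiometric oxygen readout.

    Per-section true Stern-Volmer parameters (scalars broadcast to all
    sections), a fluorescence baseline, a multiplicative illumination
    drift g(t) shared by both channels (g at the first frame must be 1:
    the normalization anchor is drift-free by construction), and noise
    with an additive Gaussian floor plus a signal-dependent (Poisson-like)
    component of variance ``shot_scale * signal``.
    """

    I_A: float = 1000.0
    I_BG: float = 100.0
    K_q: float = 3.0
    I_F_base: float = 1000.0
    drift: object = None  # callable g(t_h) -> float; None means no drift
    noise_sd: float = 2.0
    shot_scale: float = 0.05
    pixel_size_um: float = PIXEL_SIZE_UM

    def g(self, t_h: float) -> float:
        if self.drift is None:
            return 1.0
        return float(self.drift(t_h))

    def phos_clean(self, c):
        return sv_forward(c, self.I_A, self.I_BG, self.K_q)


def render_calibration_stack(
    profile,
    cam: CameraModel,
    times_h,
    shape: tuple[int, int] = (50, 1024),
    roi_x0_um: float | None = None,
    rng=None,
):
    """Render paired fluorescence/phosphorescence stacks over an oxygen field.

    Each pixel column maps to a device x coordinate; the noiseless
    phosphorescence follows the Stern-Volmer forward model at the local
    oxygen tension, both channels are scaled by the illumination drift
    g(t), and noise is added per pixel.  Deterministic for a fixed rng
    seed.  Returns (fluorescence, phosphorescence) stacks of shape
    (nt, ny, nx) as float arrays.
    """
    rng = np.random.default_rng(rng)
    times_h = np.asarray(times_h, dtype=float)
    if abs(cam.g(times_h[0]) - 1.0) > 1e-9:
        raise ValueError("illumination drift must satisfy g(t0) = 1")
    ny, nx = shape
    width_um = nx * cam.pixel_size_um
    if roi_x0_um is None:
        roi_x0_um = -width_um / 2.0
    x_px = roi_x0_um + (np.arange(nx) + 0.5) * cam.pixel_size_um

    F = np.empty((len(times_h), ny, nx))
    P = np.empty_like(F)
    for it, t in enumerate(times_h):
        c = np.asarray(profile(x_px, t), dtype=float)
        g = cam.g(t)
        f_clean = np.full(nx, cam.I_F_base) * g
        p_clean = cam.phos_clean(c) * g
        for clean, out in ((f_clean, F), (p_clean, P)):
            frame = np.broadcast_to(clean, (ny, nx)).copy()
            if cam.noise_sd > 0:
                frame = frame + rng.normal(0.0, cam.noise_sd, (ny, nx))
            if cam.shot_scale > 0:
                frame = frame + rng.normal(
                    0.0, np.sqrt(cam.shot_scale * np.maximum(clean, 0.0)), (ny, nx)
                )
            out[it] = frame
    return F, P


CALIBRATION_LEVELS = (0.0, 1.0, 3.0, 5.0, 10.0, 21.0)


def calibration_roundtrip(
    rng,
    cam: CameraModel | None = None,
    levels=CALIBRATION_LEVELS,
    profile: GelOxygenProfile | None = None,
):
    """Full synthetic oximetry experiment: render -> reduce -> fit -> invert.

    Renders calibration exposures at the known uniform supply ``levels``
    (the device's sensitivity-test set), fits the per-section Stern-Volmer
    model, then images ``profile`` (default: the linear 3-17 %O2 gradient)
    and inverts it.  Returns the fitted model, the recovered per-section
    oxygen profile, and the true values at the section centers.
    """
    from .sv_calibration import fit_calibration, normalize_intensity, reduce_roi

    rng = np.random.default_rng(rng)
    cam = cam or CameraModel(drift=lambda t: 1.0 + 0.15 * np.sin(0.8 * t))
    profile = profile or linear_field(3.0, 17.0)

    def imaged_sections(field, t_image):
        F, P = render_calibration_stack(field, cam, times_h=[0.0, t_image], rng=rng)
        red = reduce_roi(F, P, times=[0.0, t_image])
        frame = red[red["t"] > 0].copy()
        frame["I_norm"] = normalize_intensity(frame["I_P"], frame["I_F"], frame["I_F0"])
        return frame

    cal = []
    for i, c in enumerate(levels):
        frame = imaged_sections(uniform_field(c), t_image=float(i) + 1.0)
        frame["oxygen"] = c
        cal.append(frame[["section_x", "I_norm", "oxygen"]])
    model = fit_calibration(pd.concat(cal, ignore_index=True))

    frame = imaged_sections(profile, t_image=0.5)
    recovered = np.array(
        [
            float(model.invert(i, x).oxygen[0])
            for i, x in zip(frame["I_norm"], frame["section_x"])
        ]
    )
    truth = np.asarray(profile(frame["section_x"].to_numpy()), dtype=float)
    return {
        "model": model,
        "section_x": frame["section_x"].to_numpy(),
        "recovered": recovered,
        "truth": truth,
        "camera": cam,
    }


def save_stack(path, stack) -> None:
    """Write a rendered stack as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


# ---------------------------------------------------------------------------
# oxygen-dependent persistent random walks


@dataclass
class WalkModel:
    """Parameters of the oxygen-dependent persistent random walk.

    Speeds are drawn per 10-min step from a two-component lognormal
    mixture: the slow mode's median is fixed across oxygen; the fast
    mode's median scales with a piecewise-linear oxygen response curve
    through the study's uniform-condition oxygen levels, with a local
    maximum near 5 %O2, hypoxia above normoxia, and 10 %O2 on par with
    21 %O2.  Division probability over 24 h interpolates between hypoxic
    (~0.7-0.8) and normoxic (~0.4) values.  The speed response follows the
    oxygen experienced ``lag_h`` hours earlier (cells take several hours
    to adapt after a switch).
    """

    control_o2: tuple = (0.3, 1.3, 3.4, 5.3, 10.1, 21.0)
    fast_multiplier: tuple = (1.3, 1.4, 1.45, 1.55, 1.02, 1.0)
    slow_median: float = 7.5  # um/h
    slow_sigma: float = 0.35  # lognormal shape
    fast_median_base: float = 22.0  # um/h at 21 %O2
    fast_sigma: float = 0.4
    fast_fraction: float = 0.35
    persistence: float = 0.6  # 0 = fresh direction each step, 1 = ballistic
    division_o2: tuple = (0.3, 5.3, 21.0)
    division_p24: tuple = (0.7, 0.8, 0.4)
    lag_h: float = 4.0
    frame_interval_min: float = 10.0
    gel_half_um: float = GEL_HALF_UM
    gel_height_um: float = CHANNEL_HEIGHT_UM
    gel_length_um: float = 3000.0

    def fast_scale(self, o2):
        """Oxygen response multiplier of the fast mode (piecewise linear)."""
        return np.interp(o2, self.control_o2, self.fast_multiplier)

    def mean_speed(self, o2):
        """Expected per-step speed at oxygen tension o2 (mixture mean)."""
        slow = self.slow_median * np.exp(self.slow_sigma**2 / 2)
        fast = (
            self.fast_median_base
            * self.fast_scale(o2)
            * np.exp(self.fast_sigma**2 / 2)
        )
        return (1 - self.fast_fraction) * slow + self.fast_fraction * fast

    def p24(self, o2):
        """Per-cell division probability over 24 h at oxygen tension o2."""
        return np.interp(o2, self.division_o2, self.division_p24)

    def check_ordering(self) -> None:
        if self.fast_fraction == 0 or self.fast_median_base == 0:
            return  # no oxygen-sensitive mode: nothing to order
        s = self.mean_speed
        if not (s(5.3) > s(0.3) > s(21.0)):
            raise ValueError("speed response must satisfy s(5) > s(0.3) > s(21)")
        if abs(s(10.1) - s(21.0)) > 0.05 * s(21.0):
            raise ValueError("speed response must satisfy s(10) ~ s(21)")

    def default_n_cells(self) -> int:
        """Cell count implied by the seeding density and gel volume."""
        vol_ml = (
            (2 * self.gel_half_um) * self.gel_height_um * self.gel_length_um * 1e-12
        )  # um^3 -> cm^3
        return max(1, int(round(SEEDING_DENSITY_PER_ML * vol_ml)))


def _reflect(pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
    span = hi - lo
    p = np.mod(pos - lo, 2 * span)
    p = np.where(p > span, 2 * span - p, p)
    return p + lo


def simulate_tracks(
    oxygen,
    walk: WalkModel | None = None,
    n_cells: int | None = None,
    duration_h: float = 24.0,
    rng=None,
    condition: str = "synthetic",
    device_id: str = "synthetic-0",
) -> pd.DataFrame:
    """Simulate oxygen-dependent persistent random walks with divisions.

    ``oxygen`` is a callable phi(x_um, t_h) (a GelOxygenProfile or an
    IntermittentSchedule).  Cells start uniformly distributed in the gel;
    per-step speeds come from the walk model's mixture conditioned on the
    oxygen experienced ``lag_h`` earlier; directions persist between steps;
    positions reflect at the gel walls.  Each founder cell divides at most
    once, at a uniform random time, with probability p24 at its local
    oxygen: the mother track ends and two daughter tracks start at the
    division site, so live-cell counts at the endpoints measure the fold
    change (expected fold = 1 + mean p24).

    Returns a tidy track table (track_id, t_min, x_um, y_um, z_um,
    condition, device_id) sampled every frame interval.
    """
    walk = walk or WalkModel()
    walk.check_ordering()
    rng = np.random.default_rng(rng)
    if n_cells is None:
        n_cells = walk.default_n_cells()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")

    dt_min = walk.frame_interval_min
    dt_h = dt_min / 60.0
    n_steps = int(round(duration_h * 60.0 / dt_min))

    def sample_o2(x, t_h):
        t_eff = max(t_h - walk.lag_h, 0.0)
        return float(oxygen(x, t_eff))

    rows = []
    next_id = [0]

    def new_cell(x, y, z, t0_step, fast):
        cid = next_id[0]
        next_id[0] += 1
        return {
            "id": cid,
            "x": x,
            "y": y,
            "z": z,
            "birth": t0_step,
            "fast": fast,
            "dir": None,
        }

    # Founders: uniform in the gel; subpopulation label fixed at birth.
    founders = []
    for _ in range(n_cells):
        founders.append(
            new_cell(
                rng.uniform(-walk.gel_half_um, walk.gel_half_um),
                rng.uniform(0.0, walk.gel_length_um),
                rng.uniform(0.0, walk.gel_height_um),
                0,
                rng.random() < walk.fast_fraction,
            )
        )
    # Division decisions made per founder at its initial position.
    division_step = {}
    for cell in founders:
        p = walk.p24(float(oxygen(cell["x"], 0.0)))
        if rng.random() < p:
            # strictly inside the observation window, so every mother and
            # daughter track is observed at least twice
            division_step[cell["id"]] = int(rng.integers(2, max(n_steps, 3)))

    active = list(founders)
    for cell in active:
        rows.append((cell["id"], 0.0, cell["x"], cell["y"], cell["z"]))

    for step in range(1, n_steps + 1):
        t_h = step * dt_h
        born = []
        still = []
        for cell in active:
            # step the walk
            o2 = sample_o2(cell["x"], t_h)
            if cell["fast"]:
                median = walk.fast_median_base * walk.fast_scale(o2)
                sigma = walk.fast_sigma
            else:
                median = walk.slow_median
                sigma = walk.slow_sigma
            speed = median * np.exp(sigma * rng.standard_normal())  # um/h
            step_len = speed * dt_h
            fresh = rng.standard_normal(3)
            fresh /= np.linalg.norm(fresh)
            if cell["dir"] is None:
                direction = fresh
            else:
                direction = walk.persistence * cell["dir"] + (1 - walk.persistence) * fresh
                direction /= np.linalg.norm(direction)
            cell["dir"] = direction
            cell["x"] = _reflect(
                cell["x"] + step_len * direction[0], -walk.gel_half_um, walk.gel_half_um
            )
            cell["y"] = _reflect(cell["y"] + step_len * direction[1], 0.0, walk.gel_length_um)
            cell["z"] = _reflect(cell["z"] + step_len * direction[2], 0.0, walk.gel_height_um)

            if division_step.get(cell["id"]) == step:
                # mother ends; two daughters start here
                for fast in (cell["fast"], rng.random() < walk.fast_fraction):
                    d = new_cell(cell["x"], cell["y"], cell["z"], step, fast)
                    rows.append((d["id"], t_h * 60.0, d["x"], d["y"], d["z"]))
                    born.append(d)
            else:
                rows.append((cell["id"], t_h * 60.0, cell["x"], cell["y"], cell["z"]))
                still.append(cell)
        active = still + born

    table = pd.DataFrame(rows, columns=["track_id", "t_min", "x_um", "y_um", "z_um"])
    table["condition"] = condition
    table["device_id"] = device_id
    return table
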