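"""Parametric geometry of the double-layer oxygen-control chip.

The device is a PDMS disc bonded to a glass coverslip.  A central
collagen-gel channel is flanked by two media channels on the floor layer;
two gas channels run parallel above them at height ``H_g``, and a
gas-blocking polycarbonate (PC) film is embedded at height ``H_f`` to shut
out atmospheric oxygen.  The transport model works on a 2-D *x–z* cross
section of this stack: the 35 mm disc is modeled as a 35 mm wide slab, so
lateral oxygen leakage through the bulk PDMS — the effect that limits how
low the channel oxygen tension can go — is retained.

All lengths are stored in meters.  The coordinate origin sits at the
center of the gel channel: ``x`` is horizontal, normal to the channels,
``z`` is vertical from the device floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "Material",
    "MaterialProperties",
    "MATERIALS",
    "DeviceSpec",
    "MaterialGrid",
    "build_cross_section",
    "sweep_geometries",
]

MM = 1e-3
UM = 1e-6


class Material(IntEnum):
    """Material identity of a grid cell."""

    MEDIUM = 0
    GAS = 1
    GEL = 2
    PDMS = 3
    PC_FILM = 4
    GLASS = 5


@dataclass(frozen=True)
class MaterialProperties:
    """Physical properties of one device material.

    Parameters
    ----------
    density : float
        kg/m^3.  Informational; the flow field is never solved.
    viscosity : float
        Pa.s.  Informational.
    diffusivity : float
        Oxygen diffusivity D, m^2/s.
    solubility : float
        Oxygen solubility S, mM/atm.  Henry's law: c = S * p.
    """

    name: str
    density: float
    viscosity: float
    diffusivity: float
    solubility: float

    @property
    def permeability(self) -> float:
        """Oxygen permeability k = D * S (mM m^2 / (s atm)).

        The product that governs steady flux through a slab; series slabs
        add resistances t / k.
        """
        return self.diffusivity * self.solubility


# Default material properties.  Medium and gel are water-like; the PC film
# has ~2000x lower oxygen diffusivity than PDMS and the same solubility.
MATERIALS: dict[Material, MaterialProperties] = {
    Material.MEDIUM: MaterialProperties("medium", 1.0e3, 1.0e-3, 2.0e-9, 0.218),
    Material.GAS: MaterialProperties("gas", 1.0, 1.0e-5, 2.0e-5, 1.0),
    Material.GEL: MaterialProperties("gel", 1.0e3, 1.0e-3, 2.0e-9, 0.218),
    Material.PDMS: MaterialProperties("PDMS", 1.03e3, float("nan"), 4.0e-9, 1.25),
    Material.PC_FILM: MaterialProperties("PC_film", 1.2e3, float("nan"), 2.0e-12, 1.25),
    # Glass floor: no oxygen transport at all.
    Material.GLASS: MaterialProperties("glass", 2.5e3, float("nan"), 0.0, 0.0),
}


@dataclass(frozen=True)
class DeviceSpec:
    """Parametric description of the double-layer chip cross section.

    Defaults reproduce the fabricated device: 1300 um gel channel flanked
    by 500 um media channels, 1000 um gas channels whose inner edges are
    1300 um apart, all channels 150 um high, gas channels at H_g = 0.5 mm,
    PC film at H_f = 1 mm, 0.5 mm thick, in a 35 mm x 4 mm envelope.
    """

    device_width: float = 35.0 * MM
    device_height: float = 4.0 * MM
    gel_width: float = 1300.0 * UM
    media_width: float = 500.0 * UM
    gas_width: float = 1000.0 * UM
    gas_separation: float = 1300.0 * UM
    channel_height: float = 150.0 * UM
    H_g: float = 0.5 * MM
    H_f: float = 1.0 * MM
    film_thickness: float = 0.5 * MM

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lengths = {
            "device_width": self.device_width,
            "device_height": self.device_height,
            "gel_width": self.gel_width,
            "media_width": self.media_width,
            "gas_width": self.gas_width,
            "gas_separation": self.gas_separation,
            "channel_height": self.channel_height,
            "H_g": self.H_g,
            "H_f": self.H_f,
            "film_thickness": self.film_thickness,
        }
        for key, val in lengths.items():
            if not val > 0:
                raise ValueError(f"{key} must be positive, got {val!r}")
        if self.H_f < self.H_g + self.channel_height:
            raise ValueError(
                "PC film must lie above the gas channels: "
                f"H_f = {self.H_f} < H_g + channel_height = "
                f"{self.H_g + self.channel_height}"
            )
        if self.H_f + self.film_thickness > self.device_height:
            raise ValueError(
                "PC film must fit inside the device: H_f + film_thickness = "
                f"{self.H_f + self.film_thickness} > device_height = "
                f"{self.device_height}"
            )
        if self.aqueous_width > self.device_width:
            raise ValueError("aqueous layer wider than the device")
        if self.gas_outer > self.device_width / 2:
            raise ValueError("gas channels extend beyond the device envelope")
        if self.gas_separation < self.gel_width:
            # Design rule: the gas channels must not overlap the gel-channel
            # footprint, else they obstruct imaging of the gel.
            warnings.warn(
                "gas_separation < gel_width: gas channels overlap the gel "
                "channel footprint",
                stacklevel=2,
            )

    # Derived lateral landmarks (meters, positive half; mirrored about x=0).
    @property
    def gel_half(self) -> float:
        return self.gel_width / 2

    @property
    def aqueous_width(self) -> float:
        """Width of the contiguous water-like floor layer (gel + media)."""
        return self.gel_width + 2 * self.media_width

    @property
    def aqueous_half(self) -> float:
        return self.aqueous_width / 2

    @property
    def gas_inner(self) -> float:
        return self.gas_separation / 2

    @property
    def gas_outer(self) -> float:
        return self.gas_separation / 2 + self.gas_width

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, str]:
        """Key-value form with human units (mm)."""
        return {
            "device_width": f"{self.device_width / MM:g} mm",
            "device_height": f"{self.device_height / MM:g} mm",
            "gel_width": f"{self.gel_width / MM:g} mm",
            "media_width": f"{self.media_width / MM:g} mm",
            "gas_width": f"{self.gas_width / MM:g} mm",
            "gas_separation": f"{self.gas_separation / MM:g} mm",
            "channel_height": f"{self.channel_height / MM:g} mm",
            "H_g": f"{self.H_g / MM:g} mm",
            "H_f": f"{self.H_f / MM:g} mm",
            "film_thickness": f"{self.film_thickness / MM:g} mm",
        }

    @classmethod
    def from_dict(cls, data: dict) -> "DeviceSpec":
        kwargs = {key: _parse_length(val) for key, val in data.items()}
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeviceSpec":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_UNIT_FACTORS = {"m": 1.0, "mm": MM, "um": UM, "µm": UM}


def _parse_length(value) -> float:
    """Parse '0.5 mm' / '150 um' / bare number (meters) into meters."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) == 2 and parts[1] in _UNIT_FACTORS:
        return float(parts[0]) * _UNIT_FACTORS[parts[1]]
    raise ValueError(f"cannot parse length {value!r}")


@dataclass
class MaterialGrid:
    """Rectilinear material-labeled discretization of the cross section.

    ``material`` is indexed ``[iz, ix]``; cell ``(iz, ix)`` spans
    ``x_edges[ix]..x_edges[ix+1]`` by ``z_edges[iz]..z_edges[iz+1]``.
    The floor (z = 0) is glass and is treated as a zero-flux boundary by
    the solver rather than as grid cells.
    """

    spec: DeviceSpec
    x_edges: np.ndarray
    z_edges: np.ndarray
    material: np.ndarray  # (nz, nx) int, Material values
    diffusivity: np.ndarray = field(init=False)  # (nz, nx) m^2/s
    solubility: np.ndarray = field(init=False)  # (nz, nx) mM/atm

    def __post_init__(self) -> None:
        d_lut = np.zeros(len(Material))
        s_lut = np.zeros(len(Material))
        for mat, props in MATERIALS.items():
            d_lut[mat] = props.diffusivity
            s_lut[mat] = props.solubility
        self.diffusivity = d_lut[self.material]
        self.solubility = s_lut[self.material]

    @property
    def nx(self) -> int:
        return len(self.x_edges) - 1

    @property
    def nz(self) -> int:
        return len(self.z_edges) - 1

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def dz(self) -> np.ndarray:
        return np.diff(self.z_edges)

    @property
    def permeability(self) -> np.ndarray:
        """Per-cell oxygen permeability k = D * S."""
        return self.diffusivity * self.solubility

    @property
    def cell_areas(self) -> np.ndarray:
        """(nz, nx) cell areas in m^2 (per unit depth in y)."""
        return np.outer(self.dz, self.dx)

    def region_area(self, mat: Material) -> float:
        """Total cross-sectional area occupied by a material, m^2."""
        return float(self.cell_areas[self.material == mat].sum())

    def cell_index(self, x: float, z: float) -> tuple[int, int]:
        """Index of the cell containing (x, z); half-open [low, high)."""
        if not (self.x_edges[0] <= x <= self.x_edges[-1]):
            raise ValueError(f"x = {x} outside grid")
        if not (self.z_edges[0] <= z <= self.z_edges[-1]):
            raise ValueError(f"z = {z} outside grid")
        ix = min(int(np.searchsorted(self.x_edges, x, side="right")) - 1, self.nx - 1)
        iz = min(int(np.searchsorted(self.z_edges, z, side="right")) - 1, self.nz - 1)
        return iz, ix

    def material_at(self, x: float, z: float) -> Material:
        iz, ix = self.cell_index(x, z)
        return Material(self.material[iz, ix])

    def to_csv(self, path: str | Path) -> None:
        """Export the material map as a delimited table for inspection."""
        import pandas as pd

        frame = pd.DataFrame(
            self.material,
            index=np.round(self.z_centers / UM, 3),
            columns=np.round(self.x_centers / UM, 3),
        )
        frame.index.name = "z_um"
        frame.to_csv(path)


def _segment_edges(breaks: np.ndarray, resolution: float) -> np.ndarray:
    """Edge array covering [breaks[0], breaks[-1]] with every breakpoint on
    an edge; each segment is subdivided uniformly at <= resolution."""
    edges = [breaks[0]]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(np.ceil((hi - lo) / resolution - 1e-9)))
        edges.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(edges)


def build_cross_section(
    spec: DeviceSpec,
    resolution: float | tuple[float, float] = 25.0 * UM,
) -> MaterialGrid:
    """Discretize the x-z cross section into a material-labeled grid.

    The media and gel channels are merged into one contiguous aqueous layer
    of width ``gel_width + 2 * media_width`` on the floor (the slice is
    taken between the PDMS posts that separate them, and the gel is labeled
    distinctly so profiles can be sampled on it).  Gas channels sit at
    ``z in [H_g, H_g + channel_height]``, the PC film spans the full
    lateral extent at ``z in [H_f, H_f + film_thickness]``, and everything
    else is PDMS.  The z = 0 floor is glass (zero flux).

    Every material interface falls on a grid edge: segments between
    interfaces are subdivided at the requested resolution (refined where a
    segment is thinner than one cell), so region areas are exact and ties
    cannot occur — material assignment uses half-open [low, high) intervals
    on cell centers.
    """
    spec.validate()
    if np.isscalar(resolution):
        res_x = res_z = float(resolution)
    else:
        res_x, res_z = map(float, resolution)

    half_w = spec.device_width / 2
    x_breaks = np.unique(
        np.array(
            [
                -half_w,
                -spec.gas_outer,
                -spec.gas_inner,
                -spec.aqueous_half,
                -spec.gel_half,
                spec.gel_half,
                spec.aqueous_half,
                spec.gas_inner,
                spec.gas_outer,
                half_w,
            ]
        )
    )
    z_breaks = np.unique(
        np.array(
            [
                0.0,
                spec.channel_height,
                spec.H_g,
                spec.H_g + spec.channel_height,
                spec.H_f,
                spec.H_f + spec.film_thickness,
                spec.device_height,
            ]
        )
    )
    x_edges = _segment_edges(x_breaks, res_x)
    z_edges = _segment_edges(z_breaks, res_z)

    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    zc = 0.5 * (z_edges[:-1] + z_edges[1:])
    X, Z = np.meshgrid(xc, zc)

    material = np.full(X.shape, int(Material.PDMS), dtype=np.int8)

    # Aqueous floor layer: gel at the center, media on the flanks.
    floor = Z < spec.channel_height
    material[floor & (np.abs(X) < spec.aqueous_half)] = int(Material.MEDIUM)
    material[floor & (np.abs(X) < spec.gel_half)] = int(Material.GEL)

    # Gas channels.
    gas_band = (Z >= spec.H_g) & (Z < spec.H_g + spec.channel_height)
    gas_lateral = (np.abs(X) >= spec.gas_inner) & (np.abs(X) < spec.gas_outer)
    gas_cells = gas_band & gas_lateral
    material[gas_cells] = int(Material.GAS)

    # PC film, full lateral extent.
    film = (Z >= spec.H_f) & (Z < spec.H_f + spec.film_thickness)
    if np.any(film & (material != int(Material.PDMS))):
        raise ValueError(
            "geometry conflict: PC film intersects a channel "
            "(violated invariant: H_f >= H_g + channel_height)"
        )
    material[film] = int(Material.PC_FILM)

    grid = MaterialGrid(spec=spec, x_edges=x_edges, z_edges=z_edges, material=material)
    # PC film must be resolved by at least two cell layers vertically.
    film_rows = np.unique(np.nonzero(material == int(Material.PC_FILM))[0])
    if film_rows.size < 2:
        raise ValueError("PC film resolved by fewer than 2 vertical cell layers")
    return grid


def sweep_geometries(
    H_g_values,
    h_f_factor: float = 2.0,
    base: DeviceSpec | None = None,
    allow_outside_range: bool = False,
) -> list[DeviceSpec]:
    """Device specs for a (H_g, H_f) design sweep with H_f = 2 * H_g.

    Values outside the fabricated sweep range [0.25, 1.5] mm are rejected
    unless ``allow_outside_range`` is set.  A value whose film would poke
    out of the device envelope is always rejected.
    """
    base = base or DeviceSpec()
    specs = []
    for hg in H_g_values:
        hg = float(hg)
        if not allow_outside_range and not (0.25 * MM <= hg <= 1.5 * MM):
            raise ValueError(
                f"H_g = {hg / MM:g} mm outside the sweep range [0.25, 1.5] mm"
            )
        hf = h_f_factor * hg
        if hf + base.film_thickness > base.device_height:
            raise ValueError(
                f"H_g = {hg / MM:g} mm puts the film outside the device "
                f"(H_f + film_thickness > {base.device_height / MM:g} mm)"
            )
        specs.append(replace(base, H_g=hg, H_f=hf))
    return specs
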