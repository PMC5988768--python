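"""Jones-calculus forward model: two-channel A-scan amplitudes from a tissue model.

The instrument is a 1310 nm swept-source PS-OCT system: a quarter-wave plate
at 45 deg circularly polarises the light incident on the sample, and the
returning light is split into orthogonal components whose amplitudes A_V and
A_H are detected.  The sample acts as a linear retarder whose retardance
grows with the birefringence integrated along the optical path, so the
channel amplitude ratio encodes the accumulated phase retardation, folded
into [0, pi/2] by the system's quarter-cycle phase wrap.

Detection-model convention
--------------------------
We model the detected field as the Jones chain

    E_det = QWP(45) . J(pi/2 + 2*psi_rt(z), theta(z)) . QWP(45) . E_V

where ``psi_rt(z) = (2*pi/lambda0) * 2 * integral(dn dz')`` is the round-trip
retardation and the co-axial quarter-wave bias centres an isotropic sample at
equal channel amplitudes.  The resulting amplitudes are axis-independent:

    A_V = |sin(pi/4 + psi_rt)|,   A_H = |cos(pi/4 + psi_rt)|

so arctan(A_V/A_H) is pi/4 in isotropic tissue and climbs at the round-trip
rate 2*pi*2*dn/lambda0 per unit physical depth, folding at pi/2.  Whether
real hardware reports single- or double-pass retardance is immaterial here:
the simulator is calibrated through :func:`psoct.tissue.dn_for_brc`, making
every recovered gradient convention-independent.

Speckle is multiplicative, per channel and pixel, with unit mean (a damped
Rayleigh model); pixels outside tissue carry an additive Rayleigh noise floor
only.  Amplitudes are generated directly in the z-domain: no k-space
reconstruction, dispersion or sensitivity roll-off is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .errors import DomainError, InvalidGeometryError, RangeError
from .tissue import DEFAULT_WAVELENGTH_NM, TissueModel, brc_for_dn, dn_for_brc  # noqa: F401

__all__ = [
    "AcquisitionParams",
    "RetarderElement",
    "BScanPair",
    "retarder_matrix",
    "qwp",
    "berek_measure",
    "simulate_ascan",
    "simulate_bscan",
    "simulate_volume",
    "brc_for_dn",
]

#: Unit-mean Rayleigh scale: Rayleigh(scale) has mean scale*sqrt(pi/2).
_RAYLEIGH_UNIT_MEAN_SCALE = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class AcquisitionParams:
    """Swept-source acquisition geometry and noise settings.

    ``noise_sigma`` scales the multiplicative speckle: the per-channel
    amplitude factor is ``1 + noise_sigma * (r - 1)`` with ``r`` unit-mean
    Rayleigh.  The default gives a single-A-scan retardation SD of about
    1.3 deg at mid-fold, the repeatability scale of the instrument's Berek
    validation sweeps.
    """

    wavelength: float = DEFAULT_WAVELENGTH_NM  # nm, centre wavelength
    axial_pixel_air: float = 5.0  # um per axial pixel, in air (Nyquist of 10 um resolution)
    axial_resolution_air: float = 10.0  # um, in air
    lateral_pixel: float = 20.0  # um
    image_width: float = 10.0  # mm
    n_depth: int = 256  # axial pixels per A-scan
    n_ascans: int = 500  # lateral pixels per B-scan
    bscan_separation: float = 25.0  # um between adjacent B-scans
    noise_sigma: float = 0.06  # relative amplitude noise scale, 0 = noiseless
    noise_floor: float = 0.01  # additive amplitude floor outside tissue
    seed: int = 0

    def __post_init__(self):
        if self.wavelength <= 0:
            raise InvalidGeometryError("wavelength must be > 0")
        if self.axial_pixel_air <= 0 or self.lateral_pixel <= 0:
            raise InvalidGeometryError("pixel sizes must be > 0")
        if self.n_ascans < 1 or self.n_depth < 1:
            raise InvalidGeometryError("n_ascans and n_depth must be >= 1")
        if self.noise_sigma < 0 or self.noise_floor < 0:
            raise InvalidGeometryError("noise levels must be >= 0")

    @property
    def axial_pixel_air_mm(self) -> float:
        return self.axial_pixel_air * 1e-3

    @property
    def lateral_pixel_mm(self) -> float:
        return self.lateral_pixel * 1e-3

    def lateral_positions(self) -> np.ndarray:
        """Lateral pixel-centre positions (mm) across the image width."""
        return (np.arange(self.n_ascans) + 0.5) * self.lateral_pixel_mm


@dataclass(frozen=True)
class RetarderElement:
    """Linear retarder: retardance in [0, 2*pi), fast-axis orientation in [0, pi)."""

    retardance: float
    axis: float

    def __post_init__(self):
        if not (0.0 <= self.retardance < 2.0 * math.pi + 1e-12):
            raise DomainError(f"retardance must be in [0, 2*pi), got {self.retardance}")
        if not (0.0 <= self.axis < math.pi + 1e-12):
            raise DomainError(f"axis must be in [0, pi), got {self.axis}")


@dataclass
class BScanPair:
    """Co-registered vertical/horizontal channel amplitude images (depth x lateral)."""

    Av: np.ndarray
    Ah: np.ndarray
    params: AcquisitionParams
    truth: Optional[TissueModel] = None

    def __post_init__(self):
        from .errors import ShapeMismatchError

        if self.Av.shape != self.Ah.shape:
            raise ShapeMismatchError(
                f"channel shapes disagree: {self.Av.shape} vs {self.Ah.shape}"
            )
        if np.any(self.Av < 0) or np.any(self.Ah < 0):
            raise DomainError("channel amplitudes must be >= 0")

    @property
    def shape(self):
        return self.Av.shape


def retarder_matrix(elem: RetarderElement) -> np.ndarray:
    """2x2 complex Jones operator of a linear retarder (unitary; identity at 0)."""
    c = math.cos(elem.retardance / 2.0)
    s = math.sin(elem.retardance / 2.0)
    c2 = math.cos(2.0 * elem.axis)
    s2 = math.sin(2.0 * elem.axis)
    return np.array(
        [[c + 1j * s * c2, 1j * s * s2], [1j * s * s2, c - 1j * s * c2]],
        dtype=complex,
    )


def qwp(axis: float) -> np.ndarray:
    """Quarter-wave plate Jones operator at the given fast-axis orientation."""
    return retarder_matrix(RetarderElement(math.pi / 2.0, axis))


#: Source polarisation entering the sample arm (vertical linear), (E_H, E_V).
_SOURCE_STATE = np.array([0.0, 1.0], dtype=complex)


def _sandwich_amplitudes(retardance, axis):
    """|E_V|, |E_H| after QWP(45) . J(retardance, axis) . QWP(45) acting on E_V.

    Closed form of the Jones product: A_V = |sin(retardance/2)|,
    A_H = |cos(retardance/2)|, independent of ``axis``.  The explicit matrix
    chain is exercised against this in the test suite.
    """
    half = np.asarray(retardance, dtype=float) / 2.0
    return np.abs(np.sin(half)), np.abs(np.cos(half))


def fold_quarter(angle: np.ndarray | float) -> np.ndarray | float:
    """Fold an angle (radians) into [0, pi/2] as the system's phase wrap does."""
    a = np.abs(np.asarray(angle, dtype=float))
    a = np.mod(a, math.pi)
    folded = np.where(a > math.pi / 2.0, math.pi - a, a)
    return folded if folded.ndim else float(folded)


def berek_measure(
    set_retardation: float,
    set_axis: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> float:
    """Virtual Berek-compensator experiment: measured retardation in degrees.

    Propagates the circularly polarised beam through the Berek element (double
    pass: the element is traversed on the way in and out), applies the
    channel-amplitude arctan read-out and returns the result folded into
    [0 deg, 90 deg].  With ``noise_sd = 0`` the measured value equals the set
    retardation folded at 90 deg, at every optic-axis setting.
    """
    if not (0.0 <= set_retardation <= 180.0):
        raise DomainError(f"set_retardation must be in [0, 180] deg, got {set_retardation}")
    if not (0.0 <= set_axis <= 180.0):
        raise DomainError(f"set_axis must be in [0, 180] deg, got {set_axis}")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")

    theta = math.radians(set_retardation)
    axis = math.radians(set_axis) % math.pi
    # Double pass through the element: round-trip retardance 2*theta.
    element = retarder_matrix(RetarderElement(math.fmod(2.0 * theta, 2.0 * math.pi), axis))
    e = qwp(math.pi / 4.0) @ element @ qwp(math.pi / 4.0) @ _SOURCE_STATE
    av, ah = abs(e[1]), abs(e[0])
    measured = math.degrees(math.atan2(av, ah))
    if noise_sd > 0.0:
        rng = np.random.default_rng(seed)
        measured += float(rng.normal(0.0, noise_sd))
    return float(math.degrees(fold_quarter(math.radians(measured))))


def _render_columns(
    tissue: TissueModel,
    x_positions: np.ndarray,
    params: AcquisitionParams,
    rng: Optional[np.random.Generator],
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free or speckled (Av, Ah) images for the given lateral positions (mm)."""
    x = np.asarray(x_positions, dtype=float)
    if np.any(x < 0) or np.any(x > tissue.block_width):
        raise RangeError("lateral position outside tissue block")

    n = tissue.refractive_index
    pix_mm = params.axial_pixel_air_mm
    cols = np.clip((x / tissue.dx).astype(int), 0, tissue.dn_map.shape[1] - 1)

    z_air = np.arange(params.n_depth)[:, None] * pix_mm  # (nz, 1), optical depth
    surface = tissue.surface_height[cols][None, :]  # (1, ncol)
    z_t = (z_air - surface) / n  # physical depth below the local surface
    inside = (z_t >= 0.0) & (z_t < tissue.thickness_map[cols][None, :])

    rows = np.clip((z_t / tissue.dz).astype(int), 0, tissue.dn_map.shape[0] - 1)
    dn = np.where(inside, tissue.dn_map[rows, cols[None, :]], 0.0)
    # Round-trip retardation accumulated down to each pixel (rad).
    wavelength_mm = params.wavelength * 1e-6
    dpsi = 4.0 * math.pi / wavelength_mm * dn * (pix_mm / n)
    psi = np.cumsum(dpsi, axis=0)

    av, ah = _sandwich_amplitudes(math.pi / 2.0 + 2.0 * psi, tissue.axis_map[rows, cols])
    scatter = np.where(inside, tissue.scatter_profile[rows], 0.0)
    av = av * scatter
    ah = ah * scatter

    if rng is not None and params.noise_sigma > 0.0:
        shape = av.shape
        mult_v = 1.0 + params.noise_sigma * (
            rng.rayleigh(_RAYLEIGH_UNIT_MEAN_SCALE, shape) - 1.0
        )
        mult_h = 1.0 + params.noise_sigma * (
            rng.rayleigh(_RAYLEIGH_UNIT_MEAN_SCALE, shape) - 1.0
        )
        av = av * np.maximum(mult_v, 0.0)
        ah = ah * np.maximum(mult_h, 0.0)
    if rng is not None and params.noise_floor > 0.0:
        outside = ~inside
        av = av + outside * params.noise_floor * rng.rayleigh(
            _RAYLEIGH_UNIT_MEAN_SCALE, av.shape
        )
        ah = ah + outside * params.noise_floor * rng.rayleigh(
            _RAYLEIGH_UNIT_MEAN_SCALE, ah.shape
        )
    return av, ah


def simulate_ascan(
    tissue: TissueModel,
    lateral_pos: float,
    params: AcquisitionParams,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Single depth profile (Av, Ah) at a lateral position (mm).

    ``seed=None`` renders the noiseless profile; otherwise speckle and the
    outside-tissue noise floor are applied deterministically from the seed.
    """
    rng = None if seed is None else np.random.default_rng(seed)
    av, ah = _render_columns(tissue, np.array([lateral_pos]), params, rng)
    return av[:, 0], ah[:, 0]


def simulate_bscan(
    tissue: TissueModel,
    params: AcquisitionParams,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> BScanPair:
    """One full B-scan pair across the image width (``seed=None``: noiseless)."""
    if seed is None:
        rng = None
    elif isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    av, ah = _render_columns(tissue, params.lateral_positions(), params, rng)
    return BScanPair(Av=av, Ah=ah, params=params, truth=tissue)


def simulate_volume(
    tissue: TissueModel,
    params: AcquisitionParams,
    n_bscans: int = 5,
    seed: int | np.random.SeedSequence | None = None,
) -> list[BScanPair]:
    """Adjacent co-registered B-scan pairs at ``bscan_separation`` spacing.

    The tissue maps do not vary in the out-of-plane direction, so adjacent
    B-scans differ only in their speckle realisation (one spawned RNG stream
    per B-scan).
    """
    if n_bscans < 1:
        raise DomainError("n_bscans must be >= 1")
    if seed is None:
        return [simulate_bscan(tissue, params, None) for _ in range(n_bscans)]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_bscans)
    return [
        simulate_bscan(tissue, params, np.random.default_rng(child))
        for child in children
    ]
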