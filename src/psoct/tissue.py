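"""Synthetic cartilage tissue models for the indentation study.

A :class:`TissueModel` is a per-sample ground-truth map of birefringence
(Delta-n), optic-axis orientation, backscatter and surface height over a
(depth, lateral) grid of the cartilage block.  Models are generated from
:class:`GradePreset` entries whose default means and between-sample SDs are
the retardation-gradient group statistics of the bovine study (three
degeneration grades G0/G1/G2 in three imaging configurations), so that the
true birefringence coefficient (BRC) of each simulated specimen is a draw
from the configured group distribution.

The grade -> Delta-n mapping is phenomenological: loss of birefringence with
degeneration is explained mechanistically by collagen-fibre destructuring,
but no microstructural model is available, so Delta-n is calibrated directly
to the target retardation gradient through :func:`dn_for_brc`.  That makes
the generator a statistical contract, not a biomechanical simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
import yaml
from scipy.stats import truncnorm

from .errors import DomainError, InvalidGeometryError

GRADE_LABELS = ("G0", "G1", "G2")
CONFIG_LABELS = ("XZ_indented", "XZ_nonindented", "XY")

#: Refractive index of bovine cartilage used for air->tissue depth calibration.
CARTILAGE_REFRACTIVE_INDEX = 1.36

#: Centre wavelength of the swept source, nm.
DEFAULT_WAVELENGTH_NM = 1310.0


def brc_for_dn(dn: float, wavelength_nm: float = DEFAULT_WAVELENGTH_NM) -> float:
    """Retardation gradient (rad/mm of physical tissue depth) for a uniform Delta-n.

    The package adopts the round-trip convention: the measured retardation
    accumulates at ``(2*pi/lambda0) * 2 * dn`` per unit physical depth, i.e.
    the phase difference acquired over the full down-and-back optical path.
    """
    if dn < 0:
        raise DomainError(f"dn must be >= 0, got {dn}")
    if wavelength_nm <= 0:
        raise DomainError(f"wavelength must be > 0, got {wavelength_nm}")
    wavelength_mm = wavelength_nm * 1e-6
    return 4.0 * math.pi * dn / wavelength_mm


def dn_for_brc(target_brc: float, wavelength_nm: float = DEFAULT_WAVELENGTH_NM) -> float:
    """Uniform Delta-n whose ideal measured retardation slope is ``target_brc``.

    Exact inverse of :func:`brc_for_dn` under the same round-trip convention.
    """
    if target_brc < 0:
        raise DomainError(f"target_brc must be >= 0, got {target_brc}")
    if wavelength_nm <= 0:
        raise DomainError(f"wavelength must be > 0, got {wavelength_nm}")
    wavelength_mm = wavelength_nm * 1e-6
    return target_brc * wavelength_mm / (4.0 * math.pi)


@dataclass(frozen=True)
class GradePreset:
    """Ground-truth BRC distribution for one grade in one imaging configuration."""

    grade_label: str
    config_label: str
    true_brc_mean: float  # rad/mm
    true_brc_sd: float  # rad/mm, between-sample SD
    n_samples: int
    banding_asymmetry: float = 0.0  # lateral linear modulation factor of Delta-n

    def __post_init__(self):
        if self.grade_label not in GRADE_LABELS:
            raise DomainError(f"unknown grade label {self.grade_label!r}")
        if self.config_label not in CONFIG_LABELS:
            raise DomainError(f"unknown configuration label {self.config_label!r}")
        if self.true_brc_mean < 0 or self.true_brc_sd < 0:
            raise DomainError("true_brc_mean and true_brc_sd must be >= 0")
        if self.n_samples < 2:
            raise DomainError("n_samples must be >= 2")
        if self.banding_asymmetry < 0:
            raise DomainError("banding_asymmetry must be >= 0")


@dataclass(frozen=True)
class IndentationGeometry:
    """Channel-indentation geometry: a flat indenter with a gap the tissue bulges into."""

    channel_gap: float = 1.0  # mm
    strain: float = 0.56  # axial creep strain under the indenter
    bulge_height: float = 0.3  # mm, rise of the surface inside the channel
    block_width: float = 10.0  # mm, lateral extent of the cartilage block

    def __post_init__(self):
        if not (0.0 < self.strain < 1.0):
            raise InvalidGeometryError(f"strain must be in (0, 1), got {self.strain}")
        if self.channel_gap <= 0:
            raise InvalidGeometryError("channel_gap must be > 0")
        if self.bulge_height < 0:
            raise InvalidGeometryError("bulge_height must be >= 0")
        if self.block_width <= 0:
            raise InvalidGeometryError("block_width must be > 0")

    @property
    def analysis_position(self) -> float:
        """Default lateral analysis position (mm): bulge shoulder, channel edge + 0.25 mm."""
        return self.block_width / 2.0 + self.channel_gap / 2.0 + 0.25


@dataclass
class TissueModel:
    """Per-sample ground truth over a (depth, lateral) grid in physical tissue coordinates.

    ``dn_map[i, j]`` is the local birefringence at depth ``i * dz`` below the
    local surface and lateral position ``j * dx``; ``surface_height[j]`` is the
    optical (in-air) depth of the tissue surface from the top of the image, and
    ``thickness_map[j]`` the local physical tissue thickness in the fixed,
    indented state.
    """

    thickness: float  # mm, uncompressed cartilage depth
    dz: float  # mm per dn_map row (physical tissue depth)
    dx: float  # mm per dn_map column
    dn_map: np.ndarray  # (nz, nx)
    axis_map: np.ndarray  # (nz, nx), radians
    scatter_profile: np.ndarray  # (nz,), relative backscatter amplitude vs depth
    surface_height: np.ndarray  # (nx,), mm, in-air optical depth of the surface
    thickness_map: np.ndarray  # (nx,), mm, local physical thickness
    truth_brc: float  # rad/mm at the analysis position under ideal reconstruction
    refractive_index: float = CARTILAGE_REFRACTIVE_INDEX
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    grade_label: Optional[str] = None
    config_label: Optional[str] = None
    sample_index: int = 0
    analysis_position: float = field(default=0.0)  # mm

    def __post_init__(self):
        if self.thickness <= 0 or self.dz <= 0 or self.dx <= 0:
            raise InvalidGeometryError("thickness and grid spacings must be > 0")
        if self.dn_map.ndim != 2 or self.dn_map.size == 0:
            raise InvalidGeometryError("dn_map must be a non-empty 2-D grid")
        if self.dn_map.shape != self.axis_map.shape:
            raise InvalidGeometryError("dn_map and axis_map shapes disagree")
        nz, nx = self.dn_map.shape
        if self.scatter_profile.shape != (nz,):
            raise InvalidGeometryError("scatter_profile length must match dn_map depth")
        if self.surface_height.shape != (nx,) or self.thickness_map.shape != (nx,):
            raise InvalidGeometryError("surface_height/thickness_map must match dn_map width")
        if np.any(self.dn_map < 0):
            raise InvalidGeometryError("dn_map must be >= 0 everywhere")

    @property
    def block_width(self) -> float:
        return self.dn_map.shape[1] * self.dx


_CONFIG_CODE = {label: i for i, label in enumerate(CONFIG_LABELS)}
_GRADE_CODE = {label: i for i, label in enumerate(GRADE_LABELS)}


def tissue_seed_sequence(preset: GradePreset, sample_index: int, seed: int,
                         stream: int = 0) -> np.random.SeedSequence:
    """Counter-based seed fan-out: adding samples never perturbs existing ones."""
    return np.random.SeedSequence(
        [int(seed), _CONFIG_CODE[preset.config_label],
         _GRADE_CODE[preset.grade_label], int(sample_index), int(stream)]
    )


def draw_truth_brc(preset: GradePreset, sample_index: int, seed: int) -> float:
    """One specimen's true BRC: Normal(mean, sd) truncated at zero (BRC >= 0)."""
    if preset.true_brc_sd == 0.0:
        return preset.true_brc_mean
    rng = np.random.default_rng(tissue_seed_sequence(preset, sample_index, seed))
    a = (0.0 - preset.true_brc_mean) / preset.true_brc_sd
    return float(truncnorm.rvs(a, np.inf, loc=preset.true_brc_mean,
                               scale=preset.true_brc_sd, random_state=rng))


def make_tissue(
    preset: GradePreset,
    geometry: IndentationGeometry | None = None,
    sample_index: int = 0,
    seed: int = 0,
    *,
    thickness: float = 2.0,
    surface_offset: float = 0.35,
    dz: float = 0.005,
    dx: float = 0.02,
    bulge_dn_floor: float = 0.3,
    attenuation_mm: float = 1.0,
) -> TissueModel:
    """Generate one specimen's ground-truth tissue model.

    Parameters
    ----------
    preset
        Grade/configuration preset whose (mean, SD) the specimen's true BRC is
        drawn from.
    geometry
        Channel-indentation geometry; defaults to the study geometry (1 mm gap,
        56 % creep strain).
    sample_index, seed
        Deterministic identity of the specimen: identical
        ``(preset, geometry, sample_index, seed)`` give bit-identical models.
    thickness
        Uncompressed cartilage depth, mm (documented assumption; the source
        study states block size only).
    surface_offset
        In-air optical depth of the flat tissue surface from the image top, mm.
    dz, dx
        Grid spacing of the ground-truth maps, mm.
    bulge_dn_floor
        Relative Delta-n retained at the centre of the bulge (the tissue in the
        channel gap is less compressed, hence less fibre reorientation).
    attenuation_mm
        1/e depth of the backscatter amplitude profile, mm.

    Notes
    -----
    Indented-configuration models place elevated, laterally asymmetric Delta-n
    under the indenter flanks and a central bulge in ``surface_height``; the
    lateral modulation is normalised to 1 exactly at the default analysis
    position (channel edge + 0.25 mm) so that ``truth_brc`` is the gradient an
    ideal reconstruction recovers there.  Non-indented and XY models are
    laterally uniform with a flat surface.
    """
    if geometry is None:
        geometry = IndentationGeometry()
    if thickness <= 0 or dz <= 0 or dx <= 0:
        raise InvalidGeometryError("thickness, dz and dx must be > 0")
    if surface_offset < 0:
        raise InvalidGeometryError("surface_offset must be >= 0")

    nz = max(2, int(round(thickness / dz)))
    nx = max(2, int(round(geometry.block_width / dx)))
    x = (np.arange(nx) + 0.5) * dx  # lateral position, mm

    truth_brc = draw_truth_brc(preset, sample_index, seed)
    dn0 = dn_for_brc(truth_brc, DEFAULT_WAVELENGTH_NM)

    indented = preset.config_label == "XZ_indented"
    x_c = geometry.block_width / 2.0
    half_gap = geometry.channel_gap / 2.0
    x_analysis = geometry.analysis_position if indented else x_c

    if indented:
        # Lateral Delta-n profile: full under the indenter, relaxed in the bulge.
        u = np.clip((x - x_c) / half_gap, -1.0, 1.0)
        in_gap = np.abs(x - x_c) < half_gap
        profile = np.ones(nx)
        profile[in_gap] = bulge_dn_floor + (1.0 - bulge_dn_floor) * (
            1.0 - np.cos(math.pi * np.abs(u[in_gap]))
        ) / 2.0
        # Asymmetric banding around the bulge: linear modulation, exactly 1 at
        # the analysis position so truth_brc is recovered there.
        profile = profile * (
            1.0 + preset.banding_asymmetry * (x - x_analysis) / geometry.block_width
        )
        profile = np.clip(profile, 0.0, None)

        bulge = np.zeros(nx)
        bulge[in_gap] = geometry.bulge_height * (1.0 + np.cos(math.pi * u[in_gap])) / 2.0
        surface_height = np.maximum(surface_offset - bulge, 0.02)

        # Under the indenter the tissue is held at the creep strain; inside the
        # channel it keeps the height it recovered by bulging.
        compressed = thickness * (1.0 - geometry.strain)
        thickness_map = np.full(nx, compressed) + bulge
    else:
        profile = np.ones(nx)
        surface_height = np.full(nx, surface_offset)
        thickness_map = np.full(nx, thickness)

    dn_map = dn0 * np.broadcast_to(profile, (nz, nx)).copy()
    # Optic-axis orientation varies gently across the block; the circular
    # incidence design makes the measurement independent of it.
    axis_map = np.broadcast_to(
        math.pi / 4.0 + 0.5 * np.sin(2.0 * math.pi * x / geometry.block_width), (nz, nx)
    ).copy()
    depth = np.arange(nz) * dz
    scatter_profile = np.exp(-depth / attenuation_mm)

    return TissueModel(
        thickness=thickness,
        dz=dz,
        dx=dx,
        dn_map=dn_map,
        axis_map=axis_map,
        scatter_profile=scatter_profile,
        surface_height=surface_height,
        thickness_map=thickness_map,
        truth_brc=truth_brc,
        grade_label=preset.grade_label,
        config_label=preset.config_label,
        sample_index=sample_index,
        analysis_position=x_analysis,
    )


# ---------------------------------------------------------------------------
# Preset registry


def load_presets(path=None) -> dict[tuple[str, str], GradePreset]:
    """Load a preset registry keyed by (config_label, grade_label).

    With no ``path``, loads the packaged ``table1_defaults.yaml`` holding the
    study's group means/SDs and sample counts.
    """
    if path is None:
        text = resources.files("psoct").joinpath("data/table1_defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    registry: dict[tuple[str, str], GradePreset] = {}
    for entry in raw["presets"]:
        preset = GradePreset(**entry)
        registry[(preset.config_label, preset.grade_label)] = preset
    return registry


def default_presets() -> dict[tuple[str, str], GradePreset]:
    """The study's default grade presets (group means/SDs, n = 10/8/8)."""
    return load_presets()
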