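"""Reflectivity and retardation images from a two-channel B-scan pair.

The detector reports orthogonal amplitudes A_V and A_H per pixel; the
intensity image is R(z) ~ Av^2 + Ah^2 and the phase (retardation) image is
delta(z) = arctan(A_V / A_H), which lies in [0, pi/2] by construction --
the system's quarter-cycle phase wrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError
from .optics import AcquisitionParams, BScanPair


@dataclass
class IntensityImage:
    """Relative reflectivity, depth x lateral, linear scale."""

    values: np.ndarray
    params: AcquisitionParams

    def log_display(self, floor_db: float = -60.0) -> np.ndarray:
        """dB-scaled copy for display only; all computation uses linear values."""
        ref = float(self.values.max()) or 1.0
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(self.values / ref)
        return np.clip(db, floor_db, 0.0)


@dataclass
class PhaseImage:
    """Per-pixel retardation in [0, pi/2] plus a validity mask.

    ``valid`` is False where both channels are exactly zero (no signal); the
    retardation there is defined as 0 rather than raising, since pixels above
    the tissue surface are routinely at the noise floor.
    """

    values: np.ndarray
    valid: np.ndarray
    params: AcquisitionParams


def compute_reflectivity(pair: BScanPair) -> IntensityImage:
    """R(z) ~ Av^2 + Ah^2 per pixel; invariant under channel swap."""
    if pair.Av.shape != pair.Ah.shape:
        raise ShapeMismatchError("channel shapes disagree")
    return IntensityImage(values=pair.Av**2 + pair.Ah**2, params=pair.params)


def compute_retardation(pair: BScanPair) -> PhaseImage:
    """delta(z) = arctan(Av/Ah) in [0, pi/2], with a validity mask at 0/0 pixels.

    ``arctan2`` handles the axis cases exactly: Ah = 0, Av > 0 gives pi/2 and
    0/0 gives 0 (masked invalid).
    """
    if pair.Av.shape != pair.Ah.shape:
        raise ShapeMismatchError("channel shapes disagree")
    values = np.arctan2(pair.Av, pair.Ah)
    valid = ~((pair.Av == 0.0) & (pair.Ah == 0.0))
    return PhaseImage(values=values, valid=valid, params=pair.params)
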