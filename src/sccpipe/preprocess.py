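"""Intensity normalization and in-plane rigid registration.

Fluorescence intensities are put on a common scale by rescaling each stack
from its recorded laser power and photomultiplier gain to a reference pair
(laser and detector settings vary between sample batches but not within a
sample's pre/post pair).  The two excitation channels are then spatially
registered for rotation and translation using the z-sum projections of
their simultaneously acquired reflectance stacks; the resulting 2D rigid
transform is applied slice-wise to the 3D stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from .exceptions import DegenerateInputError, ValidationError
from .io import ImageStack

__all__ = [
    "NormalizationReference",
    "RigidTransform2D",
    "normalize_stack",
    "zsum_projection",
    "estimate_rigid_transform",
    "apply_transform",
]


@dataclass(frozen=True)
class NormalizationReference:
    """Reference (laser power, detector gain) the 'standard image' was taken at.

    Gain response is modeled as a power law with exponent ``gain_exponent``
    (1.0 = linear); the exponent is instrument-specific and exposed rather
    than guessed.
    """

    reference_laser_power: float = 1.0
    reference_detector_gain: float = 1.0
    gain_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.reference_laser_power <= 0 or self.reference_detector_gain <= 0:
            raise ValidationError("normalization reference values must be positive")


def normalize_stack(stack: ImageStack, ref: NormalizationReference) -> ImageStack:
    """Rescale intensities to the reference laser power and detector gain.

    out = in * (ref_power / power) * (ref_gain / gain) ** gain_exponent

    The returned stack carries the reference power/gain in its metadata, so
    normalizing twice is a no-op.
    """
    meta = stack.metadata
    if meta.laser_power <= 0 or meta.detector_gain <= 0:
        raise ValidationError("stack metadata must carry positive laser power and gain")
    scale = (ref.reference_laser_power / meta.laser_power) * (
        ref.reference_detector_gain / meta.detector_gain
    ) ** ref.gain_exponent
    out = stack.voxels.astype(np.float64) * scale
    return ImageStack(
        out,
        metadata=type(meta)(
            channel=meta.channel,
            modality=meta.modality,
            timepoint=meta.timepoint,
            laser_power=ref.reference_laser_power,
            detector_gain=ref.reference_detector_gain,
            lateral_pixel_um=meta.lateral_pixel_um,
            z_spacing_um=meta.z_spacing_um,
            batch_id=meta.batch_id,
        ),
    )


def zsum_projection(stack: ImageStack) -> np.ndarray:
    """Sum the stack along z; the (Y, X) projection used as registration substrate."""
    if stack.voxels.size == 0:
        raise DegenerateInputError("cannot project an empty stack")
    return stack.voxels.astype(np.float64).sum(axis=0)


@dataclass(frozen=True)
class RigidTransform2D:
    """In-plane rotation (about the image center) followed by translation.

    Forward mapping of an image point p = (y, x):
        F(p) = R(rotation_deg) @ (p - c) + c + t
    where c is the image center and t = (dy, dx) in voxels.
    """

    rotation_deg: float = 0.0
    dy: float = 0.0
    dx: float = 0.0

    @property
    def translation(self) -> tuple[float, float]:
        return (self.dy, self.dx)

    def _rot(self) -> np.ndarray:
        th = math.radians(self.rotation_deg)
        return np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])

    def inverse(self) -> "RigidTransform2D":
        rt = self._rot().T
        t_inv = -rt @ np.array([self.dy, self.dx])
        return RigidTransform2D(-self.rotation_deg, float(t_inv[0]), float(t_inv[1]))

    def compose(self, first: "RigidTransform2D") -> "RigidTransform2D":
        """Return self o first (apply ``first``, then ``self``)."""
        t = self._rot() @ np.array([first.dy, first.dx]) + np.array([self.dy, self.dx])
        return RigidTransform2D(
            self.rotation_deg + first.rotation_deg, float(t[0]), float(t[1])
        )

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            abs(self.rotation_deg) <= tol and abs(self.dy) <= tol and abs(self.dx) <= tol
        )

    def to_dict(self) -> dict:
        return {"rotation_deg": self.rotation_deg, "dy": self.dy, "dx": self.dx}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(d["rotation_deg"], d["dy"], d["dx"])


def _warp2d(image: np.ndarray, t: RigidTransform2D, order: int = 1) -> np.ndarray:
    """Resample one slice under the forward map F; out[q] = in[F^-1(q)]."""
    c = (np.array(image.shape, dtype=np.float64) - 1.0) / 2.0
    rt = t._rot().T
    offset = c - rt @ (c + np.array([t.dy, t.dx]))
    return ndimage.affine_transform(
        image, rt, offset=offset, order=order, mode="constant", cval=0.0
    )


def apply_transform(stack: ImageStack, t: RigidTransform2D) -> ImageStack:
    """Apply the 2D rigid transform to every z-slice (linear interpolation).

    Out-of-bounds voxels are filled with 0; no intensity crosses z-slices.
    """
    if t.is_identity():
        return stack.with_voxels(stack.voxels.astype(np.float64).copy())
    vox = stack.voxels.astype(np.float64)
    out = np.empty_like(vox)
    for z in range(vox.shape[0]):
        out[z] = _warp2d(vox[z], t)
    return stack.with_voxels(np.clip(out, 0.0, None))


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float((a * a).sum()) * float((b * b).sum()))
    if denom == 0:
        return 0.0
    return float((a * b).sum()) / denom


def estimate_rigid_transform(
    fixed: np.ndarray,
    moving: np.ndarray,
    max_rotation_deg: float = 6.0,
    coarse_step_deg: float = 0.5,
    fine_step_deg: float = 0.05,
    upsample_factor: int = 50,
) -> RigidTransform2D:
    """Estimate T so that ``apply_transform(moving, T)`` aligns with ``fixed``.

    Normalized cross-correlation over rotation + translation: a coarse grid
    over rotation with FFT-based translation search at each angle, then a
    local fine grid around the best rotation with subpixel translation.
    Images are Hann-windowed before the frequency-domain correlation and
    candidates are scored by NCC on a central crop, which suppresses the
    artificial edges the rotation's zero fill would otherwise introduce.
    Identical images return the identity transform.
    """
    fixed = np.asarray(fixed, dtype=np.float64)
    moving = np.asarray(moving, dtype=np.float64)
    if fixed.shape != moving.shape:
        raise ValidationError(f"shape mismatch: {fixed.shape} vs {moving.shape}")
    if fixed.std() == 0 or moving.std() == 0:
        raise DegenerateInputError("constant image cannot be registered")
    if np.array_equal(fixed, moving):
        return RigidTransform2D(0.0, 0.0, 0.0)

    window = np.hanning(fixed.shape[0])[:, None] * np.hanning(fixed.shape[1])[None, :]
    crop = max(2, min(fixed.shape) // 10)
    inner = (slice(crop, -crop), slice(crop, -crop))

    def score_rotation(theta: float, upsample: int):
        rot = _warp2d(moving, RigidTransform2D(theta, 0.0, 0.0))
        shift, _, _ = phase_cross_correlation(
            fixed * window, rot * window,
            upsample_factor=upsample, normalization="phase",
        )
        cand = _warp2d(rot, RigidTransform2D(0.0, float(shift[0]), float(shift[1])))
        return _ncc(fixed[inner], cand[inner]), (float(shift[0]), float(shift[1]))

    best = (-np.inf, 0.0, (0.0, 0.0))
    for theta in np.arange(-max_rotation_deg, max_rotation_deg + 1e-9, coarse_step_deg):
        s, shift = score_rotation(float(theta), upsample=1)
        if s > best[0]:
            best = (s, float(theta), shift)

    lo = best[1] - coarse_step_deg
    hi = best[1] + coarse_step_deg
    for theta in np.arange(lo, hi + 1e-9, fine_step_deg):
        s, shift = score_rotation(float(theta), upsample=upsample_factor)
        if s > best[0]:
            best = (s, float(theta), shift)

    _, theta, (dy, dx) = best
    return RigidTransform2D(theta, dy, dx)
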