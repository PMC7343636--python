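"""Synthetic bimodal confocal phantoms of the bioprinted cSCC skin construct.

Each phantom is a pair of timepoints (pre / post treatment), each with two
excitation channels (488 nm -> ZsGreen keratinocytes, 532 nm -> tdTomato
cSCC), each channel a simultaneously acquired reflectance + fluorescence
stack -- four stacks per timepoint, with full ground truth.

The scene contains:

* tumor spheroids rendered as shells of individual cSCC cell blobs around a
  dark (necrotic) core -- a proliferating rim around a non-fluorescent center;
* a sparse population of GFP-labeled keratinocytes (1% spike-in by default)
  in the epidermal band;
* a stratified reflectance texture: bright superficial band, honeycomb
  mid-band (dark nuclei), fibrous dermis;
* per-channel/timepoint laser-power and detector-gain scale factors, a rigid
  in-plane misregistration of the 532 nm channel, optional inter-channel
  bleed-through, and Poisson-Gaussian sensor noise applied last.

Cells are isotropic Gaussian blobs in physical units and therefore
anisotropic in voxels (z spacing exceeds the lateral pitch).  Treatment
removes a configured fraction of cells entirely between the pre and post
acquisitions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ManifestError, PlacementError, ValidationError
from .io import (
    MANIFEST_COLUMNS,
    AcquisitionMetadata,
    BimodalAcquisition,
    Channel,
    Group,
    ImageStack,
    Modality,
    Timepoint,
    TumorROI,
    write_stack,
)
from .preprocess import RigidTransform2D, apply_transform

__all__ = [
    "NoiseModel",
    "PhantomConfig",
    "PhantomGroundTruth",
    "generate_phantom",
    "write_phantom_sample",
    "write_manifest",
    "simulate_dataset",
    "simulate_effect_table",
    "GROUP_KILL_FRACTIONS",
]


@dataclass(frozen=True)
class NoiseModel:
    """Photon-limited detector model: Poisson shot noise + Gaussian read noise.

    ``photon_scale`` converts intensity units to expected photon counts;
    ``read_noise_sd`` is the additive detector noise SD in intensity units.
    """

    photon_scale: float = 1.0
    read_noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.photon_scale <= 0 or self.read_noise_sd < 0:
            raise ValidationError("photon_scale must be > 0 and read_noise_sd >= 0")


def _default_factors() -> dict:
    return {}


@dataclass(frozen=True)
class PhantomConfig:
    """Generating parameters for one phantom construct.

    Identical seed + config produce bit-identical phantoms.  Intensity units
    are arbitrary "photon-equivalent" counts; geometric parameters are in
    micrometres and converted internally to the anisotropic voxel grid.
    """

    volume_shape: tuple = (24, 256, 256)
    lateral_pixel_um: float = 1.1
    z_spacing_um: float = 3.1

    n_spheroids: int = 5
    spheroid_radius_um: float = 28.0
    necrotic_core_fraction: float = 0.45
    cells_per_spheroid: int = 12

    n_keratinocytes: int = 3000
    gfp_labeled_fraction: float = 0.01

    cell_radius_um: float = 3.0
    min_lateral_separation_um: float = 12.0
    min_axial_separation_um: float = 28.0

    kill_fraction_tumor: float = 0.0
    kill_fraction_keratinocyte: float = 0.0

    # (Channel, Timepoint) -> factor; unlisted pairs default to 1.0
    laser_power_factors: dict = field(default_factory=_default_factors)
    detector_gain_factors: dict = field(default_factory=_default_factors)

    misregistration: RigidTransform2D | None = None
    noise: NoiseModel | None = NoiseModel()
    bleed_through_coefficient: float = 0.0

    cell_peak_intensity: float = 200.0
    reflectance_intensity: float = 150.0
    batch_id: str = "batch0"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "necrotic_core_fraction",
            "gfp_labeled_fraction",
            "kill_fraction_tumor",
            "kill_fraction_keratinocyte",
            "bleed_through_coefficient",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if len(self.volume_shape) != 3 or min(self.volume_shape) < 16:
            raise ValidationError("volume_shape must be 3 axes of >= 16 voxels each")
        if min(self.n_spheroids, self.cells_per_spheroid, self.n_keratinocytes) < 0:
            raise ValidationError("counts must be non-negative")
        if self.spheroid_radius_um <= 0 or self.cell_radius_um <= 0:
            raise ValidationError("radii must be positive")

    def power_factor(self, channel: Channel, timepoint: Timepoint) -> float:
        return float(self.laser_power_factors.get((channel, timepoint), 1.0))

    def gain_factor(self, channel: Channel, timepoint: Timepoint) -> float:
        return float(self.detector_gain_factors.get((channel, timepoint), 1.0))

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        return (self.z_spacing_um, self.lateral_pixel_um, self.lateral_pixel_um)


@dataclass
class PhantomGroundTruth:
    """Generating truth of one phantom: the oracle for downstream tests.

    Centers are integer voxel coordinates (z, y, x).  ``true_transform`` is
    the rigid transform injected into the 532 nm channel's stacks; its
    inverse registers that channel back onto the 488 nm channel.
    """

    tumor_cell_centers_pre: list  # per spheroid: (n, 3) int arrays
    tumor_cell_centers_post: list
    keratinocyte_centers_pre: np.ndarray
    keratinocyte_labeled_pre: np.ndarray
    keratinocyte_centers_post: np.ndarray
    keratinocyte_labeled_post: np.ndarray
    spheroid_centers_vox: np.ndarray  # (n, 3) float
    true_transform: RigidTransform2D
    true_scale_factors: dict  # "channel/timepoint" -> {"laser_power": f, "detector_gain": f}
    true_kill_fractions: dict  # {"tumor": k, "keratinocyte": k}
    config: PhantomConfig

    def tumor_centers(self, timepoint: Timepoint) -> np.ndarray:
        per = (
            self.tumor_cell_centers_pre
            if timepoint == Timepoint.pre
            else self.tumor_cell_centers_post
        )
        if not per:
            return np.zeros((0, 3), dtype=int)
        return np.concatenate([np.asarray(c).reshape(-1, 3) for c in per], axis=0)

    def labeled_keratinocyte_centers(self, timepoint: Timepoint) -> np.ndarray:
        if timepoint == Timepoint.pre:
            return self.keratinocyte_centers_pre[self.keratinocyte_labeled_pre]
        return self.keratinocyte_centers_post[self.keratinocyte_labeled_post]

    def tumor_rois(self) -> list:
        """Axis-aligned boxes around each spheroid (disjoint by construction)."""
        cfg = self.config
        margin = 2.0 * cfg.cell_radius_um
        half_lat = (cfg.spheroid_radius_um + margin) / cfg.lateral_pixel_um
        half_z = (cfg.spheroid_radius_um + margin) / cfg.z_spacing_um
        Z, Y, X = cfg.volume_shape
        rois = []
        for i, c in enumerate(self.spheroid_centers_vox):
            rois.append(
                TumorROI(
                    roi_id=f"tumor{i:02d}",
                    z0=max(0, int(np.floor(c[0] - half_z))),
                    z1=min(Z, int(np.ceil(c[0] + half_z)) + 1),
                    y0=max(0, int(np.floor(c[1] - half_lat))),
                    y1=min(Y, int(np.ceil(c[1] + half_lat)) + 1),
                    x0=max(0, int(np.floor(c[2] - half_lat))),
                    x1=min(X, int(np.ceil(c[2] + half_lat)) + 1),
                )
            )
        return rois

    def to_json(self, path) -> None:
        payload = {
            "tumor_cell_centers_pre": [np.asarray(c).tolist() for c in self.tumor_cell_centers_pre],
            "tumor_cell_centers_post": [np.asarray(c).tolist() for c in self.tumor_cell_centers_post],
            "keratinocyte_centers_pre": self.keratinocyte_centers_pre.tolist(),
            "keratinocyte_labeled_pre": self.keratinocyte_labeled_pre.tolist(),
            "keratinocyte_centers_post": self.keratinocyte_centers_post.tolist(),
            "keratinocyte_labeled_post": self.keratinocyte_labeled_post.tolist(),
            "spheroid_centers_vox": self.spheroid_centers_vox.tolist(),
            "true_transform": self.true_transform.to_dict(),
            "true_scale_factors": self.true_scale_factors,
            "true_kill_fractions": self.true_kill_fractions,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# --------------------------------------------------------------------------
# Placement
# --------------------------------------------------------------------------

def _place_spheroid_centers(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    Z, Y, X = cfg.volume_shape
    margin_um = 2.0 * cfg.cell_radius_um
    half_um = cfg.spheroid_radius_um + margin_um
    w = half_um / cfg.lateral_pixel_um  # lateral half-extent in voxels
    if 2.0 * cfg.spheroid_radius_um > Z * cfg.z_spacing_um:
        raise PlacementError(
            f"spheroid diameter {2 * cfg.spheroid_radius_um:.1f} um exceeds the axial "
            f"extent {Z * cfg.z_spacing_um:.1f} um of the volume"
        )
    lo, hi = w, min(Y, X) - 1 - w
    if hi <= lo:
        raise PlacementError(
            f"lateral extent {min(Y, X)} px cannot hold a spheroid of half-extent {w:.1f} px"
        )
    zc = (Z - 1) / 2.0
    # ROI boxes floor/ceil the continuous bounds and add one voxel at the top
    # (half-open upper edge), so disjointness needs 3 voxels of slack beyond
    # the continuous half-extents.
    min_cheb = 2.0 * w + 3.0
    for _ in range(60):  # restarts
        centers: list = []
        ok = True
        for _ in range(cfg.n_spheroids):
            placed = False
            for _ in range(1000):
                y = rng.uniform(w, Y - 1 - w)
                x = rng.uniform(w, X - 1 - w)
                if all(max(abs(y - cy), abs(x - cx)) >= min_cheb for _, cy, cx in centers):
                    centers.append((zc, y, x))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(centers, dtype=np.float64).reshape(-1, 3)
    raise PlacementError(
        f"could not place {cfg.n_spheroids} non-overlapping spheroids of half-extent "
        f"{w:.1f} px in a {Y}x{X} px field"
    )


def _separation_ok(cand_um: np.ndarray, accepted_um: np.ndarray, cfg: PhantomConfig) -> bool:
    """Anisotropic resolvability metric: an ellipsoidal exclusion zone per cell."""
    if accepted_um.shape[0] == 0:
        return True
    d = accepted_um - cand_um
    n = (d[:, 0] / cfg.min_axial_separation_um) ** 2 + (
        d[:, 1] ** 2 + d[:, 2] ** 2
    ) / cfg.min_lateral_separation_um**2
    return bool(np.all(n >= 1.0))


def _place_tumor_cells(
    cfg: PhantomConfig, rng: np.random.Generator, spheroid_centers: np.ndarray
) -> list:
    vz, vy, vx = cfg.voxel_size_um
    Z, Y, X = cfg.volume_shape
    core = cfg.necrotic_core_fraction * cfg.spheroid_radius_um
    R = cfg.spheroid_radius_um
    per_spheroid = []
    accepted_um = np.zeros((0, 3))
    for c in spheroid_centers:
        c_um = c * np.array([vz, vy, vx])
        cells = []
        for _ in range(cfg.cells_per_spheroid):
            placed = False
            for _ in range(600):
                direction = rng.normal(size=3)
                norm = np.linalg.norm(direction)
                if norm == 0:
                    continue
                direction /= norm
                r = (rng.uniform(core**3, R**3)) ** (1.0 / 3.0)
                p_um = c_um + r * direction
                vox = np.rint(p_um / np.array([vz, vy, vx])).astype(int)
                if not (1 <= vox[0] < Z - 1 and 2 <= vox[1] < Y - 2 and 2 <= vox[2] < X - 2):
                    continue
                vox_um = vox * np.array([vz, vy, vx])
                if _separation_ok(vox_um, accepted_um, cfg):
                    cells.append(vox)
                    accepted_um = np.vstack([accepted_um, vox_um])
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"cannot fit {cfg.cells_per_spheroid} resolvable cells "
                    f"(min separation {cfg.min_lateral_separation_um} um lateral / "
                    f"{cfg.min_axial_separation_um} um axial) in a spheroid shell of "
                    f"radii [{core:.1f}, {R:.1f}] um"
                )
        per_spheroid.append(np.array(cells, dtype=int).reshape(-1, 3))
    return per_spheroid


def _epidermal_band(cfg: PhantomConfig) -> tuple[int, int]:
    """Slice range [z0, z1) of the keratinocyte (honeycomb) band."""
    z_sup = max(1, int(round(6.0 / cfg.z_spacing_um)))
    z_low = max(z_sup + 2, int(round(45.0 / cfg.z_spacing_um)))
    z_low = min(z_low, cfg.volume_shape[0] - 2)
    return z_sup, z_low


def _place_keratinocytes(
    cfg: PhantomConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    Z, Y, X = cfg.volume_shape
    vz, vy, vx = cfg.voxel_size_um
    z0, z1 = _epidermal_band(cfg)
    n_labeled = int(round(cfg.gfp_labeled_fraction * cfg.n_keratinocytes))
    labeled = []
    accepted_um = np.zeros((0, 3))
    for _ in range(n_labeled):
        placed = False
        for _ in range(600):
            vox = np.array(
                [rng.integers(z0, z1), rng.integers(2, Y - 2), rng.integers(2, X - 2)]
            )
            vox_um = vox * np.array([vz, vy, vx])
            if _separation_ok(vox_um, accepted_um, cfg):
                labeled.append(vox)
                accepted_um = np.vstack([accepted_um, vox_um])
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"cannot place {n_labeled} resolvable labeled keratinocytes in the "
                f"epidermal band (slices {z0}..{z1})"
            )
    n_unlabeled = cfg.n_keratinocytes - n_labeled
    unlabeled = np.column_stack(
        [
            rng.integers(z0, z1, size=n_unlabeled),
            rng.integers(2, Y - 2, size=n_unlabeled),
            rng.integers(2, X - 2, size=n_unlabeled),
        ]
    )
    centers = np.vstack([np.array(labeled, dtype=int).reshape(-1, 3), unlabeled])
    flags = np.zeros(len(centers), dtype=bool)
    flags[:n_labeled] = True
    return centers, flags


def _apply_kill(
    centers: np.ndarray, kill_fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Keep round((1 - kill) * n) cells, sampled uniformly without replacement."""
    n = len(centers)
    n_keep = int(round((1.0 - kill_fraction) * n))
    keep = np.sort(rng.choice(n, size=n_keep, replace=False)) if n else np.array([], int)
    return keep


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _render_blobs(cfg: PhantomConfig, centers: np.ndarray) -> np.ndarray:
    """Sum of isotropic (in um) Gaussian cell blobs at integer voxel centers."""
    Z, Y, X = cfg.volume_shape
    out = np.zeros((Z, Y, X), dtype=np.float64)
    if len(centers) == 0:
        return out
    sigma_um = cfg.cell_radius_um / 2.0
    sz = sigma_um / cfg.z_spacing_um
    sl = sigma_um / cfg.lateral_pixel_um
    rz, rl = int(np.ceil(4 * sz)), int(np.ceil(4 * sl))
    dz = np.arange(-rz, rz + 1)[:, None, None]
    dy = np.arange(-rl, rl + 1)[None, :, None]
    dx = np.arange(-rl, rl + 1)[None, None, :]
    kernel = cfg.cell_peak_intensity * np.exp(
        -0.5 * ((dz / sz) ** 2 + (dy / sl) ** 2 + (dx / sl) ** 2)
    )
    for cz, cy, cx in centers:
        z0, z1 = max(0, cz - rz), min(Z, cz + rz + 1)
        y0, y1 = max(0, cy - rl), min(Y, cy + rl + 1)
        x0, x1 = max(0, cx - rl), min(X, cx + rl + 1)
        out[z0:z1, y0:y1, x0:x1] += kernel[
            z0 - (cz - rz): z1 - (cz - rz),
            y0 - (cy - rl): y1 - (cy - rl),
            x0 - (cx - rl): x1 - (cx - rl),
        ]
    return out


def _render_reflectance(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Stratified-skin reflectance: bright superficial band, honeycomb, fibrous dermis."""
    Z, Y, X = cfg.volume_shape
    amp = cfg.reflectance_intensity
    z_sup, z_low = _epidermal_band(cfg)
    out = np.zeros((Z, Y, X), dtype=np.float64)

    # superficial band: bright, mildly speckled
    speckle = ndimage.gaussian_filter(rng.uniform(0.0, 1.0, size=(Y, X)), sigma=1.5)
    speckle = (speckle - speckle.min()) / max(float(np.ptp(speckle)), 1e-12)
    sup = 1.4 * amp * (0.75 + 0.5 * speckle)
    out[:z_sup] = sup[None]

    # honeycomb mid-band: bright walls around dark nuclei
    n_pts = max(8, int(Y * X / 140))
    nuclei = np.zeros((Y, X))
    pts_y = rng.uniform(0, Y - 1, size=n_pts)
    pts_x = rng.uniform(0, X - 1, size=n_pts)
    sn = 3.0
    r = int(np.ceil(3.5 * sn))
    win = np.arange(-r, r + 1)
    gy = np.exp(-0.5 * (win / sn) ** 2)
    for py, px in zip(pts_y, pts_x):
        iy, ix = int(round(py)), int(round(px))
        y0, y1 = max(0, iy - r), min(Y, iy + r + 1)
        x0, x1 = max(0, ix - r), min(X, ix + r + 1)
        nuclei[y0:y1, x0:x1] += np.outer(
            gy[y0 - (iy - r): y1 - (iy - r)], gy[x0 - (ix - r): x1 - (ix - r)]
        )
    nuclei = np.clip(nuclei / max(nuclei.max(), 1e-12), 0.0, 1.0)
    honey = amp * (1.0 - 0.8 * nuclei)
    ramp = np.linspace(1.05, 0.95, z_low - z_sup)
    out[z_sup:z_low] = honey[None] * ramp[:, None, None]

    # dermis: fibrous texture, horizontally elongated
    fib = ndimage.gaussian_filter(rng.normal(size=(Y, X)), sigma=(1.2, 6.0))
    fib = (fib - fib.mean()) / max(fib.std(), 1e-12)
    dermis = np.clip(0.55 * amp * (1.0 + 0.35 * fib), 0.0, None)
    out[z_low:] = dermis[None]
    return out


def _apply_noise(arr: np.ndarray, noise: NoiseModel | None, rng: np.random.Generator):
    if noise is None:
        return arr
    ps = noise.photon_scale
    photons = rng.poisson(np.clip(arr, 0.0, None) * ps).astype(np.float64) / ps
    if noise.read_noise_sd > 0:
        photons = photons + rng.normal(0.0, noise.read_noise_sd, size=arr.shape)
    return np.clip(photons, 0.0, None)


# --------------------------------------------------------------------------
# Phantom assembly
# --------------------------------------------------------------------------

def generate_phantom(config: PhantomConfig):
    """Generate one phantom: (pre, post, truth).

    ``pre`` and ``post`` map Channel -> BimodalAcquisition (four stacks per
    timepoint).  All randomness derives from ``config.rng_seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.rng_seed)

    spheroid_centers = (
        _place_spheroid_centers(cfg, rng)
        if cfg.n_spheroids > 0
        else np.zeros((0, 3))
    )
    tumor_per_spheroid = (
        _place_tumor_cells(cfg, rng, spheroid_centers)
        if cfg.n_spheroids > 0 and cfg.cells_per_spheroid > 0
        else [np.zeros((0, 3), int) for _ in range(cfg.n_spheroids)]
    )
    tumor_all = (
        np.concatenate([c for c in tumor_per_spheroid], axis=0)
        if tumor_per_spheroid
        else np.zeros((0, 3), int)
    )
    ker_centers, ker_labeled = _place_keratinocytes(cfg, rng)

    # treatment: remove cells uniformly without replacement, per population
    tumor_keep = _apply_kill(tumor_all, cfg.kill_fraction_tumor, rng)
    lab_idx = np.flatnonzero(ker_labeled)
    unlab_idx = np.flatnonzero(~ker_labeled)
    lab_keep = lab_idx[_apply_kill(lab_idx, cfg.kill_fraction_keratinocyte, rng)]
    unlab_keep = unlab_idx[_apply_kill(unlab_idx, cfg.kill_fraction_keratinocyte, rng)]
    ker_keep = np.sort(np.concatenate([lab_keep, unlab_keep]))

    tumor_post_mask = np.zeros(len(tumor_all), dtype=bool)
    tumor_post_mask[tumor_keep] = True
    tumor_per_spheroid_post = []
    offset = 0
    for cells in tumor_per_spheroid:
        m = tumor_post_mask[offset: offset + len(cells)]
        tumor_per_spheroid_post.append(cells[m])
        offset += len(cells)

    ker_centers_post = ker_centers[ker_keep]
    ker_labeled_post = ker_labeled[ker_keep]

    reflectance_scene = _render_reflectance(cfg, rng)
    inj = cfg.misregistration or RigidTransform2D()

    if tumor_per_spheroid_post:
        tumor_all_post = np.concatenate(tumor_per_spheroid_post, axis=0)
    else:
        tumor_all_post = np.zeros((0, 3), int)
    scale_factors = {}
    acquisitions = {Timepoint.pre: {}, Timepoint.post: {}}
    scenes = {
        Timepoint.pre: (
            _render_blobs(cfg, ker_centers[ker_labeled]),
            _render_blobs(cfg, tumor_all),
        ),
        Timepoint.post: (
            _render_blobs(cfg, ker_centers_post[ker_labeled_post]),
            _render_blobs(cfg, tumor_all_post),
        ),
    }

    for tp in (Timepoint.pre, Timepoint.post):
        gfp_scene, rfp_scene = scenes[tp]
        c = cfg.bleed_through_coefficient
        fl = {
            Channel.GFP_488: gfp_scene + c * rfp_scene,
            Channel.RFP_532: rfp_scene + c * gfp_scene,
        }
        for ch in (Channel.GFP_488, Channel.RFP_532):
            refl = reflectance_scene
            fluo = fl[ch]
            if ch == Channel.RFP_532 and not inj.is_identity():
                meta_tmp = AcquisitionMetadata(
                    channel=ch, modality=Modality.reflectance, timepoint=tp,
                    lateral_pixel_um=cfg.lateral_pixel_um, z_spacing_um=cfg.z_spacing_um,
                )
                refl = apply_transform(ImageStack(refl, meta_tmp), inj).voxels
                fluo = apply_transform(ImageStack(fluo, meta_tmp), inj).voxels
            fp = cfg.power_factor(ch, tp)
            fg = cfg.gain_factor(ch, tp)
            scale_factors[f"{ch.value}/{tp.value}"] = {
                "laser_power": fp,
                "detector_gain": fg,
            }
            scale = fp * fg
            stacks = {}
            for modality, arr in (
                (Modality.reflectance, refl),
                (Modality.fluorescence, fluo),
            ):
                noisy = _apply_noise(arr * scale, cfg.noise, rng)
                meta = AcquisitionMetadata(
                    channel=ch,
                    modality=modality,
                    timepoint=tp,
                    laser_power=fp,
                    detector_gain=fg,
                    lateral_pixel_um=cfg.lateral_pixel_um,
                    z_spacing_um=cfg.z_spacing_um,
                    batch_id=cfg.batch_id,
                )
                stacks[modality] = ImageStack(noisy, meta)
            acquisitions[tp][ch] = BimodalAcquisition(
                reflectance=stacks[Modality.reflectance],
                fluorescence=stacks[Modality.fluorescence],
            )

    truth = PhantomGroundTruth(
        tumor_cell_centers_pre=tumor_per_spheroid,
        tumor_cell_centers_post=tumor_per_spheroid_post,
        keratinocyte_centers_pre=ker_centers,
        keratinocyte_labeled_pre=ker_labeled,
        keratinocyte_centers_post=ker_centers_post,
        keratinocyte_labeled_post=ker_labeled_post,
        spheroid_centers_vox=spheroid_centers,
        true_transform=inj,
        true_scale_factors=scale_factors,
        true_kill_fractions={
            "tumor": cfg.kill_fraction_tumor,
            "keratinocyte": cfg.kill_fraction_keratinocyte,
        },
        config=cfg,
    )
    return acquisitions[Timepoint.pre], acquisitions[Timepoint.post], truth


# --------------------------------------------------------------------------
# Dataset writing
# --------------------------------------------------------------------------

def write_phantom_sample(outdir, sample_id: str, group: Group, config: PhantomConfig):
    """Generate one phantom and write its 8 stacks, ROIs, truth, manifest rows."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pre, post, truth = generate_phantom(config)
    rois = truth.tumor_rois()
    rois_path = outdir / f"{sample_id}_rois.json"
    with open(rois_path, "w") as fh:
        json.dump([r.to_dict() for r in rois], fh)
    truth.to_json(outdir / f"{sample_id}_truth.json")

    rows = []
    for tp, acqs in ((Timepoint.pre, pre), (Timepoint.post, post)):
        for ch, acq in acqs.items():
            names = {}
            for modality, stack in (
                (Modality.reflectance, acq.reflectance),
                (Modality.fluorescence, acq.fluorescence),
            ):
                name = f"{sample_id}_{tp.value}_{ch.value}_{modality.value}.tif"
                write_stack(outdir / name, stack)
                names[modality] = name
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group.value,
                    "timepoint": tp.value,
                    "channel": ch.value,
                    "reflectance_path": names[Modality.reflectance],
                    "fluorescence_path": names[Modality.fluorescence],
                    "laser_power": config.power_factor(ch, tp),
                    "detector_gain": config.gain_factor(ch, tp),
                    "lateral_pixel_um": config.lateral_pixel_um,
                    "z_spacing_um": config.z_spacing_um,
                    "batch_id": config.batch_id,
                    "rois_path": rois_path.name,
                }
            )
    return rows, truth


def write_manifest(rows, path) -> Path:
    """Write manifest rows (list of dicts or DataFrame) to CSV, with validation.

    An empty row list produces a valid empty manifest.  Round-trips
    losslessly through :func:`sccpipe.io.read_manifest_table`.
    """
    path = Path(path)
    table = pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS)
    if len(table):
        bad = sorted(set(table["group"]) - {g.value for g in Group})
        if bad:
            raise ManifestError(f"unknown group labels: {bad}")
        if table.duplicated(subset=["sample_id", "timepoint", "channel"]).any():
            raise ManifestError("duplicate sample identifiers in manifest")
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


#: Study-arm kill fractions (tumor, keratinocyte) the phantoms emulate:
#: untreated controls lose ~12% of tumor cells (baseline), 1 uM 5FU kills
#: ~50% of tumor cells and ~11% of keratinocytes, and the 2 uM arm shows an
#: increased effect.
GROUP_KILL_FRACTIONS = {
    Group.control: (0.12, 0.0),
    Group.treated_1x: (0.50, 0.11),
    Group.treated_2x: (0.70, 0.15),
}


def simulate_dataset(
    outdir,
    n_control: int = 15,
    n_treated_1x: int = 18,
    n_treated_2x: int = 20,
    base_config: PhantomConfig | None = None,
    seed: int = 0,
    group_kill_fractions: dict | None = None,
    vary_settings: bool = True,
) -> Path:
    """Write a full phantom study (images + ROIs + truth + manifest).

    Group sizes default to the dose-response design (15 control / 18 at 1x /
    20 at 2x).  When ``vary_settings`` is true, each sample gets its own
    laser/gain factors (consistent between its pre and post acquisitions but
    varying between batches of 3 samples) and a small random inter-channel
    misregistration.
    """
    outdir = Path(outdir)
    base = base_config or PhantomConfig()
    kills = group_kill_fractions or GROUP_KILL_FRACTIONS
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group, n in (
        (Group.control, n_control),
        (Group.treated_1x, n_treated_1x),
        (Group.treated_2x, n_treated_2x),
    ):
        kt, kk = kills[group]
        for _ in range(n):
            sample_id = f"S{i:03d}"
            batch_id = f"batch{i // 3}"
            factors_p, factors_g, misreg = {}, {}, None
            if vary_settings:
                for ch in (Channel.GFP_488, Channel.RFP_532):
                    fp = float(rng.uniform(0.7, 1.3))
                    fg = float(rng.uniform(0.8, 1.25))
                    for tp in (Timepoint.pre, Timepoint.post):
                        factors_p[(ch, tp)] = fp  # consistent pre/post per sample
                        factors_g[(ch, tp)] = fg
                misreg = RigidTransform2D(
                    rotation_deg=float(rng.uniform(-2.0, 2.0)),
                    dy=float(rng.uniform(-4.0, 4.0)),
                    dx=float(rng.uniform(-4.0, 4.0)),
                )
            cfg = replace(
                base,
                kill_fraction_tumor=kt,
                kill_fraction_keratinocyte=kk,
                laser_power_factors=factors_p,
                detector_gain_factors=factors_g,
                misregistration=misreg,
                batch_id=batch_id,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            rows.extend(write_phantom_sample(outdir, sample_id, group, cfg)[0])
            i += 1
    return write_manifest(rows, outdir / "manifest.csv")


# --------------------------------------------------------------------------
# Design-level study simulation (for power analyses)
# --------------------------------------------------------------------------

def simulate_effect_table(
    rng: np.random.Generator,
    n_per_arm: int = 20,
    kill_tumor_treated: float = 0.5,
    kill_ker_treated: float = 0.0,
    kill_tumor_control: float = 0.0,
    kill_ker_control: float = 0.0,
    n_tumor_cells: int = 125,
    n_keratinocytes: int = 30,
    measurement_cv: float = 0.05,
) -> pd.DataFrame:
    """Simulate per-sample percent-of-pre values at the study-design level.

    Each sample's surviving-cell count is drawn binomially from its
    population size (cell survival is independent per cell), then perturbed
    by multiplicative measurement noise emulating segmentation variability.
    Returns a tidy table with columns value / cell_type / treatment suitable
    for the factorial ANOVA.
    """
    rows = []
    for treatment, kt, kk in (
        ("untreated", kill_tumor_control, kill_ker_control),
        ("treated", kill_tumor_treated, kill_ker_treated),
    ):
        for cell_type, kill, n_cells in (
            ("cSCC", kt, n_tumor_cells),
            ("keratinocyte", kk, n_keratinocytes),
        ):
            survivors = rng.binomial(n_cells, 1.0 - kill, size=n_per_arm)
            pct = 100.0 * survivors / n_cells
            pct = pct * (1.0 + rng.normal(0.0, measurement_cv, size=n_per_arm))
            for v in pct:
                rows.append(
                    {"value": float(v), "cell_type": cell_type, "treatment": treatment}
                )
    return pd.DataFrame(rows)
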