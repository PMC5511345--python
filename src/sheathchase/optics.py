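"""Render ground-truth sheath states into fluorescence image stacks.

Each ring is an isotropic 2D Gaussian point emitter of integrated intensity
``photons_per_ring * brightness``; the cytosol contributes a uniform photon
rate inside the cell mask, scaled by the current soluble-pool brightness.
Shot noise is Poisson on the photon field, followed by additive Gaussian
read noise and a constant camera offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import CellGeometry
from .simulate import Phase, SimulationResult


@dataclass
class OpticsConfig:
    pixel_size_nm: float = 65.0
    psf_sigma_nm: float = 110.0  # ~diffraction limit for GFP at NA 1.4
    photons_per_ring: float = 60.0
    cytosol_background: float = 20.0  # photons/px at pool brightness 1
    read_noise_sd: float = 2.0
    camera_offset: float = 100.0
    shot_noise: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.psf_sigma_nm < 0 or self.read_noise_sd < 0 or \
                self.cytosol_background < 0 or self.photons_per_ring < 0:
            raise ValueError("optics parameters must be nonnegative")


@dataclass
class ImageStack:
    """Time-lapse frames with acquisition metadata.

    ``origin_um`` maps pixel (row, col) = (0, 0) to world coordinates: a
    point at world (x, y) um sits at column (x - x0)/px, row (y - y0)/px.
    """

    frames: np.ndarray  # (T, H, W), nonnegative
    frame_interval_s: float
    pixel_size_nm: float
    t0_s: float = 0.0
    origin_um: tuple[float, float] = (0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) * self.frame_interval_s

    def world_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """(..., 2) world um -> (..., 2) fractional (col, row) pixel coords."""
        xy = np.asarray(xy_um, dtype=float)
        px = self.pixel_size_nm / 1000.0
        return (xy - np.asarray(self.origin_um)) / px


def _splat(field_img: np.ndarray, cols: np.ndarray, rows: np.ndarray,
           weights: np.ndarray) -> None:
    """Bilinear deposition of point masses onto an image, in place."""
    h, w = field_img.shape
    c0 = np.floor(cols).astype(int)
    r0 = np.floor(rows).astype(int)
    fc = cols - c0
    fr = rows - r0
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(field_img, (rr[ok], cc[ok]), weights[ok] * wgt[ok])


def render_stack(
    sim: SimulationResult,
    optics: OpticsConfig,
    margin_um: float = 0.5,
    dtype=np.float32,
) -> ImageStack:
    """Render every recorded simulation frame into an image stack.

    Deterministic given ``optics.seed``. With ``shot_noise=False`` and zero
    read noise the output is the noiseless photon field plus the camera
    offset.
    """
    if not sim.frames:
        raise ValueError("simulation carries no recorded frames to render")
    geom: CellGeometry = sim.config.geometry
    xmin, ymin, xmax, ymax = geom.bounds_um()
    x0, y0 = xmin - margin_um, ymin - margin_um
    px = optics.pixel_size_nm / 1000.0
    w = int(np.ceil((xmax - xmin + 2 * margin_um) / px))
    h = int(np.ceil((ymax - ymin + 2 * margin_um) / px))
    mask = geom.mask((h, w), optics.pixel_size_nm, (x0, y0))
    sigma_px = optics.psf_sigma_nm / optics.pixel_size_nm
    rng = np.random.default_rng(optics.seed)
    frames = np.empty((len(sim.frames), h, w), dtype=dtype)
    for k, fr in enumerate(sim.frames):
        photons = np.zeros((h, w), dtype=float)
        photons[mask] = optics.cytosol_background * fr.pool.soluble_brightness
        for s in fr.sheaths:
            if s.n_rings == 0 or s.phase is Phase.GONE:
                continue
            xy = s.ring_xy_um()
            cols = (xy[:, 0] - x0) / px - 0.5
            rows = (xy[:, 1] - y0) / px - 0.5
            _splat(photons, cols, rows,
                   optics.photons_per_ring * s.ring_brightness)
        if sigma_px > 0:
            photons = gaussian_filter(photons, sigma_px, truncate=6.0)
        if optics.shot_noise:
            img = rng.poisson(np.clip(photons, 0, None)).astype(float)
        else:
            img = photons
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
        frames[k] = np.clip(img + optics.camera_offset, 0, None)
    return ImageStack(
        frames=frames,
        frame_interval_s=sim.config.frame_interval_s,
        pixel_size_nm=optics.pixel_size_nm,
        t0_s=float(sim.times_s[0]),
        origin_um=(x0, y0),
        meta={},
    )
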