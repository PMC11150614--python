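"""Seeded fundus-like phantoms with exact vessel ground truth.

A phantom is a disc-shaped field of view on a dark background containing
a branching curvilinear vessel tree darker than the surrounding tissue,
a smooth illumination gradient and sensor noise.  The vessel tree is
grown as a random recursive walk with geometrically decaying widths;
the ground-truth mask is the exact rasterisation of the generated
centerlines, so every downstream module can be tested without external
data.  Everything is a pure function of the spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_io import ImageRecord

__all__ = ["PhantomSpec", "generate_phantom", "generate_followup", "make_phantom_set"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic fundus phantom."""

    height: int = 256
    width: int = 256
    fov_radius_frac: float = 0.47
    n_roots: int = 4
    branch_prob: float = 0.04
    width_root: float = 3.5
    width_decay: float = 0.82
    tortuosity: float = 7.0        # angle jitter sd per step, degrees
    vessel_contrast: float = 0.45
    illumination_gradient: float = 0.08
    noise_sd: float = 0.04
    seed: int = 0

    def __post_init__(self):
        positive = ("height", "width", "fov_radius_frac", "n_roots",
                    "width_decay", "vessel_contrast")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.width_root < 1.0:
            raise ValueError("width_root must be at least 1 pixel")
        if not (0.0 < self.vessel_contrast <= 1.0):
            raise ValueError("vessel_contrast must lie in (0, 1]")
        for name in ("branch_prob", "tortuosity", "illumination_gradient", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# ----------------------------------------------------------------------
# vessel tree growth
# ----------------------------------------------------------------------

_STEP = 2.0          # centerline step length, px
_MIN_WIDTH = 1.2     # walks stop once thinner than this


def _grow_tree(spec: PhantomSpec) -> list:
    """Grow the branching centerline tree.

    Returns a list of ``(y, x, width)`` sample points along all
    branches.  Purely a function of the spec's seed, independent of any
    rasterisation parameters, so a follow-up phantom can reuse the
    identical topology with rescaled widths.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cy, cx = h / 2.0, w / 2.0
    fov_r = spec.fov_radius_frac * min(h, w)
    # vessels radiate from a disc-like origin offset from the FOV centre
    origin_angle = rng.uniform(0, 2 * np.pi)
    oy = cy + 0.45 * fov_r * np.sin(origin_angle)
    ox = cx + 0.45 * fov_r * np.cos(origin_angle)

    points: list = []
    jitter_sd = np.deg2rad(spec.tortuosity)
    max_steps = int(2.0 * fov_r / _STEP)

    stack = []
    for i in range(spec.n_roots):
        heading = rng.uniform(0, 2 * np.pi)
        stack.append((oy, ox, heading, float(spec.width_root), 0))

    while stack:
        y, x, heading, width, depth = stack.pop()
        for _ in range(max_steps):
            heading += rng.normal(0.0, jitter_sd)
            y += _STEP * np.sin(heading)
            x += _STEP * np.cos(heading)
            if (y - cy) ** 2 + (x - cx) ** 2 > fov_r ** 2:
                break
            points.append((y, x, width))
            if rng.uniform() < spec.branch_prob and depth < 6:
                child_w = width * spec.width_decay
                if child_w >= _MIN_WIDTH:
                    side = 1.0 if rng.uniform() < 0.5 else -1.0
                    split = np.deg2rad(rng.uniform(25.0, 50.0))
                    stack.append((y, x, heading + side * split, child_w, depth + 1))
                    heading -= side * split * 0.4
                    width = width * (0.5 + 0.5 * spec.width_decay)
                    if width < _MIN_WIDTH:
                        break
    return points


def _rasterize(points, spec: PhantomSpec, width_scale: float = 1.0) -> np.ndarray:
    """Stamp a disc of the local radius at every centerline sample."""
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=np.uint8)
    yy, xx = np.ogrid[:h, :w]
    for y, x, width in points:
        r = max(width * width_scale / 2.0, 0.5)
        ri = int(np.ceil(r))
        y0, y1 = max(int(y) - ri - 1, 0), min(int(y) + ri + 2, h)
        x0, x1 = max(int(x) - ri - 1, 0), min(int(x) + ri + 2, w)
        sub = ((yy[y0:y1] - y) ** 2 + (xx[:, x0:x1] - x) ** 2) <= r * r
        mask[y0:y1, x0:x1] |= sub.astype(np.uint8)
    return mask


def _fov_disc(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.height, spec.width
    yy, xx = np.ogrid[:h, :w]
    r = spec.fov_radius_frac * min(h, w)
    return (((yy - h / 2.0) ** 2 + (xx - w / 2.0) ** 2) <= r * r).astype(np.uint8)


def _render(spec: PhantomSpec, mask: np.ndarray, fov: np.ndarray) -> np.ndarray:
    rng = np.random.default_rng(spec.seed + 1_000_003)
    h, w = spec.height, spec.width
    profile = gaussian_filter(mask.astype(np.float32), 0.8)
    profile /= max(profile.max(), 1e-6)

    background = 0.62
    gy, gx = rng.uniform(-1, 1, size=2)
    ramp = (gy * (np.arange(h)[:, None] - h / 2) / h
            + gx * (np.arange(w)[None, :] - w / 2) / w)
    intensity = background - spec.vessel_contrast * profile \
        + spec.illumination_gradient * ramp
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=(h, w))

    # green-dominant colouring to mimic fundus appearance (cosmetic)
    image = np.stack([intensity * 0.85, intensity, intensity * 0.55], axis=-1)
    image = np.clip(image, 0.0, 1.0)
    image *= fov[:, :, None]
    image += 0.02 * (1 - fov[:, :, None])  # faintly lit border
    return np.clip(image, 0.0, 1.0).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> ImageRecord:
    """Generate one phantom record (image, exact mask, disc FOV)."""
    fov = _fov_disc(spec)
    points = _grow_tree(spec)
    mask = _rasterize(points, spec) * fov
    if mask.sum() == 0:
        raise ValueError(
            "phantom spec produced zero vessel pixels; increase n_roots, "
            "width_root or fov_radius_frac")
    image = _render(spec, mask, fov)
    return ImageRecord(image, mask, fov, id=f"phantom_{spec.seed:05d}")


def generate_followup(spec: PhantomSpec, constriction_factor: float) -> ImageRecord:
    """Same vessel topology as ``generate_phantom(spec)``, thinner vessels.

    All segment widths are multiplied by ``constriction_factor`` in
    (0, 1], so the follow-up mask is a subset of the baseline mask and
    the vessel pixel count is non-increasing in the factor.
    """
    if not (0.0 < constriction_factor <= 1.0):
        raise ValueError("constriction_factor must lie in (0, 1]")
    fov = _fov_disc(spec)
    points = _grow_tree(spec)
    mask = _rasterize(points, spec, width_scale=constriction_factor) * fov
    if mask.sum() == 0:
        raise ValueError("constriction removed all vessel pixels")
    image = _render(spec, mask, fov)
    return ImageRecord(image, mask, fov,
                       id=f"phantom_{spec.seed:05d}_c{constriction_factor:.2f}")


def make_phantom_set(n: int, seed: int = 0, **overrides) -> list[ImageRecord]:
    """Generate ``n`` phantoms with consecutive seeds derived from ``seed``."""
    base = PhantomSpec(seed=seed, **overrides)
    return [generate_phantom(replace(base, seed=seed + i)) for i in range(n)]
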