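"""Synthetic liver-like phantoms with known ground truth.

A phantom emulates the hard case the texture-aware walker is built for: a
bright "liver" blob with spatially correlated texture, an adjacent
"confuser" organ whose *mean* intensity matches the liver's (within a few
gray levels) but whose texture does not — smooth correlated noise versus
high-variance white noise, the way gas-containing bowel or stomach next to
the liver shares its mean attenuation but not its homogeneity — and a
darker background.

Blobs are smooth star-convex regions (a Fourier-perturbed radius around a
centre); the confuser is placed tangent to the liver so the two regions
touch over a thin neck.  The design makes each pipeline stage face its
intended difficulty:

- histogram seeding works because the liver is the only *homogeneous*
  structure in the gray band: the confuser's wide white noise speckles its
  thresholded mask, so erosion dissolves it and the largest connected
  component is the liver alone;
- the intensity-only walker leaks through the contact neck, where the mean
  step is a few gray levels, while the true liver/background boundary is a
  large step;
- the probability-aware weights close the neck, because the classifier
  separates the two textures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .image_io import ImageGrid, LabelMask

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort"]


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (128, 128)
    liver_center: tuple | None = None  # default: left-of-centre
    liver_radius: float = 34.0
    mu_liver: float = 140.0
    liver_noise_sigma: float = 10.0
    liver_smooth_sigma: float = 2.0  # texture correlation length (px)
    confuser_radius: float = 18.0
    mu_confuser: float = 143.0
    confuser_noise_sigma: float = 30.0
    confuser_smooth_sigma: float = 0.0  # white noise
    confuser_angle_deg: float = 0.0  # direction of the confuser from the liver
    mu_background: float = 70.0
    global_noise_sigma: float = 2.0
    boundary_amplitude: float = 0.10  # fractional radius perturbation
    n_harmonics: int = 3
    contact_depth: float = 0.75  # overlap (px) along the liver-confuser axis
    rng_seed: int = 0


def _star_radius(theta: np.ndarray, base: float, amp: float, harmonics, phases) -> np.ndarray:
    r = np.full_like(theta, 1.0)
    for k, ph in zip(harmonics, phases):
        r += (amp / k) * np.cos(k * theta + ph)
    return base * r


def _blob_mask(shape, center, base_radius, amp, harmonics, phases):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    return rho <= _star_radius(theta, base_radius, amp, harmonics, phases)


def _textured_noise(shape, sigma, smooth, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean noise with std ``sigma``; ``smooth`` > 0 correlates it."""
    noise = rng.standard_normal(shape)
    if smooth > 0:
        noise = ndimage.gaussian_filter(noise, smooth)
        std = noise.std()
        if std > 0:
            noise = noise / std
    return sigma * noise


def generate_phantom(spec: PhantomSpec | None = None, rng: np.random.Generator | None = None):
    """One phantom image and its liver mask, deterministic for a seed.

    Returns ``(ImageGrid, LabelMask)``; the mask covers the liver blob only.
    """
    spec = spec or PhantomSpec()
    if len(spec.shape) != 2:
        raise ConfigError("phantoms are generated per 2-D slice")
    rng = rng or np.random.default_rng(spec.rng_seed)
    H, W = spec.shape
    center = spec.liver_center or (H / 2.0, W / 2.0 - spec.confuser_radius / 1.5)
    harmonics = list(range(2, 2 + spec.n_harmonics))
    phases_l = rng.uniform(0, 2 * math.pi, size=spec.n_harmonics)
    phases_c = rng.uniform(0, 2 * math.pi, size=spec.n_harmonics)

    liver = _blob_mask(spec.shape, center, spec.liver_radius, spec.boundary_amplitude, harmonics, phases_l)

    # place the confuser tangent to the liver along the chosen direction so
    # the two touch over a ~1-px neck
    ang = math.radians(spec.confuser_angle_deg)
    direction = np.array([math.sin(ang), math.cos(ang)])  # (dy, dx), 0 deg = east
    r_l = _star_radius(np.array([math.atan2(direction[0], direction[1])]),
                       spec.liver_radius, spec.boundary_amplitude, harmonics, phases_l)[0]
    r_c = _star_radius(np.array([math.atan2(-direction[0], -direction[1])]),
                       spec.confuser_radius, spec.boundary_amplitude, harmonics, phases_c)[0]
    dist = r_l + r_c - spec.contact_depth
    c_center = (center[0] + dist * direction[0], center[1] + dist * direction[1])
    margin = 2.0
    for cc, rr, s in ((center, spec.liver_radius, H), (c_center, spec.confuser_radius, H)):
        rmax = rr * (1 + spec.boundary_amplitude * 1.5)
        if (
            cc[0] - rmax < -margin
            or cc[1] - rmax < -margin
            or cc[0] + rmax > H + margin - 1
            or cc[1] + rmax > W + margin - 1
        ):
            raise ConfigError("phantom blobs overflow the grid; shrink radii or grid")
    confuser = _blob_mask(spec.shape, c_center, spec.confuser_radius, spec.boundary_amplitude, harmonics, phases_c)
    confuser &= ~liver  # disjoint regions, allowed to touch

    img = np.full(spec.shape, spec.mu_background, dtype=np.float64)
    img[liver] = spec.mu_liver + _textured_noise(
        spec.shape, spec.liver_noise_sigma, spec.liver_smooth_sigma, rng
    )[liver]
    img[confuser] = spec.mu_confuser + _textured_noise(
        spec.shape, spec.confuser_noise_sigma, spec.confuser_smooth_sigma, rng
    )[confuser]
    if spec.global_noise_sigma > 0:
        img += rng.normal(0.0, spec.global_noise_sigma, size=spec.shape)
    img = np.clip(img, 0.0, 255.0)
    return (
        ImageGrid(values=img, spacing=(1.0, 1.0)),
        LabelMask(labels=liver.astype(np.uint8), spacing=(1.0, 1.0)),
    )


def generate_cohort(n: int, base_spec: PhantomSpec | None = None, seed: int = 0):
    """n phantoms with jittered blob geometry; reproducible for a seed."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    out = []
    H, W = base.shape
    for _ in range(n):
        for _attempt in range(50):  # reject jitters that overflow the grid
            child_seed = int(master.integers(2**31))
            rng = np.random.default_rng(child_seed)
            center0 = base.liver_center or (H / 2.0, W / 2.0 - base.confuser_radius / 1.5)
            spec = replace(
                base,
                liver_center=(
                    center0[0] + rng.uniform(-5, 5),
                    center0[1] + rng.uniform(-5, 5),
                ),
                liver_radius=base.liver_radius * rng.uniform(0.9, 1.1),
                confuser_radius=base.confuser_radius * rng.uniform(0.9, 1.1),
                confuser_angle_deg=rng.uniform(-40, 40),
                rng_seed=child_seed,
            )
            try:
                out.append(generate_phantom(spec, np.random.default_rng(child_seed)))
                break
            except ConfigError:
                continue
        else:
            raise ConfigError("could not fit jittered phantom on the grid")
    return out
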