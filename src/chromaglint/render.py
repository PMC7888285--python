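"""Simplified physically based rendering of relief stimulus tiles.

A stimulus is a 10 cm square tile whose upper face carries smoothed value
noise scaled to a mesoscopic relief height (peak-to-peak amplitude as a
fraction of tile width).  The tile is slanted about the horizontal axis
between a horizontal-viewing camera and a large overhead rectangular emitter
(2.5 m x 1.0 m), and shaded with direct illumination only: a Lambertian
diffuse term carrying the base color, plus a Beckmann microfacet specular
lobe with a scalar amplitude (default 0.2).  Fresnel and shadow-masking
terms are omitted; the specular term is the NDF at the half-vector angle
with cosine foreshortening.  Diffuse and specular components are kept as
separate float images so the physical specular-coverage statistic can be
computed on the specular layer alone.

Geometry (world coordinates, metres): the camera looks along -z from
(0, 0, +0.6); world "up" is +y; the emitter is a horizontal rectangle at
height ``light_height`` centred above the tile.  At slant 45 deg the mean
surface normal bisects the viewing and overhead lighting directions, the
configuration that maximises mirror reflection of the emitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .colorimetry import srgb_decompand

__all__ = [
    "HeightField",
    "RenderConfig",
    "RenderedStimulus",
    "RenderError",
    "generate_height_field",
    "beckmann_ndf",
    "shade_surface",
    "physical_specular_coverage",
]


class RenderError(RuntimeError):
    pass


@dataclass(frozen=True)
class HeightField:
    """An n x n height map in tile-width units.

    After normalization the heights span exactly [0, relief], i.e. the
    peak-to-peak amplitude equals the relief displacement scale.
    """

    n: int
    z: np.ndarray
    relief: float
    seed: int

    def __post_init__(self):
        if self.z.shape != (self.n, self.n):
            raise ValueError("height map shape does not match n")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("height map contains non-finite values")


def generate_height_field(
    n: int,
    relief: float,
    seed: int,
    smoothing_passes: int = 2,
    lattice: int = 8,
) -> HeightField:
    """Smoothed value noise normalised to a peak-to-peak span of ``relief``.

    A ``lattice x lattice`` grid of uniform random values is cubic-upsampled
    to ``n x n`` (giving ~``lattice`` undulations across the tile), smoothed
    by ``smoothing_passes`` rounds of 3x3 neighbourhood averaging, then
    min-max normalised to [0, 1] and scaled by ``relief``.
    """
    if n < 8:
        raise ValueError("resolution n must be >= 8")
    if relief < 0:
        raise ValueError("relief must be >= 0")
    rng = np.random.default_rng(seed)
    base = rng.uniform(size=(lattice + 1, lattice + 1))
    # cubic interpolation of the lattice onto the pixel grid
    coords = np.linspace(0.0, lattice, n)
    ci, cj = np.meshgrid(coords, coords, indexing="ij")
    z = ndimage.map_coordinates(base, [ci, cj], order=3, mode="nearest")
    for _ in range(smoothing_passes):
        z = ndimage.uniform_filter(z, size=3, mode="nearest")
    ptp = z.max() - z.min()
    if relief == 0.0 or ptp == 0.0:
        z = np.zeros((n, n))
    else:
        z = (z - z.min()) / ptp * relief
    return HeightField(n=n, z=z, relief=float(relief), seed=int(seed))


def beckmann_ndf(theta_m, alpha: float):
    """Beckmann normal distribution D(theta_m) for facet angle theta_m (rad).

    D = exp(-tan^2(theta_m) / alpha^2) / (pi alpha^2 cos^4 theta_m), with the
    theta_m -> pi/2 limit returning 0.  Normalised so the projected solid
    angle integral of D cos(theta) over the hemisphere is 1.
    """
    if alpha <= 0:
        raise ValueError("roughness alpha must be positive")
    theta_m = np.asarray(theta_m, float)
    cos_t = np.cos(theta_m)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        tan2 = np.where(cos_t > 1e-12, (np.sin(theta_m) / np.where(cos_t > 1e-12, cos_t, 1.0)) ** 2, np.inf)
        d = np.exp(-tan2 / alpha**2) / (np.pi * alpha**2 * np.maximum(cos_t, 1e-12) ** 4)
        d = np.where(cos_t > 1e-12, d, 0.0)
    if d.shape == ():
        return float(d)
    return d


@dataclass(frozen=True)
class RenderConfig:
    """Shading configuration for one stimulus render.

    Lengths are metres; the tile width is ``tile_width``.  The emitter is a
    horizontal rectangle centred at (0, light_height, 0) spanning
    ``light_extent`` in (x, z), sampled on a deterministic
    ``light_samples`` grid.  ``diffuse_rgb`` is the companded base color
    (decompanded to linear albedo internally).
    """

    slant_deg: float
    diffuse_rgb: tuple[float, float, float]
    roughness: float = 0.1
    specular_amplitude: float = 0.2
    tile_width: float = 0.10
    light_height: float = 0.75
    light_extent: tuple[float, float] = (2.5, 1.0)
    light_samples: tuple[int, int] = (10, 4)
    image_size: int = 128

    def __post_init__(self):
        if self.specular_amplitude < 0:
            raise ValueError("specular amplitude must be >= 0")
        if self.roughness <= 0:
            raise ValueError("roughness must be positive")
        if min(self.light_samples) < 1:
            raise ValueError("need at least one light sample")


@dataclass(frozen=True)
class RenderedStimulus:
    """Separated diffuse and specular float images plus their exact sum."""

    diffuse_img: np.ndarray
    specular_img: np.ndarray
    composite_img: np.ndarray
    config: RenderConfig
    height_field: HeightField = field(repr=False, default=None)


def _light_sample_points(cfg: RenderConfig) -> np.ndarray:
    """Deterministic cell-centred grid of emitter sample points (S, 3)."""
    nx, nz = cfg.light_samples
    ex, ez = cfg.light_extent
    xs = (np.arange(nx) + 0.5) / nx * ex - ex / 2.0
    zs = (np.arange(nz) + 0.5) / nz * ez - ez / 2.0
    X, Z = np.meshgrid(xs, zs, indexing="ij")
    pts = np.stack(
        [X.ravel(), np.full(X.size, cfg.light_height), Z.ravel()], axis=-1
    )
    return pts


def shade_surface(hf: HeightField, cfg: RenderConfig) -> RenderedStimulus:
    """Direct illumination of a slanted height field from the area emitter.

    Per pixel: diffuse = albedo * mean_s (N.L)+ over emitter samples;
    specular = amplitude * mean_s D_beckmann(angle(N, H)) (N.L)+ with
    H the half-vector between the sample direction and the viewing
    direction.  Components are returned separately; the composite is their
    exact per-pixel sum in linear units.
    """
    n = hf.n
    w = cfg.tile_width
    theta = np.radians(cfg.slant_deg)

    # tile local frame embedded in world coordinates
    e_x = np.array([1.0, 0.0, 0.0])
    e_y = np.array([0.0, np.cos(theta), -np.sin(theta)])
    e_z = np.array([0.0, np.sin(theta), np.cos(theta)])

    coords = (np.linspace(0.0, 1.0, n) - 0.5) * w
    xl, yl = np.meshgrid(coords, coords, indexing="xy")
    zl = hf.z * w  # heights to metres

    spacing = w / (n - 1)
    gy, gx = np.gradient(zl, spacing)
    nl = np.stack([-gx, -gy, np.ones_like(gx)], axis=-1)
    norms = np.linalg.norm(nl, axis=-1, keepdims=True)
    if np.any(norms == 0):
        i, j = np.argwhere(norms[..., 0] == 0)[0]
        raise RenderError(f"degenerate surface normal at pixel ({i}, {j})")
    nl = nl / norms

    # into world coordinates
    frame = np.stack([e_x, e_y, e_z], axis=0)  # rows are local basis vectors
    pos = (
        xl[..., None] * e_x + yl[..., None] * e_y + zl[..., None] * e_z
    )  # (n, n, 3)
    normal = nl @ frame  # (n, n, 3)

    view = np.array([0.0, 0.0, 1.0])
    samples = _light_sample_points(cfg)  # (S, 3)
    S = len(samples)

    p = pos.reshape(-1, 3)
    nrm = normal.reshape(-1, 3)
    ldir = samples[None, :, :] - p[:, None, :]  # (P, S, 3)
    ldir = ldir / np.linalg.norm(ldir, axis=-1, keepdims=True)

    ndotl = np.einsum("psk,pk->ps", ldir, nrm)
    ndotl = np.maximum(ndotl, 0.0)

    half = ldir + view
    half = half / np.linalg.norm(half, axis=-1, keepdims=True)
    cos_m = np.clip(np.einsum("psk,pk->ps", half, nrm), -1.0, 1.0)
    theta_m = np.arccos(np.clip(cos_m, 0.0, 1.0))
    d = beckmann_ndf(theta_m, cfg.roughness)
    d = np.where(cos_m > 0.0, d, 0.0)

    diffuse_shading = ndotl.mean(axis=1).reshape(n, n)
    specular_shading = (
        cfg.specular_amplitude * (d * ndotl).mean(axis=1).reshape(n, n)
    )

    albedo = srgb_decompand(np.asarray(cfg.diffuse_rgb, float))
    diffuse_img = diffuse_shading[..., None] * albedo
    specular_img = np.repeat(specular_shading[..., None], 3, axis=-1)
    composite = diffuse_img + specular_img
    return RenderedStimulus(
        diffuse_img=diffuse_img,
        specular_img=specular_img,
        composite_img=composite,
        config=cfg,
        height_field=hf,
    )


def physical_specular_coverage(
    stim: RenderedStimulus, frac_threshold: float = 0.1
) -> float:
    """Fraction of pixels whose specular component exceeds
    ``frac_threshold`` x the image's maximum specular value.

    Zero-specular images report coverage 0 by convention.
    """
    if not 0.0 < frac_threshold <= 1.0:
        raise ValueError("frac_threshold must lie in (0, 1]")
    spec = stim.specular_img[..., 0]
    peak = float(spec.max())
    if peak <= 0.0:
        return 0.0
    return float(np.mean(spec > frac_threshold * peak))


def coverage_table(
    reliefs,
    slants,
    roughnesses=(0.1,),
    seeds=(0,),
    frac_threshold: float = 0.1,
    image_size: int = 96,
    diffuse_rgb: tuple[float, float, float] = (0.91, 0.42, 0.31),
    **config_overrides,
):
    """Physical specular coverage over a relief x slant (x roughness) sweep.

    Returns a tidy DataFrame with one row per (relief, roughness, slant,
    seed).  The coverage statistic is a meaningful highlight-area proxy only
    while the specular lobe is sharp enough to produce distinct highlights;
    the default roughness of 0.1 sits in that regime.
    """
    import pandas as pd

    rows = []
    for relief in reliefs:
        for seed in seeds:
            hf = generate_height_field(image_size, relief, seed=seed)
            for slant in slants:
                for rough in roughnesses:
                    cfg = RenderConfig(
                        slant_deg=slant,
                        diffuse_rgb=diffuse_rgb,
                        roughness=rough,
                        image_size=image_size,
                        **config_overrides,
                    )
                    cov = physical_specular_coverage(
                        shade_surface(hf, cfg), frac_threshold
                    )
                    rows.append((relief, rough, slant, seed, cov))
    return pd.DataFrame(
        rows, columns=["relief", "roughness", "slant", "seed", "coverage"]
    )


def save_png(stim: RenderedStimulus, path, exposure: float = 1.0) -> None:
    """Write the companded composite as an 8-bit PNG (clipped preview)."""
    import imageio.v3 as iio

    from .colorimetry import srgb_compand

    img = np.clip(srgb_compand(np.clip(stim.composite_img * exposure, 0, None)), 0, 1)
    iio.imwrite(path, (img * 255).astype(np.uint8))
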