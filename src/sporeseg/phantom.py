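"""Synthetic TEM-like spore phantoms with ground-truth label masks.

Real spore micrographs show a layered, roughly ellipsoidal cross-section:
a central core, the peptidoglycan cortex, the dark protein coat, a largely
empty interspace bounded by the thin exosporium, and an outermost "nap" of
short hair-like fibres, all embedded in a bright featureless background.
The phantom generator emulates that geometry with concentric rotated
ellipses, per-layer gray levels, optical blur and detector noise, plus an
off-spore "Badreg" debris blob, so the full 8-class annotation scheme is
exercised without any external data.

Gray levels are chosen so that core/cortex/coat/background are well
separated while interspace, exosporium and nap sit close together — the
class trio that is genuinely confusable in real TEM data.  The nap carries
a fibrous angular texture so that context (not mean intensity alone) is
needed to tell it from the interspace.

A "damaged core" mode mimics spores after oxidative chemical exposure
(e.g. hypochlorite): the core and, proportionally, the inner cortex lose
their stained appearance and are replaced by a mottled decomposed texture.
The ground-truth mask is left untouched — damage is an appearance
perturbation whose downstream signature is classifier confusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .image import AnnotatedImage
from .labels import (
    BACKGROUND,
    BADREG,
    COAT,
    CORE,
    CORTEX,
    EXOSPORIUM,
    INTERSPACE,
    NAP,
)

__all__ = ["PhantomConfig", "generate_spore_phantom", "apply_core_damage", "generate_dataset"]

#: outer elliptical radius of each layer, centre outward, as a fraction of
#: min(H, W)/2
_DEFAULT_RADII = (0.40, 0.60, 0.70, 0.80, 0.86, 0.92)

_DEFAULT_GRAYS = {
    BADREG: 0.12,
    COAT: 0.22,
    CORE: 0.35,
    CORTEX: 0.65,
    EXOSPORIUM: 0.72,
    INTERSPACE: 0.80,
    NAP: 0.76,
    BACKGROUND: 0.85,
}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic spore micrograph.

    ``layer_radii`` are the outer radii of core, cortex, coat, interspace,
    exosporium and nap (strictly increasing).  Jitter fields bound the
    per-phantom random variation of geometry and intensity that
    :func:`generate_dataset` relies on for inter-image diversity.
    """

    image_size: tuple[int, int] = (512, 416)
    layer_radii: tuple[float, ...] = _DEFAULT_RADII
    layer_gray_levels: dict[int, float] = field(default_factory=lambda: dict(_DEFAULT_GRAYS))
    noise_sd: float = 0.03
    blur_sigma: float = 1.0
    ellipticity: float = 0.75
    nap_enabled: bool = True
    badreg_enabled: bool = True
    damage_level: float = 0.0
    center_jitter: float = 0.04
    radius_jitter: float = 0.06
    gray_jitter: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.layer_radii) != 6:
            raise ConfigurationError("layer_radii must list 6 outer radii (core..nap)")
        radii = np.asarray(self.layer_radii, dtype=float)
        if not np.all(np.diff(radii) > 0) or radii[0] <= 0:
            raise ConfigurationError("layer_radii must be strictly increasing and positive")
        for cls, g in self.layer_gray_levels.items():
            if not 0.0 <= g <= 1.0:
                raise ConfigurationError(f"gray level for class {cls} outside [0, 1]: {g}")
        if not 0.0 <= self.damage_level <= 1.0:
            raise ConfigurationError("damage_level must lie in [0, 1]")
        if not 0.0 < self.ellipticity <= 1.0:
            raise ConfigurationError("ellipticity must lie in (0, 1]")


def _elliptical_radius(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    ellipticity: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized elliptical radius and polar angle for every pixel."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    r0 = min(h, w) / 2.0
    re = np.sqrt(u**2 + (v / ellipticity) ** 2) / r0
    phi = np.arctan2(v, u)
    return re, phi


def generate_spore_phantom(config: PhantomConfig) -> AnnotatedImage:
    """Generate one phantom micrograph with its ground-truth mask.

    Fully reproducible from ``config.seed``; geometry (centre, orientation,
    radii) and gray levels are jittered within the configured ranges so two
    phantoms with different seeds differ the way two spores in one image
    set do.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size

    cy = h / 2.0 + rng.uniform(-config.center_jitter, config.center_jitter) * h
    cx = w / 2.0 + rng.uniform(-config.center_jitter, config.center_jitter) * w
    angle = rng.uniform(0, np.pi)
    radii = np.asarray(config.layer_radii) * (
        1.0 + rng.uniform(-config.radius_jitter, config.radius_jitter)
    )
    ell = float(np.clip(config.ellipticity + rng.uniform(-0.05, 0.05), 0.4, 1.0))
    grays = {
        cls: float(np.clip(g + rng.uniform(-config.gray_jitter, config.gray_jitter), 0, 1))
        for cls, g in config.layer_gray_levels.items()
    }

    re, phi = _elliptical_radius((h, w), (cy, cx), angle, ell)

    mask = np.full((h, w), BACKGROUND, dtype=np.uint8)
    # centre outward; the nap band falls back to background when disabled
    order = [CORE, CORTEX, COAT, INTERSPACE, EXOSPORIUM, NAP]
    inner = 0.0
    for cls, outer in zip(order, radii):
        band = (re > inner) & (re <= outer) if inner > 0 else re <= outer
        if cls == NAP and not config.nap_enabled:
            mask[band] = BACKGROUND
        else:
            mask[band] = cls
        inner = outer

    img = np.full((h, w), grays[BACKGROUND], dtype=np.float64)
    for cls in order:
        if cls == NAP:
            continue
        img[mask == cls] = grays[cls]

    # nap: hair-like fibres — alternating dark fibres over background gray
    nap_band = (re > radii[4]) & (re <= radii[5])
    if config.nap_enabled and nap_band.any():
        k = max(24, int(0.15 * min(h, w)))
        fibre = np.sin(phi * k + rng.uniform(0, 2 * np.pi)) > 0.0
        nap_vals = np.where(fibre, grays[NAP] - 0.18, grays[BACKGROUND] - 0.02)
        img[nap_band] = nap_vals[nap_band]

    # fine granular texture inside the core (stained cytoplasmic content)
    core_px = mask == CORE
    if core_px.any():
        tex = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 1.5)
        sd = tex.std()
        if sd > 0:
            img[core_px] += 0.05 * (tex[core_px] / sd)

    # off-spore debris blob ("Badreg")
    if config.badreg_enabled:
        by = h * rng.uniform(0.06, 0.16)
        bx = w * rng.uniform(0.06, 0.16)
        br = 0.07 * min(h, w) * rng.uniform(0.8, 1.2)
        yy, xx = np.mgrid[0:h, 0:w]
        blob = ((yy - by) ** 2 + (xx - bx) ** 2) <= br**2
        blob &= mask == BACKGROUND  # never overwrite the spore
        mask[blob] = BADREG
        img[blob] = grays[BADREG]

    img = ndimage.gaussian_filter(img, config.blur_sigma)
    img = img + rng.normal(0.0, config.noise_sd, (h, w))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    out = AnnotatedImage(
        pixels=img,
        mask=mask,
        meta={"source": "phantom", "seed": int(config.seed), "damage_level": 0.0},
    )
    if config.damage_level > 0:
        out = apply_core_damage(out, config.damage_level, seed=int(config.seed) + 1)
    return out


def apply_core_damage(image: AnnotatedImage, damage_level: float, seed: int) -> AnnotatedImage:
    """Perturb a phantom's appearance the way oxidative damage perturbs spores.

    The core (weight ``damage_level``) and the inner portion of the cortex
    (tapering with distance from the core, extent proportional to
    ``damage_level``) are blended toward a mottled decomposed texture.  The
    ground-truth mask is returned unchanged: the damaged regions still *are*
    core and cortex, they merely no longer look it.
    """
    if not 0.0 <= damage_level <= 1.0:
        raise ConfigurationError("damage_level must lie in [0, 1]")
    if image.mask is None or not (image.mask == CORE).any():
        raise ValueError("image mask must contain core pixels (class 3)")
    out = image.copy()
    out.meta["damage_level"] = float(damage_level)
    if damage_level == 0.0:
        return out

    rng = np.random.default_rng(seed)
    h, w = image.spatial_shape
    mask = image.mask

    # decomposed texture: discolored toward the core's gray, with both the
    # core's fine granularity and a coarser mottle
    fine = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 1.5)
    coarse = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 4.0)
    for t in (fine, coarse):
        sd = t.std()
        if sd > 0:
            t /= sd
    texture = np.clip(0.44 + 0.05 * fine + 0.06 * coarse, 0.0, 1.0)

    weight = np.zeros((h, w), dtype=np.float64)
    weight[mask == CORE] = damage_level

    # the inner fraction `damage_level` of the cortex band decomposes fully,
    # with a short smooth shoulder toward the intact outer cortex
    cortex_px = mask == CORTEX
    if cortex_px.any():
        dist_from_core = ndimage.distance_transform_edt(mask != CORE)
        band = dist_from_core[cortex_px]
        depth = band.max()
        if depth > 0:
            rel = band / depth  # 0 at the core boundary, 1 at the coat
            shoulder = np.clip((damage_level - rel) / 0.15 + 1.0, 0.0, 1.0)
            weight[cortex_px] = damage_level * shoulder

    px = out.pixels.astype(np.float64)
    if px.ndim == 3:
        blended = (1.0 - weight[..., None]) * px + weight[..., None] * texture[..., None]
    else:
        blended = (1.0 - weight) * px + weight * texture
    out.pixels = np.clip(blended, 0.0, 1.0).astype(np.float32)
    return out


def generate_dataset(n: int, config: PhantomConfig, seed: int) -> list[AnnotatedImage]:
    """Generate ``n`` phantoms with per-item derived seeds.

    Geometry and intensity jitter happen inside :func:`generate_spore_phantom`
    driven by each item's seed, so the dataset shows inter-image variation
    within the configured ranges while remaining reproducible from
    ``(n, config, seed)``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    item_seeds = rng.integers(0, 2**31 - 1, size=n)
    out = []
    for i, s in enumerate(item_seeds):
        img = generate_spore_phantom(replace(config, seed=int(s)))
        img.meta["index"] = i
        out.append(img)
    return out
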