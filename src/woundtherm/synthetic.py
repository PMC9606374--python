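"""Synthetic pseudo-colour thermal wound images.

Real infrared recordings of venous leg ulcers are not publicly deposited, so
this module emulates their salient structure: a warm elliptical wound bed
carrying a stationary random texture whose roughness depends on the healing
class, sitting on a cooler heterogeneous background, with a vendor-logo block
and a monotone pseudo-colour ("ironbow") mapping.  Unhealed wounds are given a
rougher, more asymmetric temperature texture than healed wounds, matching the
direction of the class differences the downstream texture statistics are meant
to detect; the absolute magnitudes are synthetic and make no claim of
radiometric fidelity.

Every generator output is a pure function of its parameters and seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticParams",
    "ThermalImage",
    "apply_colormap",
    "colormap_lut",
    "generate_wound_image",
    "generate_cohort",
    "write_cohort",
]

Label = Literal["healed", "unhealed"]

#: Rec.709 luminance weights, shared with :mod:`woundtherm.preprocess`.
LUMA = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class SyntheticParams:
    """Dials of the synthetic thermal-wound generator.

    Grey values live in [0, 1] ("grey units"); lengths are in pixels.  The
    defaults encode the study conditions this generator stands in for: a
    160x120 raster, a wound bed markedly warmer than the background (the
    offset is far above 3x the pixel noise, so threshold masking succeeds by
    construction), and unhealed-class texture that is rougher (shorter
    correlation length), stronger (larger amplitude) and more asymmetric
    (positive skew) than the healed class.
    """

    width: int = 160
    height: int = 120
    #: (lo, hi) range the two ellipse semi-axes are drawn from, pixels.
    wound_axes: tuple[float, float] = (16.0, 28.0)
    #: Mean grey level of the wound interior.
    base_temp_level: float = 0.75
    #: Mean grey level of the background (strictly cooler than the wound).
    background_level: float = 0.30
    texture_corr_length_healed: float = 3.0
    texture_corr_length_unhealed: float = 1.5
    texture_amp_healed: float = 0.05
    texture_amp_unhealed: float = 0.08
    #: Marginal skew of the wound texture field; positive values produce the
    #: occasional hot spot that drives cluster shade/prominence upwards.
    texture_skew_healed: float = 0.0
    texture_skew_unhealed: float = 1.2
    background_gradient_amp: float = 0.08
    background_noise_sd: float = 0.01
    #: (x0, y0, w, h) of the vendor-logo block, or None for no logo.
    logo_rect: tuple[int, int, int, int] | None = (6, 6, 42, 14)
    logo_level: float = 0.95
    colormap_name: str = "ironbow"

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("frame must be at least 8x8 pixels")
        for name in (
            "texture_amp_healed",
            "texture_amp_unhealed",
            "background_gradient_amp",
            "background_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lim = min(self.width, self.height)
        for name in ("texture_corr_length_healed", "texture_corr_length_unhealed"):
            if not 0 < getattr(self, name) < lim:
                raise ValueError(f"{name} must lie in (0, min(width, height))")
        if self.texture_amp_unhealed < self.texture_amp_healed:
            raise ValueError(
                "texture_amp_unhealed must be >= texture_amp_healed "
                "(unhealed wounds carry the rougher texture)"
            )
        if not 0.0 <= self.base_temp_level <= 1.0:
            raise ValueError("base_temp_level must be in [0, 1]")
        if self.wound_axes[0] <= 0 or self.wound_axes[0] > self.wound_axes[1]:
            raise ValueError("wound_axes must be an increasing positive range")


@dataclass
class ThermalImage:
    """A pseudo-colour thermal raster with (synthetic-only) ground truth."""

    rgb: np.ndarray  # H x W x 3 uint8
    label: str = "unknown"
    subject_id: str = ""
    #: Ground-truth wound region; only synthetic images carry one.
    true_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an H x W x 3 raster")


# ---------------------------------------------------------------------------
# Pseudo-colour mapping
# ---------------------------------------------------------------------------

def _ironbow_channels(grey: np.ndarray) -> np.ndarray:
    """Hot-iron-like map: red ignites first, then green, then blue.

    The ramp breakpoints are the Rec.709 luminance weights, so the luminance
    of the mapped colour equals the grey value exactly — the map is monotone
    and stably invertible.
    """
    r_w, g_w, b_w = LUMA
    r = np.clip(grey / r_w, 0.0, 1.0)
    g = np.clip((grey - r_w) / g_w, 0.0, 1.0)
    b = np.clip((grey - r_w - g_w) / b_w, 0.0, 1.0)
    return np.stack([r, g, b], axis=-1)


_COLORMAPS = {
    "ironbow": _ironbow_channels,
    "grey": lambda g: np.stack([g, g, g], axis=-1),
}


def apply_colormap(grey: np.ndarray, colormap_name: str = "ironbow") -> np.ndarray:
    """Map a grey field in [0, 1] to an 8-bit RGB raster.

    All registered maps are monotone in luminance, so grey ordering survives
    the round trip through :func:`woundtherm.preprocess.rgb_to_grey`.
    """
    try:
        fn = _COLORMAPS[colormap_name]
    except KeyError:
        raise ValueError(
            f"unknown colormap {colormap_name!r}; known: {sorted(_COLORMAPS)}"
        ) from None
    grey = np.clip(np.asarray(grey, dtype=float), 0.0, 1.0)
    rgb = fn(grey)
    return np.round(rgb * 255.0).astype(np.uint8)


def colormap_lut(colormap_name: str = "ironbow", n: int = 256) -> np.ndarray:
    """n x 3 uint8 lookup table sampling the map on a uniform grey grid."""
    grid = np.linspace(0.0, 1.0, n)
    return apply_colormap(grid, colormap_name)


# ---------------------------------------------------------------------------
# Image generation
# ---------------------------------------------------------------------------

def _texture_field(
    rng: np.random.Generator,
    shape: tuple[int, int],
    corr_length: float,
    skew: float,
) -> np.ndarray:
    """Unit-variance stationary random field with optional marginal skew.

    White noise is Gaussian-smoothed (correlation length = filter sigma) and
    re-standardised; a quadratic tilt z + skew*(z^2-1)/sqrt(2) then adds the
    hot-spot asymmetry, renormalised back to unit variance.
    """
    z = gaussian_filter(rng.standard_normal(shape), sigma=corr_length, mode="reflect")
    z = (z - z.mean()) / max(z.std(), 1e-12)
    if skew != 0.0:
        z = (z + skew * (z * z - 1.0) / np.sqrt(2.0)) / np.sqrt(1.0 + skew * skew)
    return z


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, a: float, b: float, theta: float
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_wound_image(
    params: SyntheticParams, label: Label, seed: int
) -> ThermalImage:
    """Generate one pseudo-colour thermal wound image.

    Deterministic for fixed ``(params, label, seed)``.  The wound is a warm
    ellipse carrying class-dependent texture; the background is a smooth
    gradient plus independent pixel noise, strictly cooler on average; the
    logo rectangle is overwritten with a constant block; the grey field is
    mapped through ``params.colormap_name``.
    """
    if label not in ("healed", "unhealed"):
        raise ValueError(f"label must be 'healed' or 'unhealed', got {label!r}")
    h, w = params.height, params.width
    margin = 2.0
    if 2 * (params.wound_axes[1] + margin) > min(h, w):
        raise ValueError(
            "wound ellipse cannot fit inside the frame: reduce wound_axes "
            f"(max semi-axis {params.wound_axes[1]}) or enlarge the frame"
        )
    rng = np.random.default_rng(seed)

    # Background: oriented linear gradient around background_level plus noise.
    phi = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (np.cos(phi) * (xx / (w - 1) - 0.5)) + (np.sin(phi) * (yy / (h - 1) - 0.5))
    grey = params.background_level + params.background_gradient_amp * ramp

    # Wound ellipse: axes, orientation, centre drawn so the ellipse fits and
    # stays clear of the (corner) logo block, as real framing would.
    a = rng.uniform(*params.wound_axes)
    b = rng.uniform(*params.wound_axes)
    theta = rng.uniform(0.0, np.pi)
    r = max(a, b) + margin
    for _ in range(200):
        cy = rng.uniform(r, h - 1 - r)
        cx = rng.uniform(r, w - 1 - r)
        if params.logo_rect is None:
            break
        x0, y0, lw, lh = params.logo_rect
        dx = max(x0 - cx, cx - (x0 + lw), 0.0)
        dy = max(y0 - cy, cy - (y0 + lh), 0.0)
        if np.hypot(dx, dy) > r:
            break
    else:
        raise ValueError("could not place the wound clear of the logo block")
    mask = _ellipse_mask((h, w), cy, cx, a, b, theta)

    if label == "unhealed":
        amp = params.texture_amp_unhealed
        corr = params.texture_corr_length_unhealed
        skew = params.texture_skew_unhealed
    else:
        amp = params.texture_amp_healed
        corr = params.texture_corr_length_healed
        skew = params.texture_skew_healed
    tex = _texture_field(rng, (h, w), corr, skew)
    grey = np.where(mask, params.base_temp_level + amp * tex, grey)

    grey = grey + rng.normal(0.0, params.background_noise_sd, size=(h, w))
    grey = np.clip(grey, 0.0, 1.0)

    if params.logo_rect is not None:
        x0, y0, lw, lh = params.logo_rect
        if x0 < 0 or y0 < 0 or x0 + lw > w or y0 + lh > h:
            raise ValueError("logo_rect extends outside the frame")
        grey[y0 : y0 + lh, x0 : x0 + lw] = params.logo_level

    rgb = apply_colormap(grey, params.colormap_name)
    return ThermalImage(rgb=rgb, label=label, true_mask=mask)


def generate_cohort(
    n_unhealed: int,
    n_healed: int,
    params: SyntheticParams | None = None,
    seed: int = 0,
) -> list[ThermalImage]:
    """Generate a labelled cohort, unhealed images first.

    Per-image seeds are derived deterministically from the master seed, so
    the whole cohort is reproducible and images are mutually independent.
    The default study composition downstream is 47 unhealed / 17 healed.
    """
    if n_unhealed < 1 or n_healed < 1:
        raise ValueError("both class counts must be >= 1")
    params = params or SyntheticParams()
    n = n_unhealed + n_healed
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    labels: list[Label] = ["unhealed"] * n_unhealed + ["healed"] * n_healed
    cohort = []
    for i, (lab, s) in enumerate(zip(labels, child_seeds)):
        img = generate_wound_image(params, lab, int(s))
        img.subject_id = f"S{i:03d}"
        cohort.append(img)
    return cohort


def write_cohort(
    cohort: Sequence[ThermalImage], out_dir: str | Path, seed: int | None = None
) -> Path:
    """Write cohort PNGs plus a ``manifest.csv`` (filename, subject_id, label, seed)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "subject_id", "label", "seed"])
        for img in cohort:
            fname = f"{img.subject_id}.png"
            Image.fromarray(img.rgb).save(out_dir / fname)
            writer.writerow([fname, img.subject_id, img.label, seed])
    return manifest
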