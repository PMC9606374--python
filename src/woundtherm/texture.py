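"""Grey-level co-occurrence matrix (GLCM) texture features.

The wound bed's grey values are quantized to ``n_levels`` equal-width bins
(levels 1..Ng, Haralick convention) and co-occurrences of level pairs are
counted at a fixed (angle, distance) offset, restricted to pixel pairs whose
*both* endpoints lie inside the wound mask.  Nineteen scalar statistics of the
normalised co-occurrence distribution p(i, j) are then computed: the classic
Haralick set (energy, contrast, correlation, variance, sum/difference
statistics, entropies, information measure of correlation) extended with
autocorrelation, dissimilarity, cluster shade/prominence, maximum probability
and the inverse-difference family, including the normalised variants.

Defaults follow the thermal-wound protocol: angle 90 degrees, distance 1,
symmetric accumulation, 16 grey levels, natural logarithms with 0*log 0 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .preprocess import (
    BinaryMask,
    GreyImage,
    WoundBed,
    compute_mask,
    extract_wound_bed,
    normalise,
    remove_logo,
    rgb_to_grey,
)
from .synthetic import ThermalImage

__all__ = [
    "GLCMConfig",
    "GLCM",
    "FeatureVector",
    "FEATURE_NAMES",
    "PreprocessConfig",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "extract_features",
    "extract_feature_table",
]

#: Canonical ordering of the 19 textural features.
FEATURE_NAMES = (
    "Eng", "Cont", "Corr", "sumSq", "sumAv", "sumVar", "Entr", "sumEnt",
    "diffEnt", "imCorr", "Hom", "aCorr", "dSim", "clSha", "clPro",
    "maxProb", "idHom", "idNorm", "idmNorm",
)

#: (row, col) offsets with row 0 at the top; angles measured as in Haralick.
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass(frozen=True)
class GLCMConfig:
    n_levels: int = 16
    angle: int = 90
    distance: int = 1
    symmetric: bool = True
    log_base: Literal["natural", "2"] = "natural"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")
        if self.angle not in _ANGLE_OFFSETS:
            raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}")

    @property
    def offset(self) -> tuple[int, int]:
        dr, dc = _ANGLE_OFFSETS[self.angle]
        return dr * self.distance, dc * self.distance


@dataclass
class GLCM:
    """Normalised co-occurrence probabilities p(i, j), levels 1..Ng."""

    p: np.ndarray
    n_pairs: int
    config: GLCMConfig

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        ng = self.config.n_levels
        if self.p.shape != (ng, ng):
            raise ValueError(f"p must be {ng}x{ng}")
        if (self.p < 0).any():
            raise ValueError("co-occurrence probabilities must be >= 0")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("co-occurrence probabilities must sum to 1")
        if self.config.symmetric and not np.array_equal(self.p, self.p.T):
            raise ValueError("symmetric GLCM must equal its transpose")


@dataclass
class FeatureVector:
    """The 19 textural features of one wound bed."""

    Eng: float
    Cont: float
    Corr: float
    sumSq: float
    sumAv: float
    sumVar: float
    Entr: float
    sumEnt: float
    diffEnt: float
    imCorr: float
    Hom: float
    aCorr: float
    dSim: float
    clSha: float
    clPro: float
    maxProb: float
    idHom: float
    idNorm: float
    idmNorm: float
    #: True when the quantized bed had a single grey level (correlation is
    #: then reported as 0 rather than undefined).
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the wound-bed isolation pipeline."""

    logo_rect: tuple[int, int, int, int] | None = (6, 6, 42, 14)
    grey_mode: Literal["luminance", "colormap_inverse"] = "luminance"
    colormap_name: str = "ironbow"
    mask_method: Literal["otsu", "fixed"] = "otsu"
    mask_threshold: float | None = None
    erosion_radius: int = 2


def quantize(bed: WoundBed, n_levels: int = 16) -> np.ndarray:
    """Quantize eligible grey values into levels 1..Ng; 0 marks excluded pixels.

    Equal-width binning of [min, max] of the eligible pixels:
    ``level = 1 + floor(Ng * (g - min) / (max - min))`` clipped to Ng.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    mask = bed.mask.values
    if mask.sum() < 2:
        raise ValueError("wound bed needs at least 2 eligible pixels")
    g = bed.grey.values
    vals = g[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(g.shape, dtype=np.int64)
    if hi == lo:
        warnings.warn("constant wound bed: all pixels mapped to level 1", stacklevel=2)
        levels[mask] = 1
        return levels
    q = 1 + np.floor(n_levels * (g - lo) / (hi - lo)).astype(np.int64)
    levels[mask] = np.clip(q[mask], 1, n_levels)
    return levels


def compute_glcm(
    levels: np.ndarray, mask: BinaryMask | np.ndarray, config: GLCMConfig = GLCMConfig()
) -> GLCM:
    """Count level co-occurrences at the configured offset inside the mask.

    Only ordered pairs with *both* endpoints mask-eligible contribute; with
    ``symmetric`` the reverse offset is accumulated as well, making p equal
    to its transpose exactly.
    """
    levels = np.asarray(levels)
    m = mask.values if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    if levels.shape != m.shape:
        raise ValueError("levels and mask shapes differ")
    dr, dc = config.offset
    ng = config.n_levels
    h, w = levels.shape

    # Window where position (r, c) and (r+dr, c+dc) both exist.
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("offset larger than the image: no eligible pairs")
    src = levels[r0:r1, c0:c1]
    dst = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = m[r0:r1, c0:c1] & m[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    i, j = src[ok], dst[ok]
    if i.size == 0:
        raise ValueError(
            "no eligible pixel pairs at this offset (degenerate mask)"
        )
    counts = np.bincount((i - 1) * ng + (j - 1), minlength=ng * ng).reshape(ng, ng)
    counts = counts.astype(float)
    if config.symmetric:
        counts = counts + counts.T
    n_pairs = int(counts.sum())
    return GLCM(p=counts / counts.sum(), n_pairs=n_pairs, config=config)


def _log(x: np.ndarray, base: str) -> np.ndarray:
    return np.log2(x) if base == "2" else np.log(x)


def _xlogx(p: np.ndarray, base: str) -> np.ndarray:
    """p * log p with the 0*log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * _log(p[nz], base)
    return out


def glcm_features(glcm: GLCM) -> FeatureVector:
    """Compute the 19 textural features of a normalised GLCM."""
    p = glcm.p
    ng = glcm.config.n_levels
    base = glcm.config.log_base
    i = np.arange(1, ng + 1)[:, None]  # row level
    j = np.arange(1, ng + 1)[None, :]  # col level

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    lv = np.arange(1, ng + 1)
    mu_x = float(lv @ px)
    mu_y = float(lv @ py)
    sd_x = float(np.sqrt(((lv - mu_x) ** 2) @ px))
    sd_y = float(np.sqrt(((lv - mu_y) ** 2) @ py))

    # Marginals of i+j (k = 2..2Ng) and |i-j| (k = 0..Ng-1).
    p_sum = np.zeros(2 * ng + 1)
    np.add.at(p_sum, (i + j).ravel(), p.ravel())
    p_sum = p_sum[2:]
    ks = np.arange(2, 2 * ng + 1)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(i - j).ravel(), p.ravel())
    kd = np.arange(ng)

    absdiff = np.abs(i - j)
    sqdiff = (i - j) ** 2

    eng = float((p * p).sum())
    cont = float((sqdiff * p).sum())
    sum_sq = float((((i - mu_x) ** 2) * p).sum())
    degenerate = sd_x == 0.0 or sd_y == 0.0
    if degenerate:
        corr = 0.0
    else:
        corr = float(((i * j * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    sum_av = float(ks @ p_sum)
    sum_var = float(((ks - sum_av) ** 2) @ p_sum)
    entr = float(-_xlogx(p, base).sum())
    sum_ent = float(-_xlogx(p_sum, base).sum())
    diff_ent = float(-_xlogx(p_diff, base).sum())

    hx = float(-_xlogx(px, base).sum())
    hy = float(-_xlogx(py, base).sum())
    pxpy = px[:, None] * py[None, :]
    valid = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[valid] * _log(pxpy[valid], base)).sum())
    denom = max(hx, hy)
    im_corr = float((entr - hxy1) / denom) if denom > 0 else 0.0

    hom = float((p / (1.0 + sqdiff)).sum())
    a_corr = float((i * j * p).sum())
    d_sim = float((absdiff * p).sum())
    dev = i + j - mu_x - mu_y
    cl_sha = float(((dev**3) * p).sum())
    cl_pro = float(((dev**4) * p).sum())
    max_prob = float(p.max())
    id_hom = float((p / (1.0 + absdiff)).sum())
    id_norm = float((p / (1.0 + absdiff / ng)).sum())
    idm_norm = float((p / (1.0 + sqdiff / ng**2)).sum())

    return FeatureVector(
        Eng=eng, Cont=cont, Corr=corr, sumSq=sum_sq, sumAv=sum_av,
        sumVar=sum_var, Entr=entr, sumEnt=sum_ent, diffEnt=diff_ent,
        imCorr=im_corr, Hom=hom, aCorr=a_corr, dSim=d_sim, clSha=cl_sha,
        clPro=cl_pro, maxProb=max_prob, idHom=id_hom, idNorm=id_norm,
        idmNorm=idm_norm, degenerate=degenerate,
    )


def extract_features(
    image: ThermalImage | np.ndarray,
    pre_config: PreprocessConfig = PreprocessConfig(),
    glcm_config: GLCMConfig = GLCMConfig(),
) -> tuple[FeatureVector, int]:
    """Full image-to-features pipeline; returns (features, mask pixel count).

    Composition: remove_logo -> rgb_to_grey -> normalise -> compute_mask ->
    extract_wound_bed -> quantize -> compute_glcm -> glcm_features.
    Deterministic.
    """
    rgb = image.rgb if isinstance(image, ThermalImage) else np.asarray(image)
    rgb = remove_logo(rgb, pre_config.logo_rect)
    grey = rgb_to_grey(rgb, pre_config.grey_mode, pre_config.colormap_name)
    grey = normalise(grey)
    mask = compute_mask(
        grey,
        method=pre_config.mask_method,
        threshold=pre_config.mask_threshold,
        erosion_radius=pre_config.erosion_radius,
    )
    bed = extract_wound_bed(grey, mask)
    levels = quantize(bed, glcm_config.n_levels)
    glcm = compute_glcm(levels, mask, glcm_config)
    return glcm_features(glcm), mask.n_pixels


def extract_feature_table(
    images: Iterable[ThermalImage],
    pre_config: PreprocessConfig = PreprocessConfig(),
    glcm_config: GLCMConfig = GLCMConfig(),
    filenames: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Feature table: one row per image with label, the 19 features and
    the extraction settings (n_levels, angle, distance, mask size)."""
    rows = []
    for idx, img in enumerate(images):
        fv, n_mask = extract_features(img, pre_config, glcm_config)
        row: dict[str, object] = {
            "filename": filenames[idx] if filenames is not None else f"{img.subject_id}.png",
            "subject_id": img.subject_id,
            "label": img.label,
        }
        row.update(fv.as_dict())
        row.update(
            n_levels=glcm_config.n_levels,
            angle=glcm_config.angle,
            distance=glcm_config.distance,
            mask_pixels=n_mask,
        )
        rows.append(row)
    return pd.DataFrame(rows)
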