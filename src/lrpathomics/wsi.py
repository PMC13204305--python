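"""Slide-to-patch preprocessing: tissue detection, tiling, Macenko stain
normalization, and RGB z-scoring.

Coordinates are 0-based with the origin at the top-left; a patch at
(x, y) covers the half-open extent [x, x+256) x [y, y+256), x indexing
columns and y indexing rows. Tiles lie on a non-overlapping 256-pixel grid
and partial edge tiles are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .synthetic import _nnls2

IO_DEFAULT = 255.0


@dataclass
class PatchRecord:
    slide_id: str
    x: int  # column offset, multiple of patch size
    y: int  # row offset, multiple of patch size
    pixels: np.ndarray  # 256 x 256 x 3 uint8
    tissue_frac: float


@dataclass
class StainModel:
    """Fitted 2-stain optical-density basis (hematoxylin first, then eosin)."""

    stain_matrix: np.ndarray  # 3 x 2, unit-norm columns
    max_conc: np.ndarray  # 99th-percentile concentration per stain
    io: float = IO_DEFAULT
    beta_od: float = 0.15
    alpha_pct: float = 1.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stain_matrix"] = self.stain_matrix.tolist()
        d["max_conc"] = self.max_conc.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StainModel":
        return cls(
            stain_matrix=np.asarray(d["stain_matrix"], float),
            max_conc=np.asarray(d["max_conc"], float),
            io=d.get("io", IO_DEFAULT),
            beta_od=d.get("beta_od", 0.15),
            alpha_pct=d.get("alpha_pct", 1.0),
        )


@dataclass
class ChannelStats:
    """Per-channel mean and sd over a reference patch set."""

    mean: np.ndarray
    sd: np.ndarray
    source_slides: tuple = ()  # provenance: slides the stats were fitted on


def rgb_to_od(img: np.ndarray, io: float = IO_DEFAULT) -> np.ndarray:
    """Optical density: -log10((I + 1) / io), per channel."""
    return -np.log10((img.astype(float) + 1.0) / io)


def od_to_rgb(od: np.ndarray, io: float = IO_DEFAULT) -> np.ndarray:
    img = io * np.power(10.0, -od) - 1.0
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def detect_tissue(
    image: np.ndarray, sat_threshold: float = 0.05, od_threshold: float = 0.15
) -> np.ndarray:
    """Pixel-level tissue mask: HSV saturation OR mean optical density.

    A pixel is tissue iff saturation > sat_threshold or its mean OD over
    channels > od_threshold (catches grey/dark pigments with low
    saturation).
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image (H x W x 3)")
    img = image.astype(np.float32)
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    # HSV saturation, (max - min)/max with S = 0 where max = 0
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0.0)
    od_mean = -np.log10((img + 1.0) / IO_DEFAULT).mean(axis=2)
    return (sat > sat_threshold) | (od_mean > od_threshold)


def tile_slide(
    image: np.ndarray,
    mask: np.ndarray,
    slide_id: str = "slide",
    patch_size: int = 256,
    min_tissue_frac: float = 0.5,
) -> list:
    """Non-overlapping grid tiling with background removal.

    Scans the grid in row-major order; keeps patches whose tissue fraction
    is at least ``min_tissue_frac``. Partial edge tiles are discarded.
    """
    h, w = image.shape[:2]
    if h < patch_size or w < patch_size:
        warnings.warn("image smaller than one patch; no tiles produced")
        return []
    patches = []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            frac = float(mask[y : y + patch_size, x : x + patch_size].mean())
            if frac >= min_tissue_frac:
                patches.append(
                    PatchRecord(
                        slide_id=slide_id,
                        x=x,
                        y=y,
                        pixels=image[y : y + patch_size, x : x + patch_size],
                        tissue_frac=frac,
                    )
                )
    return patches


def macenko_fit(
    pixels: np.ndarray,
    io: float = IO_DEFAULT,
    beta_od: float = 0.15,
    alpha_pct: float = 1.0,
    min_pixels: int = 1000,
) -> StainModel:
    """Estimate the 2-stain OD basis of an image by Macenko's method.

    Pixels with any-channel OD below ``beta_od`` are discarded; the
    remaining OD cloud is projected onto its top-2 principal plane; stain
    vectors are taken at the ``alpha_pct`` and ``100 - alpha_pct`` angle
    percentiles, unit-normalized, and ordered hematoxylin first (larger
    blue-channel OD). Concentration maxima are 99th percentiles of the
    non-negative least-squares concentrations.
    """
    if not 0 < alpha_pct < 50:
        raise ValueError("alpha_pct must lie in (0, 50)")
    flat = pixels.reshape(-1, 3)
    od = rgb_to_od(flat, io)
    od = od[od.min(axis=1) >= beta_od]
    if od.shape[0] < min_pixels:
        raise ValueError(
            f"only {od.shape[0]} tissue pixels after OD filtering "
            f"(need {min_pixels})"
        )
    cov = np.cov(od.T)
    evals, evecs = np.linalg.eigh(cov)
    # 8-bit quantization alone produces a second eigenvalue around 1e-4 of
    # the first on a single-stain image, while genuine two-stain mixtures
    # sit around 1e-1; 1e-3 separates the two regimes by two orders each way.
    if evals[-2] < 1e-3 * max(evals[-1], 1e-30):
        raise ValueError("degenerate stain plane")
    plane = evecs[:, -2:][:, ::-1]  # columns: top-2 eigenvectors
    # orient plane vectors so projections are mostly positive
    proj = od @ plane
    if proj[:, 0].mean() < 0:
        plane[:, 0] *= -1
        proj[:, 0] *= -1
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(phi, [alpha_pct, 100 - alpha_pct])
    v1 = plane @ np.array([np.cos(lo), np.sin(lo)])
    v2 = plane @ np.array([np.cos(hi), np.sin(hi)])
    vecs = []
    for v in (v1, v2):
        if v.sum() < 0:
            v = -v
        vecs.append(v / np.linalg.norm(v))
    # hematoxylin has the larger blue-channel OD
    if vecs[0][2] >= vecs[1][2]:
        stain = np.stack([vecs[0], vecs[1]], axis=1)
    else:
        stain = np.stack([vecs[1], vecs[0]], axis=1)
    conc = _nnls2(stain, od)
    max_conc = np.percentile(conc, 99, axis=0)
    if np.any(max_conc <= 0):
        raise ValueError("degenerate stain plane")
    return StainModel(
        stain_matrix=stain, max_conc=max_conc, io=io, beta_od=beta_od,
        alpha_pct=alpha_pct,
    )


def macenko_normalize(
    patch: np.ndarray, source: StainModel, reference: StainModel
) -> np.ndarray:
    """Map a patch from its source stain basis to a reference basis.

    Per-pixel source concentrations are rescaled by the ratio of reference
    to source concentration maxima and re-rendered through the reference
    stain matrix. Background (OD ~ 0) maps to background.
    """
    shape = patch.shape
    od = rgb_to_od(patch.reshape(-1, 3), source.io)
    conc = _nnls2(source.stain_matrix, od)
    conc = conc * (reference.max_conc / source.max_conc)
    od_new = conc @ reference.stain_matrix.T
    return od_to_rgb(od_new, reference.io).reshape(shape)


def zscore_rgb(patches, stats: ChannelStats | None = None,
               source_slides: tuple = ()):
    """Z-score patches per RGB channel.

    When ``stats`` is None the per-channel mean/sd are computed from the
    given patches (training set) and returned for reuse on held-out data,
    honouring the no-leakage contract.
    """
    arr = np.asarray(patches)
    out = arr.astype(np.float32, copy=True)
    if stats is None:
        flat = out.reshape(-1, out.shape[-1])
        mean = flat.mean(axis=0, dtype=np.float64)
        sd = np.sqrt(
            np.maximum(flat.astype(np.float64).var(axis=0, dtype=np.float64), 0)
        )
        if np.any(sd == 0):
            raise ValueError("constant channel; sd is zero")
        stats = ChannelStats(mean=mean, sd=sd, source_slides=tuple(source_slides))
    if np.any(stats.sd == 0):
        raise ValueError("constant channel; sd is zero")
    out -= stats.mean.astype(np.float32)
    out /= stats.sd.astype(np.float32)
    return out, stats
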