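"""Tile extraction and stain preprocessing for whole-slide-derived images.

The stages mirror standard computational-pathology practice: non-overlapping
224x224 tiling at a target resolution, rejection of background/blurry tiles
by Canny edge content, per-slide brightness standardization, and Macenko
stain normalization in optical-density space.  Feature extraction is a
pluggable seam (`embed_patches`): any callable mapping a tile to a fixed-
length vector can stand behind it, so bags generated directly in feature
space bypass the image stages entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.color import rgb2gray
from skimage.feature import canny
from skimage.transform import resize

__all__ = [
    "Tile",
    "StainModel",
    "REFERENCE_STAIN_MODEL",
    "InsufficientTissueError",
    "tile_image",
    "edge_fraction",
    "filter_patches",
    "standardize_brightness",
    "macenko_fit",
    "macenko_apply",
    "embed_patches",
    "identity_pool_embedder",
]

TILE_SIZE = 224


class InsufficientTissueError(ValueError):
    """Tile has too few tissue (high optical density) pixels to fit stains."""


@dataclass
class Tile:
    """A fixed-size RGB tile with its 0-based (row, col) origin in the source."""

    pixels: np.ndarray
    origin: tuple = (0, 0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile must be H x W x 3 RGB")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("tile values must lie in [0, 255]")
        self.pixels = self.pixels.astype(np.uint8)


@dataclass
class StainModel:
    """Macenko stain model: 3x2 unit-norm OD stain vectors (haematoxylin,
    eosin columns) plus reference 99th-percentile concentrations."""

    stain_matrix: np.ndarray  # 3 x 2
    max_concentrations: np.ndarray  # 2

    def __post_init__(self):
        self.stain_matrix = np.asarray(self.stain_matrix, dtype=float)
        self.max_concentrations = np.asarray(self.max_concentrations, dtype=float)
        if self.stain_matrix.shape != (3, 2):
            raise ValueError("stain_matrix must be 3x2")
        norms = np.linalg.norm(self.stain_matrix, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain vectors must have unit norm")
        if (self.stain_matrix < -1e-9).any():
            raise ValueError("stain vector entries must be nonnegative")

    def to_json(self, path=None) -> str:
        import json

        payload = json.dumps(
            {
                "stain_matrix": self.stain_matrix.tolist(),
                "max_concentrations": self.max_concentrations.tolist(),
            },
            indent=1,
        )
        if path is not None:
            from pathlib import Path

            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "StainModel":
        import json
        from pathlib import Path

        text = Path(source).read_text() if not str(source).lstrip().startswith("{") else str(source)
        d = json.loads(text)
        return cls(np.asarray(d["stain_matrix"]), np.asarray(d["max_concentrations"]))


# Widely used H&E reference (unit-norm columns) with matching reference
# maximum concentrations; shipped as the default normalization target.
_REF = np.array([[0.5626, 0.2159], [0.7201, 0.8012], [0.4062, 0.5581]])
REFERENCE_STAIN_MODEL = StainModel(
    stain_matrix=_REF / np.linalg.norm(_REF, axis=0),
    max_concentrations=np.array([1.9705, 1.0308]),
)


def tile_image(image, tile_size: int = TILE_SIZE, microns_per_pixel: float | None = None,
               target_mpp: float = 0.5) -> list:
    """Cut a non-overlapping grid of tiles; partial border tiles are dropped.

    If ``microns_per_pixel`` is provided the image is first resampled to
    ``target_mpp`` (0.5 um/px by default).  An image smaller than one tile
    yields an empty list.
    """
    image = np.asarray(image)
    if microns_per_pixel is not None and microns_per_pixel != target_mpp:
        scale = microns_per_pixel / target_mpp
        new_shape = (
            int(round(image.shape[0] * scale)),
            int(round(image.shape[1] * scale)),
            image.shape[2],
        )
        image = resize(image, new_shape, order=1, preserve_range=True,
                       anti_aliasing=scale < 1).round().clip(0, 255).astype(np.uint8)
    h, w = image.shape[:2]
    tiles = []
    for r in range(0, h - tile_size + 1, tile_size):
        for c in range(0, w - tile_size + 1, tile_size):
            tiles.append(Tile(image[r : r + tile_size, c : c + tile_size], (r, c)))
    return tiles


def _as_pixels(tile):
    return tile.pixels if isinstance(tile, Tile) else np.asarray(tile)


def edge_fraction(tile, canny_low: float = 50.0, canny_high: float = 150.0,
                  sigma: float = 1.0) -> float:
    """Fraction of pixels the Canny detector marks as edges on the grayscale
    tile.  Hysteresis thresholds are on the 8-bit grayscale scale."""
    gray = rgb2gray(_as_pixels(tile))  # in [0, 1]
    edges = canny(gray, sigma=sigma, low_threshold=canny_low / 255.0,
                  high_threshold=canny_high / 255.0)
    return float(edges.mean())


def filter_patches(tiles, edge_threshold: float = 2.0, **canny_kwargs):
    """Reject background and blurry tiles by edge content.

    A tile is rejected when its edge percentage (edge_fraction x 100) is
    less than or equal to ``edge_threshold`` (default 2).  Returns the kept
    tiles and a rejection log DataFrame (tile_id, origin, edge_pct, kept).
    """
    if edge_threshold < 0:
        raise ValueError("edge_threshold must be nonnegative")
    kept, rows = [], []
    for i, tile in enumerate(tiles):
        pct = edge_fraction(tile, **canny_kwargs) * 100.0
        keep = pct > edge_threshold
        origin = tile.origin if isinstance(tile, Tile) else (0, 0)
        rows.append({"tile_id": i, "row": origin[0], "col": origin[1],
                     "edge_pct": pct, "kept": keep})
        if keep:
            kept.append(tile)
    return kept, pd.DataFrame(rows)


def standardize_brightness(tile, target: int = 240, percentile: float = 90.0):
    """Linearly rescale so the given luminance percentile maps to ``target``.

    Idempotent up to 8-bit rounding.  A (near-)black tile is returned
    unchanged with a warning rather than dividing by ~0.
    """
    pixels = _as_pixels(tile).astype(float)
    lum = rgb2gray(pixels.astype(np.uint8)) * 255.0
    p = np.percentile(lum, percentile)
    if p < 1.0:
        warnings.warn("tile is (near-)black; brightness left unchanged")
        return tile if isinstance(tile, Tile) else pixels.astype(np.uint8)
    out = np.clip(np.round(pixels * (target / p)), 0, 255).astype(np.uint8)
    return Tile(out, tile.origin) if isinstance(tile, Tile) else out


# ---------------------------------------------------------------------------
# Macenko stain normalization


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Optical density OD = -log10((I + 1) / 256), elementwise."""
    return -np.log10((pixels.astype(float) + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    img = 256.0 * np.power(10.0, -np.clip(od, 0, None)) - 1.0
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _nnls_two_stain(stain_matrix: np.ndarray, od_pixels: np.ndarray) -> np.ndarray:
    """Nonnegative least squares for the 2-stain system, vectorized.

    Solves min ||S c - od||^2 s.t. c >= 0 per pixel.  With two columns the
    KKT cases enumerate: unconstrained solution if it is nonnegative, else
    the better of the two single-stain projections (clipped at zero).
    """
    s = stain_matrix
    gram = s.T @ s
    rhs = od_pixels @ s  # N x 2
    c_free = rhs @ np.linalg.inv(gram).T
    c1 = np.clip(rhs[:, 0] / gram[0, 0], 0, None)
    c2 = np.clip(rhs[:, 1] / gram[1, 1], 0, None)

    def residual2(c):
        return np.einsum("ij,ij->i", c @ gram, c) - 2 * np.einsum("ij,ij->i", c, rhs)

    cand1 = np.column_stack([c1, np.zeros_like(c1)])
    cand2 = np.column_stack([np.zeros_like(c2), c2])
    use_free = (c_free >= 0).all(axis=1)
    best_edge = np.where((residual2(cand1) <= residual2(cand2))[:, None], cand1, cand2)
    return np.where(use_free[:, None], c_free, best_edge)


def macenko_fit(tile, od_threshold: float = 0.15, angle_percentile: float = 1.0,
                min_tissue_pixels: int = 100) -> StainModel:
    """Estimate the two dominant stain vectors of a tile (Macenko method).

    Pixels with optical density above ``od_threshold`` in every channel are
    projected onto the top-2 principal plane of their OD covariance; the
    extreme directions at ``angle_percentile`` and its complement become the
    stain vectors, ordered so haematoxylin (larger red-channel OD) comes
    first.  Concentrations are solved by nonnegative least squares and the
    per-stain 99th percentiles stored as reference maxima.
    """
    pixels = _as_pixels(tile)
    od = rgb_to_od(pixels).reshape(-1, 3)
    tissue = od[(od > od_threshold).all(axis=1)]
    if tissue.shape[0] < min_tissue_pixels:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} tissue pixels above OD {od_threshold}"
        )

    _, vecs = np.linalg.eigh(np.cov(tissue, rowvar=False))
    plane = vecs[:, [2, 1]]  # top-2 eigenvectors
    # orient so projections are mostly positive
    for k in range(2):
        if (tissue @ plane[:, k]).sum() < 0:
            plane[:, k] *= -1
    proj = tissue @ plane
    angles = np.arctan2(proj[:, 1], proj[:, 0])
    lo, hi = np.percentile(angles, [angle_percentile, 100.0 - angle_percentile])
    v_lo = plane @ np.array([np.cos(lo), np.sin(lo)])
    v_hi = plane @ np.array([np.cos(hi), np.sin(hi)])

    stains = []
    for v in (v_lo, v_hi):
        v = np.clip(v, 0, None)
        n = np.linalg.norm(v)
        if n < 1e-9:
            raise InsufficientTissueError("degenerate stain direction")
        stains.append(v / n)
    # haematoxylin first: blue-purple, so it absorbs (has larger OD in) the
    # red channel, while eosin transmits red
    if stains[0][0] < stains[1][0]:
        stains = stains[::-1]
    stain_matrix = np.column_stack(stains)

    # percentile over ALL pixels, not just the tissue mask: the pixel
    # population is invariant under re-rendering, which makes repeated
    # normalization a (near-)identity
    conc = _nnls_two_stain(stain_matrix, od)
    max_c = np.percentile(conc, 99, axis=0)
    if (max_c <= 0).any():
        raise InsufficientTissueError("zero stain concentration on tissue pixels")
    return StainModel(stain_matrix, max_c)


def macenko_apply(tile, fitted: StainModel, reference: StainModel = REFERENCE_STAIN_MODEL):
    """Re-render a tile in the reference stain basis.

    Concentrations under the fitted model are rescaled by the ratio of
    reference to fitted maximum concentrations, mixed through the reference
    stain matrix and mapped back from optical density, clipped to [0, 255].
    """
    if (fitted.max_concentrations <= 0).any():
        raise ValueError("fitted model has zero max concentration")
    pixels = _as_pixels(tile)
    shape = pixels.shape
    od = rgb_to_od(pixels).reshape(-1, 3)
    conc = _nnls_two_stain(fitted.stain_matrix, od)
    conc *= reference.max_concentrations / fitted.max_concentrations
    out = od_to_rgb(conc @ reference.stain_matrix.T).reshape(shape)
    return Tile(out, tile.origin) if isinstance(tile, Tile) else out


# ---------------------------------------------------------------------------
# Patch embedding seam


def identity_pool_embedder(pixels: np.ndarray) -> np.ndarray:
    """Channel-wise mean and standard deviation: a 6-d summary embedding."""
    p = pixels.astype(float)
    return np.concatenate([p.mean(axis=(0, 1)), p.std(axis=(0, 1))])


def embed_patches(tiles, embedder=identity_pool_embedder) -> np.ndarray:
    """Stack one feature vector per tile, in tile order.

    ``embedder`` maps an H x W x 3 array to a fixed-length vector.  Bags
    already in feature form (a 2-D array) pass through unchanged.
    """
    if isinstance(tiles, np.ndarray) and tiles.ndim == 2:
        return tiles  # synthetic passthrough: already K x D features
    feats = [np.asarray(embedder(_as_pixels(t)), dtype=float).ravel() for t in tiles]
    if not feats:
        return np.empty((0, 0))
    dim = feats[0].size
    if any(f.size != dim for f in feats):
        raise ValueError("embedder output length inconsistent across tiles")
    return np.vstack(feats)
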