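"""Plot-image preprocessing: vegetation segmentation, geometry standardisation,
flip augmentation and trait normalisation.

The segmentation uses the visible-band difference vegetation index (VDVI),

    VDVI = (2*G - R - B) / (2*G + R + B),

thresholded at 0.057 by default, with dark pixels (green component < 10)
removed from the vegetation region.  Masked RGB/DSM pairs are centred on the
canopy centroid, rotated so the mask's principal axis is horizontal, and
padded/cropped to a fixed size with black (RGB) / zero (DSM) background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ShapeError, ZeroVarianceError

#: canonical trait order used everywhere in the package
TRAITS = ("DW", "SL", "NN", "NB", "PH")

DEFAULT_VDVI_THRESHOLD = 0.057
DEFAULT_MIN_GREEN = 10


# ---------------------------------------------------------------------------
# image pair container
# ---------------------------------------------------------------------------


@dataclass
class PlotImagePair:
    """Masked RGB image + DSM for one plot.

    Attributes
    ----------
    rgb : (H, W, 3) uint8 array
    dsm : (H, W) float array of heights in metres (above local ground once
        standardised)
    mask : (H, W) bool vegetation mask
    plot_id : identifier of the source plot
    """

    rgb: np.ndarray
    dsm: np.ndarray
    mask: np.ndarray
    plot_id: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        self.dsm = np.asarray(self.dsm, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ShapeError(f"rgb must be (H, W, 3), got {self.rgb.shape}")
        if self.rgb.shape[:2] != self.dsm.shape or self.dsm.shape != self.mask.shape:
            raise ShapeError(
                f"rgb {self.rgb.shape[:2]}, dsm {self.dsm.shape} and mask "
                f"{self.mask.shape} must share spatial dimensions"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


# ---------------------------------------------------------------------------
# VDVI and vegetation mask
# ---------------------------------------------------------------------------


def vdvi(rgb) -> np.ndarray | float:
    """Visible-band difference vegetation index, (2G - R - B) / (2G + R + B).

    Accepts an (..., 3) array or a single (R, G, B) triple.  Pixels with
    R = G = B = 0 have a zero denominator; they are defined to have VDVI 0
    (and are therefore never classed as vegetation).

    Returns values in [-1, 1], scalar for a single triple.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    scalar = arr.ndim == 1
    if arr.shape[-1] != 3:
        raise ShapeError(f"last axis must hold (R, G, B), got shape {arr.shape}")
    r, g, b = arr[..., 0], arr[..., 1], arr[..., 2]
    num = 2.0 * g - r - b
    den = 2.0 * g + r + b
    out = np.divide(num, den, out=np.zeros_like(num), where=den != 0)
    return float(out) if scalar else out


@dataclass
class MaskResult:
    """Vegetation mask plus bookkeeping for downstream exclusion."""

    mask: np.ndarray
    n_vegetation: int
    excluded: bool  # True when no vegetation pixel was found

    def __iter__(self):  # allow ``mask, n, excluded = vegetation_mask(...)``
        return iter((self.mask, self.n_vegetation, self.excluded))


def vegetation_mask(
    rgb: np.ndarray,
    threshold: float = DEFAULT_VDVI_THRESHOLD,
    min_green: int = DEFAULT_MIN_GREEN,
) -> MaskResult:
    """Segment vegetation: VDVI strictly above ``threshold`` AND green >= ``min_green``.

    An empty mask sets ``excluded`` so callers can drop the plot, mirroring
    manual removal of failed plots.
    """
    arr = np.asarray(rgb)
    index = vdvi(arr)
    mask = (index > threshold) & (arr[..., 1] >= min_green)
    n = int(mask.sum())
    return MaskResult(mask=mask, n_vegetation=n, excluded=n == 0)


# ---------------------------------------------------------------------------
# geometry standardisation
# ---------------------------------------------------------------------------


def _mask_orientation(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Centroid (row, col) and principal-axis angle of a binary mask.

    The angle is measured from the column (horizontal) axis; rotating the
    image by ``-angle`` makes the principal axis horizontal.  A mask with
    isotropic second moments gets angle 0.
    """
    rows, cols = np.nonzero(mask)
    centroid = np.array([rows.mean(), cols.mean()])
    dr = rows - centroid[0]
    dc = cols - centroid[1]
    mu_rr = np.mean(dr * dr)
    mu_cc = np.mean(dc * dc)
    mu_rc = np.mean(dr * dc)
    if np.isclose(mu_rc, 0.0) and mu_cc >= mu_rr:
        return centroid, 0.0
    angle = 0.5 * np.arctan2(2.0 * mu_rc, mu_cc - mu_rr)
    return centroid, float(angle)


def standardize_geometry(
    pair: PlotImagePair,
    target_h: int,
    target_w: int,
    rotate: bool = True,
) -> PlotImagePair:
    """Centre, orient and pad/crop a plot image pair to a fixed size.

    The canopy centroid is translated to the centre of the target canvas and
    the mask's principal axis rotated to horizontal (rigid transform, nearest
    neighbour resampling so mask areas and the RGB palette are preserved).
    Off-mask RGB pixels become black; the DSM has the local ground reference
    (median of off-mask heights) subtracted and off-mask values set to 0.

    Raises ``ValueError`` on an empty mask.  Warns when the aligned canopy
    does not fit the target canvas (it is then centre-cropped).
    """
    if not pair.mask.any():
        raise ValueError(f"plot {pair.plot_id!r}: empty vegetation mask")

    centroid, angle = _mask_orientation(pair.mask)
    if not rotate:
        angle = 0.0

    # ground reference from soil (off-mask) pixels; whole plot is canopy -> 0
    soil = pair.dsm[~pair.mask]
    ground = float(np.median(soil)) if soil.size else 0.0
    dsm = (pair.dsm - ground).astype(np.float32)

    # inverse map: output pixel -> input pixel (rotation about the centroid
    # composed with centroid -> canvas-centre translation)
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, s], [-s, c]])  # output->input map: rotate by -angle
    center_out = np.array([(target_h - 1) / 2.0, (target_w - 1) / 2.0])
    offset = centroid - rot @ center_out

    def _warp(img: np.ndarray, cval: float) -> np.ndarray:
        return ndimage.affine_transform(
            img, rot, offset=offset, output_shape=(target_h, target_w),
            order=0, mode="constant", cval=cval,
        )

    new_mask = _warp(pair.mask.astype(np.uint8), 0).astype(bool)
    new_dsm = _warp(dsm, 0.0)
    new_rgb = np.stack(
        [_warp(pair.rgb[..., ch].astype(np.float32), 0.0) for ch in range(3)], axis=-1
    )

    if new_mask.sum() < 0.98 * pair.mask.sum():
        warnings.warn(
            f"plot {pair.plot_id!r}: canopy larger than target canvas after "
            "alignment; centre-cropped",
            stacklevel=2,
        )

    new_rgb[~new_mask] = 0
    new_dsm[~new_mask] = 0.0
    return PlotImagePair(
        rgb=np.clip(new_rgb, 0, 255).astype(np.uint8),
        dsm=new_dsm,
        mask=new_mask,
        plot_id=pair.plot_id,
    )


# ---------------------------------------------------------------------------
# flip augmentation
# ---------------------------------------------------------------------------

#: augmentation variants in output order
AUGMENTATIONS = ("orig", "vflip", "hflip", "vhflip")


def _flip(arr: np.ndarray, vertical: bool, horizontal: bool) -> np.ndarray:
    if vertical:
        arr = arr[::-1]
    if horizontal:
        arr = arr[:, ::-1]
    return np.ascontiguousarray(arr)


def flip_pair(pair: PlotImagePair, vertical: bool, horizontal: bool) -> PlotImagePair:
    """Apply the same up-down / left-right flips to rgb, dsm and mask."""
    return replace(
        pair,
        rgb=_flip(pair.rgb, vertical, horizontal),
        dsm=_flip(pair.dsm, vertical, horizontal),
        mask=_flip(pair.mask, vertical, horizontal),
    )


def augment(pairs: Sequence[PlotImagePair]) -> list[PlotImagePair]:
    """Four-fold flip augmentation: identity, vertical, horizontal, both.

    Output length is exactly ``4 * len(pairs)``; variants keep the source
    plot_id (trait labels are invariant under flips).
    """
    out: list[PlotImagePair] = []
    for pair in pairs:
        out.append(pair)
        out.append(flip_pair(pair, vertical=True, horizontal=False))
        out.append(flip_pair(pair, vertical=False, horizontal=True))
        out.append(flip_pair(pair, vertical=True, horizontal=True))
    return out


def augment_arrays(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip augmentation on a stacked (N, C, H, W) tensor with targets copied.

    Used on training folds; returns (4N, C, H, W) and (4N, ...) arrays in the
    same variant order as :func:`augment`.
    """
    variants = [x, x[:, :, ::-1, :], x[:, :, :, ::-1], x[:, :, ::-1, ::-1]]
    xa = np.concatenate([np.ascontiguousarray(v) for v in variants], axis=0)
    ya = np.concatenate([y, y, y, y], axis=0)
    return xa, ya


# ---------------------------------------------------------------------------
# trait normalisation
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Per-plot trait values, raw and z-score normalised.

    ``norm_mean`` / ``norm_sd`` are the statistics of the fitting rows; the
    inverse transform is exact.
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    norm_mean: pd.Series
    norm_sd: pd.Series
    fit_rows: pd.Index = field(default=None)  # type: ignore[assignment]

    def inverse(self, normalized: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        """Map z-scores back to the raw trait scale."""
        if isinstance(normalized, np.ndarray):
            normalized = pd.DataFrame(normalized, columns=self.raw.columns)
        return normalized * self.norm_sd + self.norm_mean

    @property
    def traits(self) -> list[str]:
        return list(self.raw.columns)


def normalize_traits(raw: pd.DataFrame, fit_rows: Iterable | None = None) -> TraitTable:
    """z-score normalise each trait column: mean 0, variance 1 on ``fit_rows``.

    Statistics are computed on ``fit_rows`` only (default: all rows) and the
    transform applied to every row.  Variance is the population variance
    (ddof=0) so the normalised fitting columns have variance exactly 1.

    Raises
    ------
    ZeroVarianceError
        naming the degenerate trait if a fitting column is constant.
    """
    raw = pd.DataFrame(raw).astype(float)
    fit = raw if fit_rows is None else raw.loc[list(fit_rows)]
    if len(fit) == 0:
        raise ValueError("fit_rows is empty")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0, ddof=0)
    bad = sd.index[(sd == 0) | ~np.isfinite(sd)]
    if len(bad):
        raise ZeroVarianceError(
            f"trait(s) {list(bad)} have zero variance on the fitting rows"
        )
    normalized = (raw - mean) / sd
    return TraitTable(
        raw=raw,
        normalized=normalized,
        norm_mean=mean,
        norm_sd=sd,
        fit_rows=fit.index,
    )
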