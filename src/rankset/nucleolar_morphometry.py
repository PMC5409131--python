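"""Nucleolar area morphometry from paired nuclear/protein stain channels.

The readout is the nucleolar-stain (e.g. nucleolin) area as a percentage of
the DAPI-defined nuclear area, per cell. The nuclear mask comes from an Otsu
threshold on the nuclear channel (a fixed threshold can be supplied
instead); the nucleolar mask is the set of protein-channel pixels whose
8-bit intensity lies in the inclusive band [band_low, band_high] — the
two-slider thresholding convention, default 50–100 — intersected with the
nuclear mask. Images are assumed pre-cropped to single nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .data_model import ImagePair

DEFAULT_BAND = (50, 100)


@dataclass(frozen=True)
class NclMeasurement:
    nuclear_px: int
    nucleolar_px: int
    ratio_pct: float


def nuclear_mask(
    nuclear_channel: np.ndarray, fixed_threshold: int | None = None
) -> np.ndarray:
    """Boolean nuclear mask: pixels strictly above the (Otsu) threshold."""
    nuc = np.asarray(nuclear_channel)
    if fixed_threshold is not None:
        thr = fixed_threshold
    else:
        if nuc.min() == nuc.max():
            raise ValueError("uniform nuclear channel: cannot threshold")
        thr = threshold_otsu(nuc)
    mask = nuc > thr
    if not mask.any():
        raise ValueError("empty nuclear mask")
    return mask


def ncl_ratio(
    img: ImagePair,
    band_low: int = DEFAULT_BAND[0],
    band_high: int = DEFAULT_BAND[1],
    fixed_nuclear_threshold: int | None = None,
) -> NclMeasurement:
    """Nucleolar area as a percentage of nuclear area for one cell.

    Returns pixel counts of both masks and 100 * nucleolar / nuclear.
    """
    if band_low > band_high:
        raise ValueError(f"band_low {band_low} exceeds band_high {band_high}")
    nuc_mask = nuclear_mask(img.nuclear_channel, fixed_nuclear_threshold)
    pro = img.protein_channel
    band_mask = (pro >= band_low) & (pro <= band_high)
    ncl_mask = band_mask & nuc_mask
    n_nuc = int(nuc_mask.sum())
    n_ncl = int(ncl_mask.sum())
    return NclMeasurement(
        nuclear_px=n_nuc,
        nucleolar_px=n_ncl,
        ratio_pct=100.0 * n_ncl / n_nuc,
    )


def compare_groups(ratios_a, ratios_b) -> float:
    """Relative difference of group means, in percent: 100 (mean_B - mean_A)/mean_A.

    Descriptive effect size only — group B relative to reference group A.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_a = a.mean()
    if mean_a == 0:
        raise ValueError("reference group mean is zero; relative difference undefined")
    return float(100.0 * (b.mean() - mean_a) / mean_a)
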