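"""Map normalisation, resampling and grey-level discretization.

Two discretization modes mirror the two kinds of input:

* ``zscore_binwidth`` (anatomical images): z-score normalisation over the
  normalisation mask followed by a fixed bin width (default 0.1, giving
  roughly 60 bins over the +-3 sigma bulk of a brain image);
* ``range_binwidth`` (quantitative biomarker maps): clipping to a
  physiologically reasonable value range followed by a fixed per-map bin
  width chosen so that the histogram has 60-67 bins (default: range / 64).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["DiscretizationPolicy", "preprocess_map", "default_biomarker_policies"]


@dataclass
class DiscretizationPolicy:
    """How one map is normalised and discretized before texture analysis."""

    mode: str = "zscore_binwidth"          # or "range_binwidth"
    bin_width: float = 0.1                 # in (possibly normalised) map units
    value_range: tuple[float, float] | None = None  # biomarker maps only
    target_bins: tuple[int, int] = (60, 67)

    def __post_init__(self) -> None:
        if self.mode not in ("zscore_binwidth", "range_binwidth"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.mode == "range_binwidth":
            if self.value_range is None:
                raise ValueError("range_binwidth mode requires a value_range")
            lo, hi = self.value_range
            if hi <= lo:
                raise ValueError("value_range must be increasing")
            n_bins = int(np.ceil((hi - lo) / self.bin_width))
            if not self.target_bins[0] <= n_bins <= self.target_bins[1]:
                raise ValueError(
                    f"bin width {self.bin_width} yields {n_bins} bins over {self.value_range}, "
                    f"outside the target window {self.target_bins}")

    @classmethod
    def for_range(cls, lo: float, hi: float, n_bins: int = 64) -> "DiscretizationPolicy":
        """A biomarker policy with bin width = range / n_bins."""
        return cls(mode="range_binwidth", bin_width=(hi - lo) / n_bins, value_range=(lo, hi))


def default_biomarker_policies(mti_limit: float = 1.0) -> dict[str, DiscretizationPolicy]:
    """Default value ranges and bin widths per biomarker map.

    The MTI range is symmetric; ``mti_limit`` is typically set per cohort to
    a high percentile of the observed |MTI|.
    """
    rng = DiscretizationPolicy.for_range
    return {
        "OEF": rng(0.0, 1.0),
        "CMRO2": rng(0.0, 350.0),
        "capiPO2": rng(0.0, 100.0),
        "mitoPO2": rng(0.0, 100.0),
        "CBV": rng(0.0, 0.2),
        "uCBV": rng(0.0, 0.2),
        "ADC": rng(0.0, 4e-3),
        "MVD": rng(0.0, 5000.0),
        "VSI": rng(0.0, 0.05),
        "MTI": rng(-mti_limit, mti_limit),
        "ceT1w": DiscretizationPolicy(),
        "FLAIR": DiscretizationPolicy(),
    }


def _resample(volume: np.ndarray, spacing, target: float, order: int) -> np.ndarray:
    factors = tuple(s / target for s in spacing)
    if np.allclose(factors, 1.0):
        return volume
    return ndimage.zoom(volume, factors, order=order, mode="nearest", grid_mode=False)


def preprocess_map(volume: np.ndarray, mask: np.ndarray, policy: DiscretizationPolicy,
                   spacing=(1.0, 1.0, 1.0), norm_mask: np.ndarray | None = None,
                   target_spacing_mm: float = 1.0):
    """Normalise, resample to isotropic voxels and discretize one map.

    Intensities are resampled trilinearly, masks nearest-neighbour.  Returns
    ``(disc, resampled_mask, values)``: integer grey levels (1-based inside
    the mask, 0 outside), the resampled binary mask, and the normalised /
    clipped floating-point values used for first-order statistics.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must share a shape")
    if not mask.any():
        raise ValueError("empty mask")

    if policy.mode == "zscore_binwidth":
        ref = norm_mask if norm_mask is not None else (volume != 0)
        if not np.any(ref):
            ref = np.ones_like(mask)
        mu, sd = volume[ref].mean(), volume[ref].std()
        values = (volume - mu) / (sd if sd > 0 else 1.0)
    else:
        lo, hi = policy.value_range
        values = np.clip(volume, lo, hi)

    values = _resample(values, spacing, target_spacing_mm, order=1)
    rmask = _resample(mask.astype(np.uint8), spacing, target_spacing_mm, order=0).astype(bool)
    if not rmask.any():
        raise ValueError("mask is empty after resampling")

    if policy.mode == "zscore_binwidth":
        anchor = values[rmask].min()
    else:
        anchor = policy.value_range[0]
    disc = np.zeros(values.shape, dtype=np.int32)
    inside = values[rmask]
    levels = np.floor((inside - anchor) / policy.bin_width).astype(np.int32) + 1
    # the upper range edge falls into the top bin, not a new one
    levels = np.clip(levels, 1, None)
    top = int(np.ceil((inside.max() - anchor) / policy.bin_width)) if inside.max() > anchor else 1
    levels = np.minimum(levels, max(top, 1))
    disc[rmask] = levels
    return disc, rmask, values
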