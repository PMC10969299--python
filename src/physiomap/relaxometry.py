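"""Transverse relaxation-rate mapping and two-point diffusion imaging.

R2* (gradient-echo) and R2 (spin-echo) maps are obtained from multi-echo
series by a log-linear mono-exponential fit, and the apparent diffusion
coefficient (ADC) from a two-point DWI acquisition (b = 0 and 1000 s/mm^2) via

    ADC = -(1/b) * ln(S / S0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid

__all__ = ["EchoSeries", "RateMap", "DiffusionPair", "fit_rate_map", "compute_adc"]


@dataclass
class EchoSeries:
    """A multi-echo acquisition: one volume per echo time.

    ``echo_times_ms`` must be strictly increasing with at least three echoes;
    ``kind`` is ``"GE"`` or ``"SE"``.
    """

    volumes: list[VolumeGrid]
    echo_times_ms: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        self.echo_times_ms = np.asarray(self.echo_times_ms, dtype=float)
        if len(self.volumes) != len(self.echo_times_ms):
            raise ValueError("one volume per echo time required")
        if len(self.echo_times_ms) < 3:
            raise ValueError("at least 3 echoes required")
        if np.any(np.diff(self.echo_times_ms) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if np.any(self.echo_times_ms < 0):
            raise ValueError("echo times must be nonnegative")
        if self.kind not in ("GE", "SE"):
            raise ValueError(f"kind must be GE or SE, got {self.kind!r}")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError("all echo volumes must share a shape")

    @property
    def stack(self) -> np.ndarray:
        """Signal stacked as (x, y, z, echo)."""
        return np.stack([v.data for v in self.volumes], axis=-1)


@dataclass
class RateMap:
    """A relaxation-rate map in s^-1 with a validity mask."""

    rate: VolumeGrid
    valid: np.ndarray
    kind: str = "R2"
    s0: np.ndarray | None = None


@dataclass
class DiffusionPair:
    """b=0 and b=1000 s/mm^2 volumes of a two-point DWI acquisition."""

    s0: VolumeGrid
    s1000: VolumeGrid
    b_values: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self) -> None:
        if tuple(self.b_values) != (0.0, 1000.0):
            raise ValueError("two-point protocol requires b values {0, 1000} s/mm^2")
        if self.s0.shape != self.s1000.shape:
            raise ValueError("b=0 and b=1000 volumes must share geometry")


def fit_rate_map(series: EchoSeries, mask: np.ndarray | None = None) -> RateMap:
    """Fit a mono-exponential decay rate per voxel by log-linear least squares.

    The slope of -ln S(TE) versus TE (TE converted to seconds) is estimated by
    ordinary least squares, which is exact on noise-free mono-exponential
    signals.  Voxels with a nonpositive signal at any echo are flagged invalid
    and assigned rate 0.
    """
    stack = series.stack
    if mask is None:
        mask = np.ones(stack.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    te_s = series.echo_times_ms * 1e-3

    sig = stack[mask]  # (n, e)
    valid = np.all(sig > 0, axis=1)
    logs = np.where(sig > 0, np.log(np.maximum(sig, 1e-300)), 0.0)

    # closed-form simple linear regression of log-signal on TE
    te_c = te_s - te_s.mean()
    denom = float(np.sum(te_c**2))
    slope = logs @ te_c / denom
    rate_vals = np.where(valid, -slope, 0.0)
    intercept = logs.mean(axis=1) - slope * te_s.mean()
    s0_vals = np.where(valid, np.exp(intercept), 0.0)

    rate = np.zeros(stack.shape[:3])
    rate[mask] = rate_vals
    valid_map = np.zeros(stack.shape[:3], dtype=bool)
    valid_map[mask] = valid
    s0_map = np.zeros(stack.shape[:3])
    s0_map[mask] = s0_vals

    geom = series.volumes[0]
    kind = "R2*" if series.kind == "GE" else "R2"
    return RateMap(geom.like(rate, units="s^-1", kind=kind), valid_map, kind=kind, s0=s0_map)


def compute_adc(pair: DiffusionPair, mask: np.ndarray | None = None) -> VolumeGrid:
    """Two-point ADC map in mm^2/s.

    Degenerate voxels (S <= 0 or S > S0) are clamped to ADC = 0 and flagged in
    the ``invalid`` entry of the output metadata, keeping downstream masks
    usable.
    """
    s0 = pair.s0.data
    s = pair.s1000.data
    if mask is None:
        mask = np.ones(s0.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if np.any(s0[mask] <= 0):
        raise ValueError("S0 must be positive inside the mask")

    b = pair.b_values[1]
    ratio = np.ones_like(s0)
    good = mask & (s > 0) & (s <= s0)
    ratio[good] = s[good] / s0[good]
    adc = np.zeros_like(s0)
    adc[good] = -np.log(ratio[good]) / b
    invalid = mask & ~good
    return pair.s0.like(adc, units="mm^2/s", invalid=invalid)
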