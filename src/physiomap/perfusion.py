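"""Dynamic susceptibility contrast (DSC) perfusion processing.

The stages are: conversion of the dynamic signal to relaxation-rate change
curves dR2(t), gamma-variate fitting of the first bolus passage per voxel,
automatic arterial-input-function (AIF) selection, and computation of relative
CBV (area ratio to the AIF), relative CBF (block-circulant SVD deconvolution)
and, from spin-echo data with its own AIF, the microvascular CBV.

Hybrid gradient-echo/spin-echo (GESE) acquisitions carry both echo kinds per
frame and are split into separate GE and SE series before processing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import circulant

from .bolus import gamma_variate, gamma_variate_area

__all__ = [
    "DynamicSeries",
    "ConcentrationCurve",
    "DeltaR2Curves",
    "GammaFit",
    "AifResult",
    "split_gese",
    "merge_gese",
    "signal_to_delta_r2",
    "fit_first_pass",
    "fit_first_pass_many",
    "select_aif",
    "first_pass_area",
    "compute_cbv",
    "compute_cbf",
    "compute_micro_cbv",
]


@dataclass
class DynamicSeries:
    """4-D DSC signal with timing and echo metadata.

    ``signal`` is (x, y, z, t) for a plain series, or (x, y, z, t, 2) for a
    hybrid GESE series whose last axis holds the GE and SE echo of each frame
    (``echo_time_ms`` is then a (GE, SE) pair).  ``baseline_window`` is the
    half-open frame range acquired before bolus arrival.
    """

    signal: np.ndarray
    frame_interval: float
    echo_time_ms: float | tuple[float, float]
    echo_kind: str = "GE"
    baseline_window: tuple[int, int] = (0, 5)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        expected_ndim = 5 if self.echo_kind == "hybrid" else 4
        if self.signal.ndim != expected_ndim:
            raise ValueError(
                f"{self.echo_kind} series expects {expected_ndim}-D signal, got {self.signal.ndim}-D"
            )
        if self.echo_kind == "hybrid":
            if self.signal.shape[-1] != 2 or np.ndim(self.echo_time_ms) != 1:
                raise ValueError("hybrid series needs a trailing echo axis of size 2 "
                                 "and a (GE, SE) echo_time_ms pair")
        if self.n_frames < 40:
            raise ValueError("DSC series requires at least 40 frames")
        b0, b1 = self.baseline_window
        if b1 - b0 < 5:
            raise ValueError("baseline window must span at least 5 pre-bolus frames")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[3]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class ConcentrationCurve:
    """A single dR2(t) curve in s^-1 on a time base in seconds."""

    times: np.ndarray
    delta_r2: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.delta_r2 = np.asarray(self.delta_r2, dtype=float)
        if self.times.shape != self.delta_r2.shape:
            raise ValueError("times and delta_r2 must have equal length")


@dataclass
class DeltaR2Curves:
    """dR2(t) for a collection of voxels: ``curves`` is (n_voxels, n_frames)."""

    times: np.ndarray
    curves: np.ndarray
    invalid: np.ndarray  # per-voxel flag: nonpositive signal encountered

    def curve(self, i: int) -> ConcentrationCurve:
        return ConcentrationCurve(self.times, self.curves[i])


@dataclass
class GammaFit:
    """Fitted first-pass gamma-variate parameters for one voxel."""

    K: float
    t0: float
    alpha: float
    b: float
    rmse: float = 0.0
    valid: bool = True

    @property
    def peak_time(self) -> float:
        return self.t0 + self.alpha * self.b

    @property
    def peak_value(self) -> float:
        return float(self.K * (self.alpha * self.b) ** self.alpha * np.exp(-self.alpha))

    def __call__(self, t) -> np.ndarray:
        return gamma_variate(t, self.K, self.t0, self.alpha, self.b)


@dataclass
class AifResult:
    """Averaged arterial input function and the provenance of its voxels."""

    curve: ConcentrationCurve
    fit: GammaFit
    voxel_indices: np.ndarray
    scores: np.ndarray

    @property
    def area(self) -> float:
        return first_pass_area(self.fit)


# ---------------------------------------------------------------------------
# hybrid splitting

def split_gese(series: DynamicSeries) -> tuple[DynamicSeries, DynamicSeries]:
    """Separate a hybrid GESE series into a GE series and an SE series.

    Frame counts and timing are preserved; the per-frame echo tag (the
    trailing axis) selects the destination series.
    """
    if series.echo_kind != "hybrid":
        raise ValueError("split_gese requires a hybrid GESE series")
    te_ge, te_se = series.echo_time_ms
    common = dict(frame_interval=series.frame_interval,
                  baseline_window=series.baseline_window,
                  voxel_size_mm=series.voxel_size_mm)
    ge = DynamicSeries(series.signal[..., 0], echo_time_ms=float(te_ge), echo_kind="GE", **common)
    se = DynamicSeries(series.signal[..., 1], echo_time_ms=float(te_se), echo_kind="SE", **common)
    return ge, se


def merge_gese(ge: DynamicSeries, se: DynamicSeries) -> DynamicSeries:
    """Interleave separate GE and SE series back into one hybrid series."""
    if ge.signal.shape != se.signal.shape:
        raise ValueError("GE and SE series must share shape")
    sig = np.stack([ge.signal, se.signal], axis=-1)
    return DynamicSeries(sig, ge.frame_interval, (ge.echo_time_ms, se.echo_time_ms),
                         echo_kind="hybrid", baseline_window=ge.baseline_window,
                         voxel_size_mm=ge.voxel_size_mm)


# ---------------------------------------------------------------------------
# signal -> dR2

def signal_to_delta_r2(series: DynamicSeries, mask: np.ndarray | None = None,
                       baseline_window: tuple[int, int] | None = None) -> DeltaR2Curves:
    """Convert DSC signal to dR2(t) = -(1/TE) * ln(S(t)/S_baseline).

    TE is taken in seconds.  Voxels whose signal is nonpositive at any frame
    (or whose baseline mean is nonpositive) are flagged; their offending
    frames are evaluated at a tiny positive floor rather than NaN.
    """
    if series.echo_kind == "hybrid":
        raise ValueError("split the hybrid series before dR2 conversion")
    if mask is None:
        mask = np.ones(series.signal.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    b0, b1 = baseline_window if baseline_window is not None else series.baseline_window

    sig = series.signal[mask]  # (n, t)
    base = sig[:, b0:b1].mean(axis=1)
    bad_base = base <= 0
    base = np.where(bad_base, 1.0, base)
    ratio = sig / base[:, None]
    bad_frames = ratio <= 0
    ratio = np.where(bad_frames, 1e-12, ratio)
    te_s = float(series.echo_time_ms) * 1e-3
    dr2 = -np.log(ratio) / te_s
    invalid = bad_base | bad_frames.any(axis=1)
    return DeltaR2Curves(series.times, dr2, invalid)


# ---------------------------------------------------------------------------
# first-pass gamma-variate fitting
#
# Variable projection: for a trial arrival t0 the log-model
#   ln g = ln K + alpha*ln(t-t0) - (t-t0)/b
# is linear in (ln K, alpha, 1/b); the 1-D profile over t0 is minimised by
# golden-section search.  Weights y^2 make the log-domain least squares
# approximate the linear-domain one; on noise-free gamma data the fit is exact.

_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _first_pass_windows(curves: np.ndarray, frac_start: float = 0.05,
                        frac_end: float = 0.2) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-curve (start, end] frame indices of the first passage.

    start: the frame after the last sub-threshold frame before the peak,
    where the threshold is the larger of ``frac_start`` of the peak and four
    baseline noise standard deviations (so pre-bolus noise spikes cannot pull
    the window start early); end: first frame after the peak falling below
    ``frac_end`` of the peak (recirculation exclusion).  Returns
    (start_idx, end_idx, peak_idx); end is exclusive.
    """
    n, t = curves.shape
    frame_ix = np.arange(t)[None, :]
    peak_idx = np.argmax(curves, axis=1)
    ymax = curves[np.arange(n), peak_idx]
    base_sd = curves[:, : min(5, t)].std(axis=1)
    thresh_start = np.maximum(frac_start * ymax, 4.0 * base_sd)[:, None]
    below_before_peak = (curves < thresh_start) & (frame_ix <= peak_idx[:, None])
    last_below = np.where(below_before_peak, frame_ix, -1).max(axis=1)
    start_idx = np.minimum(last_below + 1, peak_idx)
    # first frame strictly after the peak below the end threshold
    below_end = curves < frac_end * ymax[:, None]
    after_peak = frame_ix > peak_idx[:, None]
    cut = below_end & after_peak
    has_cut = cut.any(axis=1)
    end_idx = np.where(has_cut, np.argmax(cut, axis=1), t)
    return start_idx, end_idx, peak_idx


def _loglin_objective(curves: np.ndarray, times: np.ndarray, t0: np.ndarray,
                      in_window: np.ndarray):
    """Weighted log-domain SSE and linear parameters for per-voxel trial t0."""
    dt = times[None, :] - t0[:, None]
    usable = in_window & (dt > 1e-9) & (curves > 0)
    w = np.where(usable, curves**2, 0.0)
    logy = np.where(usable, np.log(np.where(usable, curves, 1.0)), 0.0)
    logdt = np.where(usable, np.log(np.where(usable, dt, 1.0)), 0.0)
    dtc = np.where(usable, dt, 0.0)
    # basis: [1, log(dt), -dt]; coefficients [ln K, alpha, 1/b]
    B = np.stack([np.ones_like(dtc), logdt, -dtc], axis=-1)  # (n, t, 3)
    Bw = B * w[..., None]
    A = np.einsum("ntk,ntl->nkl", Bw, B)
    rhs = np.einsum("ntk,nt->nk", Bw, logy)
    # regularise voxels with a singular normal matrix (too few usable frames)
    ok = usable.sum(axis=1) >= 4
    A = A + (~ok)[:, None, None] * np.eye(3)[None]
    try:
        coef = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        coef = (np.linalg.pinv(A) @ rhs[..., None])[..., 0]
    resid = logy - np.einsum("ntk,nk->nt", B, coef)
    sse = np.einsum("nt,nt->n", w, resid**2)
    sse = np.where(ok, sse, np.inf)
    return sse, coef, ok


def fit_first_pass_many(curves: np.ndarray, times: np.ndarray,
                        n_iter: int = 60) -> list[GammaFit]:
    """Vectorised first-pass gamma-variate fit of many curves on one time base.

    Curves with no detectable peak (peak below four baseline noise standard
    deviations, or too few usable frames) come back flagged invalid.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=float))
    times = np.asarray(times, dtype=float)
    n, t = curves.shape
    dt_frame = float(times[1] - times[0]) if t > 1 else 1.0

    start_idx, end_idx, peak_idx = _first_pass_windows(curves)
    ymax = curves[np.arange(n), peak_idx]

    # noise estimate from the pre-bolus portion of each curve
    pre = np.arange(t)[None, :] < np.maximum(start_idx, 2)[:, None]
    base_sd = np.sqrt(
        np.sum(np.where(pre, curves, 0.0) ** 2, axis=1) / np.maximum(pre.sum(axis=1), 1)
    )
    detectable = ymax > np.maximum(4.0 * base_sd, 1e-9)

    frame_ix = np.arange(t)[None, :]
    in_window = (frame_ix >= start_idx[:, None]) & (frame_ix < end_idx[:, None])

    t_start = times[np.minimum(start_idx, t - 1)]
    lo = np.maximum(t_start - 4.0 * dt_frame, times[0] - 2.0 * dt_frame)
    hi = t_start - 1e-6 * dt_frame

    # golden-section search on the profile objective over t0 (one vectorised
    # objective evaluation per iteration)
    a, b = lo.copy(), hi.copy()
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, _, _ = _loglin_objective(curves, times, c, in_window)
    fd, _, _ = _loglin_objective(curves, times, d, in_window)
    for _ in range(n_iter):
        take_c = fc < fd  # minimum lies in [a, d]
        c_old, d_old, fc_old, fd_old = c, d, fc, fd
        b = np.where(take_c, d_old, b)
        a = np.where(take_c, a, c_old)
        c = np.where(take_c, b - _GOLDEN * (b - a), d_old)
        d = np.where(take_c, c_old, a + _GOLDEN * (b - a))
        x_eval = np.where(take_c, c, d)
        f_eval, _, _ = _loglin_objective(curves, times, x_eval, in_window)
        fc = np.where(take_c, f_eval, fd_old)
        fd = np.where(take_c, fc_old, f_eval)
    t0 = (a + b) / 2.0
    sse, coef, ok = _loglin_objective(curves, times, t0, in_window)

    K = np.exp(coef[:, 0])
    alpha = coef[:, 1]
    binv = coef[:, 2]
    good = detectable & ok & (alpha > 0) & (binv > 0) & np.isfinite(sse)
    bvals = np.where(binv > 0, 1.0 / np.where(binv > 0, binv, 1.0), np.nan)

    fits = []
    for i in range(n):
        if not good[i]:
            fits.append(GammaFit(0.0, 0.0, 1.0, 1.0, rmse=np.inf, valid=False))
            continue
        model = gamma_variate(times, K[i], t0[i], alpha[i], bvals[i])
        w = in_window[i]
        rmse = float(np.sqrt(np.mean((model[w] - curves[i][w]) ** 2)))
        fits.append(GammaFit(float(K[i]), float(t0[i]), float(alpha[i]), float(bvals[i]),
                             rmse=rmse, valid=True))
    return fits


def fit_first_pass(curve: ConcentrationCurve) -> GammaFit:
    """Fit the first bolus passage of one dR2(t) curve (see the batched fitter)."""
    return fit_first_pass_many(curve.delta_r2[None, :], curve.times)[0]


def first_pass_area(fit: GammaFit) -> float:
    """Area under the fitted first-pass curve (analytic gamma integral)."""
    if not fit.valid:
        return 0.0
    return float(gamma_variate_area(fit.K, fit.t0, fit.alpha, fit.b))


# ---------------------------------------------------------------------------
# AIF selection

def select_aif(curves: DeltaR2Curves, fits: list[GammaFit] | None = None,
               top_n: int = 10, min_voxels: int = 5) -> AifResult:
    """Select arterial voxels and average their fitted first-pass curves.

    Candidates are all voxels with a valid first-pass fit; each is scored by
    the rank sum of early arrival (low t0), high fitted peak, and narrow width
    (low alpha*b).  The ``top_n`` best-ranked voxels are averaged and the
    average refitted.  Deterministic for fixed input (ties broken by index).
    """
    if fits is None:
        fits = fit_first_pass_many(curves.curves, curves.times)
    valid = np.array([f.valid for f in fits]) & ~np.asarray(curves.invalid, dtype=bool)
    idx = np.flatnonzero(valid)
    if idx.size < max(min_voxels, 1):
        raise ValueError(f"AIF selection requires at least {min_voxels} acceptable voxels, "
                         f"got {idx.size}")
    t0 = np.array([fits[i].t0 for i in idx])
    peak = np.array([fits[i].peak_value for i in idx])
    width = np.array([fits[i].alpha * fits[i].b for i in idx])

    def _rank(x):
        order = np.argsort(x, kind="stable")
        r = np.empty_like(order)
        r[order] = np.arange(len(x))
        return r

    score = _rank(t0) + _rank(-peak) + _rank(width)
    take = idx[np.argsort(score, kind="stable")[: min(top_n, idx.size)]]
    fitted = np.stack([fits[i](curves.times) for i in take])
    mean_curve = ConcentrationCurve(curves.times, fitted.mean(axis=0))
    mean_fit = fit_first_pass(mean_curve)
    return AifResult(mean_curve, mean_fit, take, score[np.searchsorted(idx, take)])


# ---------------------------------------------------------------------------
# CBV / CBF / microvascular CBV

def compute_cbv(curve_fit: GammaFit, aif: AifResult, scale: float = 1.0) -> float:
    """Relative CBV as the tissue/AIF first-pass area ratio (x ``scale``)."""
    aif_area = aif.area
    if aif_area <= 0:
        raise ValueError("AIF first-pass integral must be positive")
    return scale * first_pass_area(curve_fit) / aif_area


def compute_micro_cbv(se_curve_fit: GammaFit, se_aif: AifResult, scale: float = 1.0) -> float:
    """Microvascular CBV: the CBV contract applied to spin-echo data with its own AIF."""
    return compute_cbv(se_curve_fit, se_aif, scale=scale)


def _circulant_deconv(aif_curve: np.ndarray, lam: float) -> np.ndarray:
    """Truncated-SVD pseudo-inverse of the zero-padded circulant AIF matrix."""
    t = aif_curve.size
    padded = np.concatenate([aif_curve, np.zeros(t)])
    A = circulant(padded)
    U, s, Vt = np.linalg.svd(A)
    if s[0] <= 0:
        raise ValueError("singular AIF matrix")
    keep = s > lam * s[0]
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return (Vt.T * s_inv) @ U.T


def compute_cbf(tissue_curves: np.ndarray, aif: AifResult, frame_interval: float,
                lam: float = 0.2, flow_units_scale: float = 6000.0) -> np.ndarray:
    """Relative CBF by block-circulant SVD deconvolution.

    The tissue curves are deconvolved by the AIF (zero-padded circulant
    formulation, singular values truncated below ``lam`` times the largest);
    CBF is the residue-function maximum per unit frame, scaled by
    ``flow_units_scale`` (6000 converts fraction/s to mL/100g/min on the
    relative scale).  ``lam=1`` truncates every singular value and yields 0.
    """
    curves = np.atleast_2d(np.asarray(tissue_curves, dtype=float))
    aif_c = np.asarray(aif.curve.delta_r2, dtype=float)
    Ainv = _circulant_deconv(aif_c, lam)
    t = aif_c.size
    padded = np.concatenate([curves, np.zeros_like(curves)], axis=1)
    residue = padded @ Ainv.T
    rmax = residue[:, :t].max(axis=1)
    cbf = np.maximum(rmax, 0.0) / frame_interval * flow_units_scale
    return cbf if tissue_curves.ndim > 1 else float(cbf[0])
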