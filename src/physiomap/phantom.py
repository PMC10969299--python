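"""Synthetic brain/tumor phantoms and forward-simulated raw MRI.

The generator emulates a two-class glioma cohort whose classes differ in
oxygen metabolism and neovascularization: IDH-wildtype tumors are modelled as
hypoxic (high OEF, high CMRO2, low tissue PO2) and strongly neovascularized
(high CBV and microvascular CBV, arteriole-dominated clockwise hysteresis
loops), IDH-mutant tumors as better oxygenated with weaker vascular
signatures and counter-clockwise loops.  Cohorts are drawn with the default
IDH-wildtype prevalence of 0.74.

Two acquisition protocols are emulated: ``site_A_separate`` acquires separate
GE-DSC and SE-DSC series (60 frames, single dose), ``site_B_hybrid`` a single
interleaved GESE-DSC series (80 frames, double dose, different TR/TE).

Forward model per voxel:

* multi-echo signal  S(TE) = S0 exp(-TE * R2*) (GE) or S0 exp(-TE * R2) (SE),
  with R2* = R2 + k * CBV * OEF (the qBOLD static-dephasing offset);
* DSC rate change  dR2(t) = dose * A * CBV * g1(t - t0) for GE and
  dose * A * uCBV * g1(t - t0 - s) for SE, where g1 is a unit-area
  gamma-variate whose width encodes the mean transit time CBV/CBF and the
  temporal shift s (default one frame) is signed by the loop orientation so
  the hysteresis loop closes clockwise (+1) or counter-clockwise (-1);
* two-point DWI  S(b) = S0 exp(-b * ADC);
* ceT1w / FLAIR as smooth contrast-weighted composites of the ground truth.

A designated arterial region (earliest arrival, unit blood volume, narrowest
transit) provides the AIF ground truth; its first-pass area is the
normalisation that makes downstream relative CBV recover the simulated
blood-volume fraction exactly in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .bolus import unit_area_gamma, gamma_variate_peak_value, gamma_variate_area
from .constants import PhysioConstants
from .grid import VolumeGrid
from .relaxometry import DiffusionPair, EchoSeries
from .perfusion import DynamicSeries, merge_gese
from . import vam

__all__ = [
    "FieldStats", "ClassEffect", "ClassEffectModel", "default_class_effects",
    "ProtocolTiming", "SITE_A", "SITE_B", "PROTOCOLS",
    "PhantomSpec", "GroundTruthMaps", "Phantom", "PatientBundle",
    "make_phantom", "simulate_echo_series", "simulate_dsc", "simulate_dwi",
    "simulate_anatomical", "simulate_patient", "simulate_cohort",
    "GE_ECHO_TIMES_MS", "SE_ECHO_TIMES_MS",
]

LABELS = ("IDHwt", "IDHmut")

#: area scale of the dR2 bolus response, s^-1 * s per unit blood-volume fraction
BOLUS_AMPLITUDE = 120.0
#: gamma-variate shape parameter used by the forward model
BOLUS_ALPHA = 3.0

GE_ECHO_TIMES_MS = (4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0)
SE_ECHO_TIMES_MS = (20.0, 40.0, 60.0, 80.0, 100.0)


@dataclass(frozen=True)
class FieldStats:
    """Mean and standard deviation of a ground-truth field within a compartment."""
    mean: float
    sd: float


@dataclass(frozen=True)
class ClassEffect:
    """Tissue-compartment distributions for one class (or normal brain)."""

    oef: FieldStats
    cbv: FieldStats
    cbf: FieldStats            # mL/100g/min
    adc: FieldStats            # mm^2/s
    micro_cbv: FieldStats
    loop_orientation: int = 1  # +1 clockwise (arteriole), -1 counter-clockwise


@dataclass(frozen=True)
class ClassEffectModel:
    """Class-conditional tumor distributions plus cohort prevalence."""

    idhwt: ClassEffect
    idhmut: ClassEffect
    normal: ClassEffect
    prevalence_idhwt: float = 0.74

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_idhwt <= 1.0:
            raise ValueError("prevalence must lie in (0, 1]")

    def for_label(self, label: str) -> ClassEffect:
        if label == "IDHwt":
            return self.idhwt
        if label == "IDHmut":
            return self.idhmut
        raise ValueError(f"unknown class label {label!r}")


def default_class_effects(effect_scale: float = 1.0) -> ClassEffectModel:
    """The study conditions: hypoxic/neovascularized IDHwt vs oxygenated IDHmut.

    ``effect_scale`` interpolates every tumor-class mean toward the midpoint
    of the two classes; 0 removes the class contrast entirely (a null
    configuration for specificity checks) while leaving within-class spread
    untouched.
    """
    normal = ClassEffect(
        oef=FieldStats(0.35, 0.02), cbv=FieldStats(0.030, 0.003),
        cbf=FieldStats(50.0, 4.0), adc=FieldStats(0.8e-3, 0.05e-3),
        micro_cbv=FieldStats(0.012, 0.0015), loop_orientation=1,
    )
    idhwt = ClassEffect(
        oef=FieldStats(0.60, 0.05), cbv=FieldStats(0.060, 0.006),
        cbf=FieldStats(70.0, 6.0), adc=FieldStats(1.0e-3, 0.10e-3),
        micro_cbv=FieldStats(0.024, 0.003), loop_orientation=1,
    )
    idhmut = ClassEffect(
        oef=FieldStats(0.38, 0.05), cbv=FieldStats(0.040, 0.005),
        cbf=FieldStats(55.0, 5.0), adc=FieldStats(1.3e-3, 0.12e-3),
        micro_cbv=FieldStats(0.013, 0.002), loop_orientation=-1,
    )
    if effect_scale != 1.0:
        def blend(a: ClassEffect, b: ClassEffect, sign: float) -> ClassEffect:
            out = {}
            for name in ("oef", "cbv", "cbf", "adc", "micro_cbv"):
                fa: FieldStats = getattr(a, name)
                fb: FieldStats = getattr(b, name)
                mid = 0.5 * (fa.mean + fb.mean)
                out[name] = FieldStats(mid + effect_scale * (fa.mean - mid), fa.sd)
            orient = a.loop_orientation if effect_scale > 0 else 1
            return ClassEffect(loop_orientation=orient, **out)
        idhwt, idhmut = blend(idhwt, idhmut, +1), blend(idhmut, idhwt, -1)
    return ClassEffectModel(idhwt=idhwt, idhmut=idhmut, normal=normal)


@dataclass(frozen=True)
class ProtocolTiming:
    """Acquisition timing of one site's DSC protocol."""

    name: str
    n_frames: int
    frame_interval: float   # s
    te_ge_ms: float
    te_se_ms: float
    dose_scale: float
    baseline_frames: int
    arrival_s: float        # tissue bolus arrival


SITE_A = ProtocolTiming("site_A_separate", 60, 1.0, 30.0, 80.0, 1.0, 10, 15.0)
SITE_B = ProtocolTiming("site_B_hybrid", 80, 1.5, 20.0, 60.0, 2.0, 8, 18.0)
PROTOCOLS = {p.name: p for p in (SITE_A, SITE_B)}


@dataclass
class PhantomSpec:
    """Geometry, class label, protocol and seed of one synthetic patient."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    tumor_center: tuple[float, float, float] | None = None
    tumor_radii: tuple[float, float, float] = (10.0, 12.0, 9.0)
    class_label: str = "IDHwt"
    seed: int = 0
    protocol: str = "site_A_separate"

    def __post_init__(self) -> None:
        if self.class_label not in LABELS:
            raise ValueError(f"class_label must be one of {LABELS}")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {tuple(PROTOCOLS)}")

    @property
    def timing(self) -> ProtocolTiming:
        return PROTOCOLS[self.protocol]


@dataclass
class GroundTruthMaps:
    """Per-voxel physiological ground truth of one phantom."""

    oef: np.ndarray
    cbv: np.ndarray
    cbf: np.ndarray
    adc: np.ndarray
    micro_cbv: np.ndarray
    r2: np.ndarray
    s0: np.ndarray
    loop_orientation: np.ndarray
    mvd: np.ndarray
    vsi: np.ndarray
    voxel_size_mm: float = 1.0

    def r2star(self, consts: PhysioConstants = PhysioConstants()) -> np.ndarray:
        """R2* implied by the qBOLD forward model, R2 + k * CBV * OEF."""
        return self.r2 + consts.k * self.cbv * self.oef


@dataclass
class Phantom:
    spec: PhantomSpec
    gt: GroundTruthMaps
    brain_mask: np.ndarray
    tumor_mask: np.ndarray
    arterial_mask: np.ndarray


@dataclass
class PatientBundle:
    """Raw simulated MRI of one synthetic patient plus masks and label."""

    pid: str
    label: str
    phantom: Phantom
    ge_echo: EchoSeries
    se_echo: EchoSeries
    dwi: DiffusionPair
    cet1w: VolumeGrid
    flair: VolumeGrid
    dsc: dict  # {"ge":..., "se":...} or {"hybrid":...}


# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _smooth_field(shape, rng, sigma: float = 2.0) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma)


def _fill(out: np.ndarray, mask: np.ndarray, stats: FieldStats, fld: np.ndarray,
          lo: float, hi: float) -> None:
    """Write a compartment: smooth texture renormalised to exact (mean, sd)."""
    vals = fld[mask]
    sd = vals.std()
    if stats.sd > 0 and sd > 0 and vals.size > 1:
        vals = (vals - vals.mean()) / sd
        out[mask] = stats.mean + stats.sd * vals
    else:
        out[mask] = stats.mean
    out[mask] = np.clip(out[mask], lo, hi)


_FIELD_RANGES = {
    "oef": (1e-3, 1.0),
    "cbv": (1e-4, 0.2),
    "cbf": (1.0, 400.0),
    "adc": (1e-5, 4e-3),
    "micro_cbv": (1e-5, 0.2),
}


def make_phantom(spec: PhantomSpec, effects: ClassEffectModel | None = None) -> Phantom:
    """Build ground-truth maps and masks for one synthetic patient.

    Maps are drawn from the class-conditional compartment distributions with
    smooth spatial texture; within each compartment the sample mean and
    standard deviation match the configured values exactly.  The tumor
    ellipsoid must lie fully inside the brain mask.
    """
    effects = effects or default_class_effects()
    shape = tuple(int(s) for s in spec.grid_shape)
    rng = np.random.default_rng(spec.seed)

    center = tuple((s - 1) / 2.0 for s in shape)
    brain_radii = tuple(0.45 * s for s in shape)
    brain = _ellipsoid_mask(shape, center, brain_radii)

    tcenter = spec.tumor_center or tuple(c + 0.08 * s for c, s in zip(center, shape))
    for c, r, s in zip(tcenter, spec.tumor_radii, shape):
        if c - r < 0 or c + r > s - 1:
            raise ValueError("tumor ellipsoid extends outside the grid")
    tumor = _ellipsoid_mask(shape, tcenter, spec.tumor_radii)
    if np.any(tumor & ~brain):
        raise ValueError("tumor ellipsoid must lie fully inside the brain mask")

    # arterial reference region: small sphere, displaced from the tumor
    art_center = (center[0], center[1] - 0.30 * shape[1], center[2])
    art_r = max(2.0, 0.04 * min(shape))
    arterial = _ellipsoid_mask(shape, art_center, (art_r,) * 3) & brain & ~tumor

    tumor_effect = effects.for_label(spec.class_label)
    normal = brain & ~tumor  # arterial overrides applied after the fill

    maps = {}
    for name, (lo, hi) in _FIELD_RANGES.items():
        out = np.zeros(shape)
        fld = _smooth_field(shape, rng)
        _fill(out, normal, getattr(effects.normal, name), fld, lo, hi)
        _fill(out, tumor, getattr(tumor_effect, name), fld, lo, hi)
        maps[name] = out

    # arterial voxels: unit blood volume, fast transit
    maps["cbv"][arterial] = 1.0
    maps["micro_cbv"][arterial] = 1.0
    maps["cbf"][arterial] = 2000.0

    r2 = np.where(brain, 12.0, 0.0)
    s0 = np.where(brain, 500.0, 0.0)
    orient = np.where(tumor, tumor_effect.loop_orientation, effects.normal.loop_orientation)
    orient = np.where(brain, orient, 0).astype(int)

    # implied microvascular geometry (unit dose, forward-model peak ratio)
    b_map = _transit_scale(maps["cbv"], maps["cbf"])
    peak_shape = gamma_variate_peak_value(
        1.0 / (6.0 * b_map**(BOLUS_ALPHA + 1.0)), BOLUS_ALPHA, b_map)
    ge_peak = BOLUS_AMPLITUDE * maps["cbv"] * peak_shape
    se_peak = BOLUS_AMPLITUDE * maps["micro_cbv"] * peak_shape
    qmax_gt = np.where(se_peak > 0, ge_peak / np.maximum(se_peak, 1e-30) ** 1.5, 0.0)
    mvd, _ = vam.compute_mvd(qmax_gt, maps["cbv"], maps["adc"])
    vsi, _ = vam.compute_vsi(maps["cbv"], maps["adc"], qmax_gt)

    gt = GroundTruthMaps(oef=maps["oef"], cbv=maps["cbv"], cbf=maps["cbf"],
                         adc=maps["adc"], micro_cbv=maps["micro_cbv"], r2=r2, s0=s0,
                         loop_orientation=orient, mvd=np.where(brain, mvd, 0.0),
                         vsi=np.where(brain, vsi, 0.0), voxel_size_mm=spec.voxel_size_mm)
    return Phantom(spec, gt, brain, tumor, arterial)


def _transit_scale(cbv: np.ndarray, cbf: np.ndarray) -> np.ndarray:
    """Gamma-variate scale b from the mean transit time CBV / CBF.

    CBF in mL/100g/min converts to a fractional rate via /6000; the mean
    first-pass transit (alpha+1)*b is set equal to the MTT.
    """
    mtt = np.where(cbf > 0, cbv / np.maximum(cbf / 6000.0, 1e-9), 1.0)
    return np.clip(mtt, 0.5, 20.0) / (BOLUS_ALPHA + 1.0)


def _add_noise(signal: np.ndarray, sd_abs: np.ndarray | float, rng, rician: bool):
    if np.all(np.asarray(sd_abs) == 0):
        return signal
    n1 = rng.standard_normal(signal.shape) * sd_abs
    if rician:
        n2 = rng.standard_normal(signal.shape) * sd_abs
        return np.sqrt((signal + n1) ** 2 + n2**2)
    return signal + n1


def simulate_echo_series(gt: GroundTruthMaps, echo_times_ms, kind: str,
                         noise_sd: float = 0.0, rng=None, rician: bool = False,
                         consts: PhysioConstants = PhysioConstants()) -> EchoSeries:
    """Forward-simulate a multi-echo GE or SE acquisition.

    GE decays with R2* = R2 + k * CBV * OEF, SE with R2 alone, so the GE
    signal never exceeds the SE signal at matched echo time.  ``noise_sd`` is
    the Gaussian noise level relative to the voxel's S0 (Rician optional).
    """
    echo_times_ms = np.asarray(echo_times_ms, dtype=float)
    if echo_times_ms.size < 3 or np.any(np.diff(echo_times_ms) <= 0):
        raise ValueError("need >=3 strictly increasing echo times")
    if np.any(echo_times_ms < 0):
        raise ValueError("negative echo times are not allowed")
    rate = gt.r2star(consts) if kind == "GE" else gt.r2
    rng = rng or np.random.default_rng(0)
    vols = []
    for te in echo_times_ms:
        sig = gt.s0 * np.exp(-te * 1e-3 * rate)
        sig = _add_noise(sig, noise_sd * gt.s0, rng, rician)
        vols.append(VolumeGrid(sig, gt.voxel_size_mm))
    return EchoSeries(vols, echo_times_ms, kind)


def _dsc_delta_r2(gt: GroundTruthMaps, timing: ProtocolTiming, echo: str,
                  shift_frames: float) -> np.ndarray:
    times = np.arange(timing.n_frames) * timing.frame_interval
    b_map = _transit_scale(gt.cbv, gt.cbf)
    t0 = np.full(gt.cbv.shape, timing.arrival_s)
    t0 = np.where(gt.cbv >= 0.5, timing.arrival_s - 3.0, t0)  # arterial voxels arrive early
    vol = gt.cbv if echo == "GE" else gt.micro_cbv
    if echo == "SE":
        t0 = t0 + gt.loop_orientation * shift_frames * timing.frame_interval
    dt = times[None, None, None, :] - t0[..., None]
    bb = b_map[..., None]
    norm = 1.0 / (6.0 * bb ** (BOLUS_ALPHA + 1.0))  # Gamma(alpha+1) = 6 for alpha 3
    shape_t = np.where(dt > 0, norm * np.where(dt > 0, dt, 1.0) ** BOLUS_ALPHA
                       * np.exp(-np.where(dt > 0, dt, 0.0) / bb), 0.0)
    return timing.dose_scale * BOLUS_AMPLITUDE * vol[..., None] * shape_t


def simulate_dsc(gt: GroundTruthMaps, timing: ProtocolTiming | str = SITE_A,
                 noise_sd: float = 0.0, shift_frames: float = 1.0, rng=None,
                 rician: bool = False) -> dict:
    """Forward-simulate DSC perfusion MRI under a site protocol.

    Returns ``{"ge": ..., "se": ...}`` for the separate-acquisition protocol
    and ``{"hybrid": ...}`` for the hybrid GESE protocol.  The SE bolus is
    shifted by ``shift_frames`` frames, signed by the voxel's loop
    orientation, which closes the downstream hysteresis loop clockwise (+1)
    or counter-clockwise (-1).
    """
    if isinstance(timing, str):
        timing = PROTOCOLS[timing]
    if timing.dose_scale <= 0:
        raise ValueError("dose_scale must be positive")
    rng = rng or np.random.default_rng(0)

    series = {}
    for echo, te in (("GE", timing.te_ge_ms), ("SE", timing.te_se_ms)):
        dr2 = _dsc_delta_r2(gt, timing, echo, shift_frames)
        sig = gt.s0[..., None] * np.exp(-te * 1e-3 * dr2)
        sig = _add_noise(sig, noise_sd * gt.s0[..., None], rng, rician)
        series[echo] = DynamicSeries(sig, timing.frame_interval, te, echo_kind=echo,
                                     baseline_window=(0, timing.baseline_frames),
                                     voxel_size_mm=(gt.voxel_size_mm,) * 3)
    if timing.name == "site_B_hybrid":
        return {"hybrid": merge_gese(series["GE"], series["SE"])}
    return {"ge": series["GE"], "se": series["SE"]}


def simulate_dwi(gt: GroundTruthMaps, noise_sd: float = 0.0, rng=None) -> DiffusionPair:
    """Two-point DWI: S(b) = S0 exp(-b * ADC) at b = 0 and 1000 s/mm^2."""
    rng = rng or np.random.default_rng(0)
    s0 = _add_noise(gt.s0.copy(), noise_sd * gt.s0, rng, False)
    s1000 = _add_noise(gt.s0 * np.exp(-1000.0 * gt.adc), noise_sd * gt.s0, rng, False)
    vs = (gt.voxel_size_mm,) * 3
    return DiffusionPair(VolumeGrid(s0, vs), VolumeGrid(s1000, vs))


def simulate_anatomical(gt: GroundTruthMaps, noise_sd: float = 0.0, rng=None):
    """Synthetic ceT1w and FLAIR volumes as contrast-weighted composites.

    These stand in for acquired anatomical images: contrast enhancement
    tracks blood volume, FLAIR hyperintensity tracks diffusivity and hypoxia.
    """
    rng = rng or np.random.default_rng(0)
    brain = gt.s0 > 0
    cet1w = gt.s0 * (0.55 + 5.0 * np.clip(gt.cbv, 0, 0.2))
    flair = gt.s0 * (0.30 + 300.0 * gt.adc + 0.5 * gt.oef)
    cet1w = np.where(brain, _add_noise(cet1w, noise_sd * gt.s0, rng, False), 0.0)
    flair = np.where(brain, _add_noise(flair, noise_sd * gt.s0, rng, False), 0.0)
    vs = (gt.voxel_size_mm,) * 3
    return VolumeGrid(cet1w, vs), VolumeGrid(flair, vs)


def simulate_patient(spec: PhantomSpec, effects: ClassEffectModel | None = None,
                     noise_sd: float = 0.0, pid: str | None = None) -> PatientBundle:
    """Simulate every raw series of one patient from a phantom spec."""
    effects = effects or default_class_effects()
    phantom = make_phantom(spec, effects)
    gt = phantom.gt
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    ge_echo = simulate_echo_series(gt, GE_ECHO_TIMES_MS, "GE", noise_sd, rng)
    se_echo = simulate_echo_series(gt, SE_ECHO_TIMES_MS, "SE", noise_sd, rng)
    dwi = simulate_dwi(gt, noise_sd, rng)
    cet1w, flair = simulate_anatomical(gt, noise_sd, rng)
    dsc = simulate_dsc(gt, spec.timing, noise_sd=noise_sd, rng=rng)
    return PatientBundle(pid or f"sub-{spec.seed:06d}", spec.class_label, phantom,
                         ge_echo, se_echo, dwi, cet1w, flair, dsc)


def simulate_cohort(n: int, effects: ClassEffectModel | None = None,
                    protocol: str = "site_A_separate", seed: int = 0,
                    grid_shape: tuple[int, int, int] = (32, 32, 32),
                    noise_sd: float = 0.003) -> list[PatientBundle]:
    """Simulate a cohort of patient bundles with class prevalence 0.74.

    Labels are drawn i.i.d. with the model's IDHwt prevalence; per-patient
    seeds and tumor geometries derive deterministically from the cohort seed.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 patients")
    effects = effects or default_class_effects()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    labels = np.where(rng.random(n) < effects.prevalence_idhwt, "IDHwt", "IDHmut")
    child_seeds = rng.integers(0, 2**31 - 1, size=n)

    shape = np.asarray(grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    bundles = []
    for i in range(n):
        prng = np.random.default_rng(child_seeds[i])
        radii = prng.uniform(0.11, 0.16, size=3) * shape.min()
        jitter = prng.uniform(-0.05, 0.05, size=3) * shape
        spec = PhantomSpec(grid_shape=tuple(int(s) for s in grid_shape),
                           tumor_center=tuple(center + jitter),
                           tumor_radii=tuple(radii),
                           class_label=str(labels[i]),
                           seed=int(child_seeds[i]), protocol=protocol)
        bundles.append(simulate_patient(spec, effects, noise_sd=noise_sd,
                                        pid=f"sub-{seed:04d}-{i:04d}"))
    return bundles
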