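"""Synthetic 4D lung perfusion phantoms with known ground truth.

The phantom emulates a first-pass contrast bolus acquisition: a
pulmonary-trunk structure carrying a gamma-variate arterial input, lung
parenchyma whose concentration curves follow the indicator-dilution
convolution with region-wise ground-truth PBF/PBV (MTT implied by the
central volume theorem), a saturating signal-enhancement map, an optional
constant residual-contrast baseline left over from a previous injection,
and additive Gaussian noise.

Discrete tracer-kinetic model
-----------------------------
All curves live on the frame grid (interval ``dt_s``).  The tissue curve is
the rectangle-rule discrete convolution

    C_t[i] = dt * sum_j C_a[i - j - d] * f * R[j],      f = PBF / 6000  (1/s)

with the residue kernel ``R[j] = (1 - dt/MTT)**j`` — the exact solution of
the single-compartment washout on the grid.  This kernel has ``R[0] = 1``
(so PBF is the height of ``f*R``) and ``dt * sum R = MTT`` (so the
tissue/arterial integral ratio is PBV/100), i.e. the central volume theorem
holds exactly on the grid; it requires ``MTT >= dt``, which generation
enforces.  ``d`` is the trunk→tissue transit delay in whole frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import regions as _regions
from .errors import ValidationError
from .series import DynamicSeries

__all__ = [
    "AifParams", "PhantomSpec", "GroundTruth",
    "generate_aif", "tissue_curve_from_truth",
    "signal_from_concentration", "concentration_from_enhancement",
    "generate_phantom", "default_region_truth",
]


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate first-pass bolus with an optional recirculation bump.

    ``amplitude`` is the peak concentration of the first pass (arbitrary
    concentration units; all concentrations in the package are consistent
    relative units, since no relaxivity calibration exists).
    ``steady_state_conc`` is the concentration of one full dose after
    complete mixing in the blood pool — the reference for
    ``residual_fraction`` (a first-pass bolus is ~25x more concentrated
    than the fully mixed dose).
    """

    amplitude: float = 1.0
    shape_alpha: float = 3.0
    scale_tp_s: float = 4.0  # time-to-peak of the gamma variate
    trunk_arrival_s: float = 3.0  # injection site -> pulmonary trunk transit
    recirc_amplitude: float = 0.0  # fraction of first-pass amplitude
    recirc_delay_s: float = 12.0
    steady_state_conc: float = 0.04

    def __post_init__(self):
        if min(self.amplitude, self.shape_alpha, self.scale_tp_s) <= 0:
            raise ValidationError("gamma-variate parameters must be positive")
        if self.recirc_amplitude < 0 or self.steady_state_conc <= 0:
            raise ValidationError("invalid AIF parameters")


def default_region_truth() -> pd.DataFrame:
    """Ground-truth PBF/PBV per region, with gravity and apico-basal gradients.

    Base values (PBF 220 ml/min/100ml, PBV 18 ml/100ml) sit in the range
    reported for COPD lungs.  Dorsal (back) regions are more perfused than
    ventral (front) ones — the gravity-dependent gradient — with a slightly
    longer MTT dorsally; upper (apical) regions are mildly less perfused
    than lower (basal) ones.
    """
    base_pbf, base_pbv = 220.0, 18.0
    depth_f = {"front": (0.85, 0.78), "back": (1.15, 1.25)}  # (pbf, pbv) factors
    vert_f = {"upper": 0.95, "middle": 1.0, "lower": 1.05}
    rows = []
    for (side, vert, depth), rid in sorted(
        _regions.REGION_IDS.items(), key=lambda kv: kv[1]
    ):
        fp, fv = depth_f[depth]
        g = vert_f[vert]
        rows.append(dict(region_id=rid, side=side, vertical=vert, depth=depth,
                         name=f"{side}-{vert}-{depth}",
                         pbf=base_pbf * fp * g, pbv=base_pbv * fv * g))
    df = pd.DataFrame(rows)
    df["mtt_s"] = 60.0 * df.pbv / df.pbf
    return df


@dataclass
class PhantomSpec:
    """Everything needed to generate one phantom acquisition.

    Defaults reproduce the study acquisition: 24 volumes at 1.47 s/volume
    (35.28 s total), contrast injected 5 s after the start of the
    measurement, saturating enhancement, 2% additive noise.
    """

    grid_shape: tuple[int, int, int] = (32, 32, 16)
    voxel_size_mm: tuple[float, float, float] = (9.0, 9.0, 15.0)
    n_frames: int = 24
    dt_s: float = 1.47
    injection_delay_s: float = 5.0
    arrival_delay_s: float = 1.47  # extra trunk->tissue delay, quantized to frames
    aif_params: AifParams = field(default_factory=AifParams)
    region_truth: pd.DataFrame | None = None  # defaults to default_region_truth()
    s0: float = 100.0
    sat_beta: float = 0.3
    residual_fraction: float = 0.0
    noise_sd: float = 2.0
    vessel_fraction: float = 0.0  # fraction of lung voxels made high-PBV vessels
    smooth_gradient: bool = False  # continuous ventral->dorsal gradient mode
    seed: int = 0

    def truth_table(self) -> pd.DataFrame:
        return (self.region_truth if self.region_truth is not None
                else default_region_truth()).copy()

    def validate(self) -> None:
        if self.s0 <= 0 or self.sat_beta < 0 or self.noise_sd < 0:
            raise ValidationError("s0 must be >0, sat_beta and noise_sd >= 0")
        if not 0.0 <= self.residual_fraction <= 1.0:
            raise ValidationError("residual_fraction must lie in [0, 1]")
        truth = self.truth_table()
        if (truth.pbf <= 0).any() or (truth.pbv <= 0).any():
            raise ValidationError("ground-truth PBF and PBV must be positive")
        mtt = 60.0 * truth.pbv / truth.pbf
        if (mtt < self.dt_s).any():
            raise ValidationError(
                "implied MTT = 60*PBV/PBF falls below the frame interval for "
                "at least one region; the discrete washout kernel is undefined"
            )
        onset = self.injection_delay_s + self.aif_params.trunk_arrival_s
        peak = onset + self.aif_params.scale_tp_s
        if peak > self.n_frames * self.dt_s:
            raise ValidationError("bolus peak occurs after the last frame")


@dataclass
class GroundTruth:
    """Truth container for recovery tests (not available for real data)."""

    region_table: pd.DataFrame  # region_id, name, ..., pbf, pbv, mtt_s
    mtt_s: np.ndarray  # per-voxel truth maps (NaN outside lung)
    pbf: np.ndarray
    pbv: np.ndarray
    aif_first_pass: np.ndarray  # concentration increment above baseline
    aif_baseline: float
    arrival_frame: int  # frame during which the bolus reaches the trunk
    delay_frames: int  # additional trunk->tissue delay in frames
    vessel_mask: np.ndarray | None = None


def _frame_average(func, n_frames: int, dt: float, nsub: int = 16) -> np.ndarray:
    """Average a continuous curve over each frame interval (time integration)."""
    offsets = (np.arange(nsub) + 0.5) / nsub * dt
    t = np.arange(n_frames)[:, None] * dt + offsets[None, :]
    return func(t).mean(axis=1)


def generate_aif(
    params: AifParams,
    n_frames: int,
    dt_s: float,
    injection_delay_s: float = 5.0,
    residual_fraction: float = 0.0,
) -> np.ndarray:
    """Arterial concentration per frame: residual baseline + first pass.

    The first-pass component is a gamma-variate starting at
    ``injection_delay_s + trunk_arrival_s`` (zero before), averaged over
    each frame interval; an optional recirculation bump is a scaled,
    delayed copy.  The residual baseline is constant over the acquisition —
    elimination with a half-life of hours is negligible over <40 s.
    """
    onset = injection_delay_s + params.trunk_arrival_s
    if onset + params.scale_tp_s > n_frames * dt_s:
        raise ValidationError("first-pass peak occurs after the last frame")

    a, al, tp = params.amplitude, params.shape_alpha, params.scale_tp_s

    def gamma(t):
        x = np.clip((t - onset) / tp, 0.0, None)
        return a * x**al * np.exp(al * (1.0 - x))

    def curve(t):
        c = gamma(t)
        if params.recirc_amplitude > 0:
            c = c + params.recirc_amplitude * gamma(t - params.recirc_delay_s)
        return c

    first_pass = _frame_average(curve, n_frames, dt_s)
    baseline = residual_fraction * params.steady_state_conc
    return baseline + first_pass


def aif_analytic_integral(params: AifParams) -> float:
    """Closed-form time integral of the gamma-variate first pass (conc*s).

    integral = a * tp * exp(alpha) * Gamma(alpha+1) / alpha^(alpha+1),
    times (1 + recirculation fraction).
    """
    from scipy.special import gamma as G

    a, al, tp = params.amplitude, params.shape_alpha, params.scale_tp_s
    base = a * tp * np.exp(al) * G(al + 1.0) / al ** (al + 1.0)
    return float(base * (1.0 + params.recirc_amplitude))


def residue_kernel(mtt_s: float, dt_s: float, n: int) -> np.ndarray:
    """Discrete compartment washout kernel R[j] = (1 - dt/MTT)^j."""
    if mtt_s < dt_s:
        raise ValidationError("MTT must be >= dt for the discrete washout kernel")
    return (1.0 - dt_s / mtt_s) ** np.arange(n)


def tissue_curve_from_truth(
    aif_first_pass: np.ndarray,
    pbf: float,
    pbv: float,
    dt_s: float,
    delay_frames: int = 0,
    residual_baseline: float = 0.0,
) -> np.ndarray:
    """Tissue concentration C_t = f*(C_a (*) R) by discrete convolution.

    ``aif_first_pass`` must be the arterial concentration *increment* above
    any residual baseline; the tissue's own residual baseline (the blood
    fraction of the circulating residual, i.e. residual * steady-state *
    PBV/100) is passed separately and added as a constant.
    """
    aif = np.asarray(aif_first_pass, dtype=float)
    n = aif.size
    mtt = 60.0 * pbv / pbf
    f = pbf / 6000.0  # ml/min/100ml -> fraction per second
    kern = f * residue_kernel(mtt, dt_s, n)
    if delay_frames:
        aif = np.concatenate([np.zeros(delay_frames), aif[: n - delay_frames]])
    conv = dt_s * np.convolve(aif, kern)[:n]
    return residual_baseline + conv


def signal_from_concentration(c, s0: float, sat_beta: float):
    """Saturating enhancement map S = s0 * (1 + c / (1 + sat_beta*c)).

    Monotone increasing and concave in ``c``; reduces to the linear map
    ``s0*(1+c)`` for ``sat_beta = 0`` and saturates at ``s0*(1+1/sat_beta)``.
    The concavity is what dampens high (arterial) concentrations more than
    dilute (tissue) ones.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValidationError("concentration must be non-negative")
    if s0 <= 0 or sat_beta < 0:
        raise ValidationError("require s0 > 0 and sat_beta >= 0")
    return s0 * (1.0 + c / (1.0 + sat_beta * c))


def concentration_from_enhancement(e, sat_beta: float):
    """Invert the saturation map: e = c/(1+beta*c)  =>  c = e/(1-beta*e)."""
    e = np.asarray(e, dtype=float)
    if sat_beta > 0:
        e = np.minimum(e, 1.0 / sat_beta * (1.0 - 1e-9))
    return e / (1.0 - sat_beta * e)


def _structural_masks(shape: tuple[int, int, int]):
    nx, ny, nz = shape
    lung = np.zeros(shape, dtype=bool)
    xl0, xl1 = round(0.06 * nx), round(0.41 * nx)
    xr0, xr1 = round(0.59 * nx), round(0.94 * nx)
    y0, y1 = round(0.12 * ny), round(0.88 * ny)
    z0, z1 = round(0.12 * nz), round(0.88 * nz)
    lung[xl0:xl1, y0:y1, z0:z1] = True
    lung[xr0:xr1, y0:y1, z0:z1] = True
    trunk = np.zeros(shape, dtype=bool)
    trunk[round(0.44 * nx):round(0.56 * nx),
          round(0.30 * ny):round(0.48 * ny),
          round(0.30 * nz):round(0.70 * nz)] = True
    return lung, trunk


def generate_phantom(spec: PhantomSpec) -> tuple[DynamicSeries, GroundTruth]:
    """Generate one seeded phantom acquisition and its ground truth.

    Identical ``spec`` (including seed) yields bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.grid_shape
    nt, dt = spec.n_frames, spec.dt_s

    lung, trunk = _structural_masks(spec.grid_shape)
    part = _regions.build_partition(lung, spec.voxel_size_mm)
    labels = part.labels

    truth = spec.truth_table()
    present = set(np.unique(labels)) - {0}
    missing = present - set(truth.region_id)
    if missing:
        raise ValidationError(f"region_truth missing regions {sorted(missing)}")

    aif_full = generate_aif(spec.aif_params, nt, dt, spec.injection_delay_s,
                            spec.residual_fraction)
    aif_baseline = spec.residual_fraction * spec.aif_params.steady_state_conc
    aif_fp = aif_full - aif_baseline
    onset = spec.injection_delay_s + spec.aif_params.trunk_arrival_s
    arrival_frame = int(onset // dt)
    if arrival_frame < 1:
        raise ValidationError("bolus arrives before the second frame")
    delay_frames = int(round(spec.arrival_delay_s / dt))

    conc = np.zeros((nx, ny, nz, nt), dtype=float)
    conc[trunk] = aif_full

    mtt_map = np.full(spec.grid_shape, np.nan)
    pbf_map = np.full(spec.grid_shape, np.nan)
    pbv_map = np.full(spec.grid_shape, np.nan)

    # optional continuous ventral->dorsal perfusion gradient inside regions:
    # PBF and PBV scale together, so curves scale linearly and MTT is kept.
    if spec.smooth_gradient:
        ys = np.arange(ny)
        grad = 0.8 + 0.4 * (ys - ys.min()) / max(ys.max() - ys.min(), 1)
    else:
        grad = np.ones(ny)

    for _, reg in truth.iterrows():
        sel = labels == reg.region_id
        if not sel.any():
            continue
        base = tissue_curve_from_truth(
            aif_fp, reg.pbf, reg.pbv, dt, delay_frames,
            residual_baseline=spec.residual_fraction
            * spec.aif_params.steady_state_conc * reg.pbv / 100.0,
        )
        scale = grad[np.nonzero(sel)[1]]  # per-voxel factor by y index
        conc[sel] = scale[:, None] * base[None, :]
        mtt_map[sel] = 60.0 * reg.pbv / reg.pbf
        pbf_map[sel] = scale * reg.pbf
        pbv_map[sel] = scale * reg.pbv

    vessel_mask = None
    if spec.vessel_fraction > 0:
        lung_idx = np.flatnonzero(labels.ravel() > 0)
        n_ves = max(1, int(spec.vessel_fraction * lung_idx.size))
        pick = rng.choice(lung_idx, size=n_ves, replace=False)
        vessel_mask = np.zeros(spec.grid_shape, dtype=bool)
        vessel_mask.ravel()[pick] = True
        flat = conc.reshape(-1, nt)
        flat[pick] *= 5.0  # blood-filled: ~5x parenchymal blood volume
        pv = pbv_map.ravel(); pv[pick] *= 5.0
        pf = pbf_map.ravel(); pf[pick] *= 5.0  # MTT unchanged

    signal = signal_from_concentration(conc, spec.s0, spec.sat_beta)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, size=signal.shape)
        np.clip(signal, 0.0, None, out=signal)

    series = DynamicSeries(
        data=signal, dt_s=dt, voxel_size_mm=spec.voxel_size_mm,
        lung_mask=lung, trunk_mask=trunk, region_labels=labels,
    )
    truth["mtt_s"] = 60.0 * truth.pbv / truth.pbf
    gt = GroundTruth(
        region_table=truth, mtt_s=mtt_map, pbf=pbf_map, pbv=pbv_map,
        aif_first_pass=aif_fp, aif_baseline=aif_baseline,
        arrival_frame=arrival_frame, delay_frames=delay_frames,
        vessel_mask=vessel_mask,
    )
    return series, gt


def with_residual(spec: PhantomSpec, residual_fraction: float) -> PhantomSpec:
    """Copy of a spec with a different carried-over residual fraction."""
    return replace(spec, residual_fraction=residual_fraction)
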