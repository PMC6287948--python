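"""Indicator-dilution deconvolution and voxelwise MTT/PBF/PBV maps.

The tissue curve is modelled as C_t = C_a (*) f*R with flow-scaled residue
f*R(t); discretizing the convolution with the rectangle rule gives a
lower-triangular Toeplitz system A x = c_t with A[i, j] = dt * C_a[i-j].
The system is solved per voxel by truncated SVD: singular values below a
fraction of the largest are zeroed (default 15%, the canonical
bolus-tracking choice) and the pseudo-inverse applied.

Parameters follow indicator-dilution theory:

* PBF = 6000 * height of the flow-scaled residue  [ml/min/100ml]
* PBV = 100 * integral(C_t) / integral(C_a)       [ml/100ml; post-arrival window]
* MTT = 60 * PBV / PBF                            [s; central volume theorem]

Hard SVD truncation at coarse temporal resolution systematically flattens
the residue peak (the classic flow underestimation of standard SVD
bolus tracking), while reading the height as a per-voxel maximum inflates
it under noise (an order-statistic bias).  ``quantify_lung`` therefore
reads the height with a matched filter: each voxel's regularized residue
is projected onto the truncated reconstruction of a unit-height
single-compartment residue at that voxel's MTT (found by a short fixed
point through the central volume theorem), with the tissue transit delay
identified once by shape-matching against the voxel-median residue.  The
projection is exact on noise-free model-consistent data at any truncation
and suppresses read-out noise by an order of magnitude relative to the
raw maximum, which remains available as ``pbf_mode="peak_max"`` and in
:func:`params_from_residue`.

Bolus delay between trunk and tissue is absorbed by the causal Toeplitz
system itself (it shifts the residue peak); no explicit delay fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import toeplitz

from .aif import AifCurve
from .errors import ComputeError, ValidationError
from .kinetics import ConcentrationSeries

log = logging.getLogger(__name__)

__all__ = [
    "ResidueEstimate", "PerfusionMaps",
    "build_convolution_matrix", "tsvd_pseudoinverse", "deconvolve_voxel",
    "params_from_residue", "area_height_mtt", "quantify_lung",
]

_MTT_GRID_MAX_S = 20.0
_MAX_DELAY_FRAMES = 5


@dataclass
class ResidueEstimate:
    """Flow-scaled residue f*R(t) for one voxel (units 1/s)."""

    residue: np.ndarray
    pbf_scale: float  # f = max of the scaled residue
    truncation_frac: float
    n_kept: int  # singular values retained
    condition: float  # sigma_max / sigma_min of the full matrix
    valid: bool = True


@dataclass
class PerfusionMaps:
    """Voxelwise perfusion parameter maps (NaN outside valid voxels)."""

    mtt_s: np.ndarray
    pbf: np.ndarray
    pbv: np.ndarray
    valid_mask: np.ndarray
    invalid_fraction: float = 0.0


def build_convolution_matrix(aif_values: np.ndarray, dt_s: float) -> np.ndarray:
    """Lower-triangular Toeplitz discretization of convolution with the AIF."""
    a = np.asarray(aif_values, dtype=float)
    if a.size < 2:
        raise ValidationError("AIF must have at least 2 samples")
    return dt_s * toeplitz(a, np.zeros_like(a))


def tsvd_pseudoinverse(
    matrix: np.ndarray, truncation_frac: float = 0.15
) -> tuple[np.ndarray, int, float]:
    """Truncated-SVD pseudo-inverse; returns (pinv, n_kept, condition)."""
    if not 0.0 < truncation_frac < 1.0:
        raise ValidationError("truncation_frac must lie in (0, 1)")
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    cond = float(s[0] / s[-1]) if s[-1] > 0 else np.inf
    keep = s >= truncation_frac * s[0]
    n_kept = int(keep.sum())
    inv_s = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    pinv = (vt.T * inv_s) @ u.T
    return pinv, n_kept, cond


def deconvolve_voxel(
    tissue_curve: np.ndarray,
    conv_matrix: np.ndarray,
    truncation_frac: float = 0.15,
) -> ResidueEstimate:
    """Solve A x = c_t for the flow-scaled residue of one voxel."""
    c = np.asarray(tissue_curve, dtype=float)
    if c.size != conv_matrix.shape[0]:
        raise ValidationError("tissue curve length does not match matrix")
    pinv, n_kept, cond = tsvd_pseudoinverse(conv_matrix, truncation_frac)
    residue = pinv @ c
    valid = n_kept > 0 and residue.max(initial=0.0) > 0
    return ResidueEstimate(
        residue=residue, pbf_scale=float(residue.max(initial=0.0)),
        truncation_frac=truncation_frac, n_kept=n_kept, condition=cond,
        valid=valid,
    )


def params_from_residue(
    residue: np.ndarray,
    tissue_curve: np.ndarray,
    aif_values: np.ndarray,
    dt_s: float,
) -> tuple[float, float, float, bool]:
    """(mtt_s, pbf, pbv, valid) from one voxel's residue and curves.

    Curves must already be restricted to the common post-arrival window.
    Non-positive PBF or PBV flags the voxel invalid rather than raising.
    """
    pbf = 6000.0 * float(np.max(residue, initial=0.0))
    denom = float(np.trapezoid(aif_values, dx=dt_s))
    pbv = 100.0 * float(np.trapezoid(tissue_curve, dx=dt_s)) / denom
    if pbf <= 0 or pbv <= 0:
        return np.nan, np.nan, np.nan, False
    mtt = 60.0 * pbv / pbf
    return mtt, pbf, pbv, True


def area_height_mtt(residue: np.ndarray, dt_s: float) -> float:
    """Diagnostic MTT as residue area / height (alternative to central volume)."""
    h = float(np.max(residue, initial=0.0))
    if h <= 0:
        return np.nan
    return float(dt_s * np.sum(np.clip(residue, 0.0, None)) / h)


def _model_residue(m: int, dt: float, mtt_s: float, delay: int) -> np.ndarray:
    r = np.zeros(m)
    r[delay:] = (1.0 - dt / mtt_s) ** np.arange(m - delay)
    return r


def _estimate_delay(PA: np.ndarray, dt: float, median_residue: np.ndarray) -> int:
    """Tissue transit delay (frames), by matching normalized reconstructions
    of delayed model residues to the voxel-median residue."""
    m = PA.shape[0]
    med = median_residue / max(np.linalg.norm(median_residue), 1e-30)
    best_d, best_score = 0, -np.inf
    for d in range(min(_MAX_DELAY_FRAMES, m - 1) + 1):
        rec = PA @ _model_residue(m, dt, 5.0, d)
        nrm = np.linalg.norm(rec)
        if nrm <= 0:
            continue
        score = float((rec / nrm) @ med)
        if score > best_score:
            best_score, best_d = score, d
    return best_d


def _matched_filter_height(
    residues: np.ndarray, pinv: np.ndarray, A: np.ndarray, dt: float,
    pbv: np.ndarray,
) -> np.ndarray:
    """Per-voxel flow-scaled residue height f by matched-filter projection.

    Projects each voxel's regularized residue onto the truncated
    reconstruction of a unit-height single-compartment residue at the
    voxel's own MTT, iterating MTT through the central volume theorem
    (3-4 iterations suffice; the projection varies smoothly with MTT).
    """
    m = A.shape[0]
    PA = pinv @ A
    med_residue = np.median(residues, axis=0)
    if med_residue.max(initial=0.0) <= 0:
        return residues.max(axis=1)
    delay = _estimate_delay(PA, dt, med_residue)
    mtt_grid = np.linspace(dt * 1.05, _MTT_GRID_MAX_S, 80)
    templates = np.stack([PA @ _model_residue(m, dt, mt, delay)
                          for mt in mtt_grid])  # (G, m)
    norms = np.einsum("gm,gm->g", templates, templates)
    height_grid = (residues @ templates.T) / np.clip(norms, 1e-30, None)

    idx = np.arange(residues.shape[0])
    mtt_v = np.full(residues.shape[0], 5.0)
    height = np.zeros(residues.shape[0])
    for _ in range(4):
        gi = np.clip(np.searchsorted(mtt_grid, mtt_v) - 1, 0, len(mtt_grid) - 2)
        frac = np.clip((mtt_v - mtt_grid[gi])
                       / (mtt_grid[gi + 1] - mtt_grid[gi]), 0.0, 1.0)
        height = (height_grid[idx, gi] * (1 - frac)
                  + height_grid[idx, gi + 1] * frac)
        with np.errstate(divide="ignore", invalid="ignore"):
            mtt_v = np.clip(
                np.where(height > 0, 0.01 * pbv / height, mtt_grid[-1]),
                mtt_grid[0], mtt_grid[-1])
    return height


def quantify_lung(
    conc: ConcentrationSeries,
    lung_mask: np.ndarray,
    aif: AifCurve,
    truncation_frac: float = 0.15,
    pbf_mode: str = "matched_filter",
) -> PerfusionMaps:
    """Deconvolve every masked voxel and assemble MTT/PBF/PBV maps.

    All voxels share one truncated pseudo-inverse of the AIF convolution
    matrix, so the whole lung is a single matrix product; the result is
    deterministic for identical input.

    ``pbf_mode="matched_filter"`` (default) reads the residue height by
    projection onto the reconstructed unit model residue at the voxel's
    MTT; ``"peak_max"`` is the plain per-voxel maximum.
    """
    mask = np.asarray(lung_mask).astype(bool)
    if not mask.any():
        raise ValidationError("empty lung mask")
    n = conc.n_frames
    arr = conc.arrival_frame
    if arr > n // 2:
        raise ComputeError(
            "insufficient first-pass coverage: bolus arrival after half the frames"
        )
    win = slice(arr, n)
    aif_win = aif.values[win]
    A = build_convolution_matrix(aif_win, conc.dt_s)
    pinv, n_kept, cond = tsvd_pseudoinverse(A, truncation_frac)
    if n_kept == 0:
        raise ComputeError("all singular values truncated; AIF degenerate")

    tissue = conc.data[mask][:, win]  # (n_vox, m)
    residues = tissue @ pinv.T
    aif_area = float(np.trapezoid(aif_win, dx=conc.dt_s))
    pbv = 100.0 * np.trapezoid(tissue, dx=conc.dt_s, axis=1) / aif_area

    if pbf_mode == "peak_max":
        pbf = 6000.0 * residues.max(axis=1)
    elif pbf_mode == "matched_filter":
        pbf = 6000.0 * _matched_filter_height(residues, pinv, A, conc.dt_s, pbv)
    else:
        raise ValidationError(f"unknown pbf_mode {pbf_mode!r}")

    valid = (pbf > 0) & (pbv > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtt = np.where(valid, 60.0 * pbv / np.where(pbf > 0, pbf, np.nan), np.nan)

    shape = conc.data.shape[:3]
    maps = {k: np.full(shape, np.nan) for k in ("mtt", "pbf", "pbv")}
    maps["mtt"][mask] = np.where(valid, mtt, np.nan)
    maps["pbf"][mask] = np.where(valid, pbf, np.nan)
    maps["pbv"][mask] = np.where(valid, pbv, np.nan)
    valid_mask = np.zeros(shape, dtype=bool)
    valid_mask[mask] = valid
    frac_bad = 1.0 - valid.mean()
    if frac_bad > 0:
        log.info("quantify_lung: %.2f%% voxels invalid", 100 * frac_bad)
    return PerfusionMaps(
        mtt_s=maps["mtt"], pbf=maps["pbf"], pbv=maps["pbv"],
        valid_mask=valid_mask, invalid_fraction=float(frac_bad),
    )
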