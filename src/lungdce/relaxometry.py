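"""Voxel-wise T1 / S0 estimation from variable-flip-angle SPGR data.

The spoiled gradient echo steady-state magnitude is

    S(alpha) = S0 * sin(alpha) * (1 - E1) / (1 - E1 * cos(alpha)),
    E1 = exp(-TR / T1),

which is linear in the transformed coordinates S/sin(alpha) vs S/tan(alpha)
with slope E1 (DESPOT1). The fit here runs that linearization per voxel and
then refines (T1, S0) by bounded nonlinear least squares on the untransformed
signals, which is the maximum-likelihood estimate under additive Gaussian
noise and is robust at low flip angles where the linearization is noise-biased.

The module also computes qS0 — lung S0 normalized to a skeletal-muscle
reference region — a proton-density-weighted index of tissue water content.
qS0 deliberately inherits the raw S0's T2*/coil-sensitivity weighting; it is
a ratio index, not an absolute water measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import VolumeSeries
from .protocol import AcquisitionProtocol

log = logging.getLogger("lungdce")

T1_BOUNDS_MSEC = (50.0, 10000.0)


@dataclass
class T1FitResult:
    """Per-voxel T1 (ms), relative equilibrium signal S0 (a.u.), validity and
    root-mean-square signal residual."""

    t1_map: np.ndarray
    s0_map: np.ndarray
    valid_mask: np.ndarray
    residual_map: np.ndarray
    affine: np.ndarray | None = None


@dataclass
class QS0Map:
    """Muscle-normalized equilibrium signal. ``muscle_reference_value`` is the
    per-slice reference vector in per-slice mode, or a scalar in global mode."""

    qs0_map: np.ndarray
    muscle_reference_value: np.ndarray | float
    mode: str = "per-slice"


def spgr_signal(s0, t1_msec, tr_msec, flip_deg):
    """Steady-state SPGR magnitude. Broadcasts over array inputs.

    Raises ``ValueError`` on non-finite scalar inputs; array inputs propagate
    NaN so callers can flag voxels instead of aborting.
    """
    s0 = np.asarray(s0, float)
    t1 = np.asarray(t1_msec, float)
    tr = np.asarray(tr_msec, float)
    alpha = np.deg2rad(np.asarray(flip_deg, float))
    if all(x.ndim == 0 for x in (s0, t1, tr, alpha)) and \
            not np.all(np.isfinite([float(s0), float(t1), float(tr),
                                    float(alpha)])):
        raise ValueError("non-finite input to spgr_signal")
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        e1 = np.exp(-tr / t1)
        out = s0 * np.sin(alpha) * (1.0 - e1) / (1.0 - e1 * np.cos(alpha))
    return out


def spgr_invert_t1(signal, s0, tr_msec, flip_deg):
    """Invert the SPGR equation for T1 given S0.

    Returns T1 in ms; samples whose implied E1 falls outside (0, 1) — signal
    at or above the proton-density ceiling, or non-physical — come back NaN.
    """
    signal = np.asarray(signal, float)
    s0 = np.asarray(s0, float)
    alpha = np.deg2rad(float(flip_deg))
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    with np.errstate(invalid="ignore", divide="ignore"):
        e1 = (s0 * sin_a - signal) / (s0 * sin_a - signal * cos_a)
        t1 = np.where((e1 > 0.0) & (e1 < 1.0), -tr_msec / np.log(e1), np.nan)
    return t1


def _despot1_seed(signals: np.ndarray, angles_rad: np.ndarray,
                  tr_msec: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized DESPOT1 linear regression.

    ``signals``: (n_vox, n_angles). Returns (t1, s0) arrays; non-physical
    slopes are clipped into the T1 bounds so they can seed the refinement.
    """
    y = signals / np.sin(angles_rad)
    x = signals / np.tan(angles_rad)
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = sxy / sxx
        intercept = ym[:, 0] - slope * xm[:, 0]
    e1_lo = np.exp(-tr_msec / T1_BOUNDS_MSEC[0])
    e1_hi = np.exp(-tr_msec / T1_BOUNDS_MSEC[1])
    slope = np.clip(np.nan_to_num(slope, nan=0.5), e1_lo, e1_hi)
    t1 = -tr_msec / np.log(slope)
    s0 = intercept / (1.0 - slope)
    s0 = np.where(np.isfinite(s0) & (s0 > 0), s0, signals.max(axis=1) * 10.0)
    return t1, s0


def _refine_voxel(signals: np.ndarray, angles_rad: np.ndarray, tr_msec: float,
                  t1_0: float, s0_0: float) -> tuple[float, float, float, bool]:
    """Bounded nonlinear refinement of one voxel; returns (t1, s0, rms, ok)."""
    sin_a, cos_a = np.sin(angles_rad), np.cos(angles_rad)
    s0_hi = max(signals.max() * 1e4, 10.0 * s0_0, 1.0)

    def model(p):
        e1 = np.exp(-tr_msec / p[0])
        return p[1] * sin_a * (1.0 - e1) / (1.0 - e1 * cos_a)

    def resid(p):
        return model(p) - signals

    def jac(p):
        t1, s0 = p
        e1 = np.exp(-tr_msec / t1)
        denom = 1.0 - e1 * cos_a
        d_e1 = e1 * tr_msec / t1 ** 2
        ds_de1 = s0 * sin_a * (cos_a - 1.0) / denom ** 2
        return np.column_stack([ds_de1 * d_e1, sin_a * (1.0 - e1) / denom])

    x0 = np.array([np.clip(t1_0, *T1_BOUNDS_MSEC), max(s0_0, 1e-6)])
    res = least_squares(
        resid, x0, jac=jac,
        bounds=([T1_BOUNDS_MSEC[0], 1e-9], [T1_BOUNDS_MSEC[1], s0_hi]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, method="trf",
    )
    t1, s0 = res.x
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    on_bound = (
        t1 <= T1_BOUNDS_MSEC[0] * (1 + 1e-9)
        or t1 >= T1_BOUNDS_MSEC[1] * (1 - 1e-9)
    )
    return float(t1), float(s0), rms, bool(res.success and not on_bound)


def average_vfa_repeats(vfa: VolumeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Average repeated volumes acquired at the same flip angle.

    Returns ``(data, angles)`` where data is (x, y, z, n_distinct_angles) and
    angles are in acquisition order of first appearance.
    """
    if vfa.flip_angles_deg is None:
        raise ValueError("VFA series carries no flip angles")
    angles = np.asarray(vfa.flip_angles_deg, float)
    data = vfa.data if vfa.data.ndim == 4 else vfa.data[..., None]
    if data.shape[3] != angles.size:
        raise ValueError("flip angle list length does not match volume count")
    distinct = list(dict.fromkeys(angles.tolist()))
    averaged = np.stack(
        [data[..., angles == a].mean(axis=3) for a in distinct], axis=3
    )
    return averaged, np.asarray(distinct, float)


def fit_vfa(vfa: VolumeSeries, protocol: AcquisitionProtocol,
            mask: np.ndarray | None = None) -> T1FitResult:
    """Estimate T1 and S0 per voxel from a VFA stack.

    Repeated volumes at each flip angle are averaged first; the DESPOT1
    linearization seeds a bounded Levenberg-type refinement with
    T1 in [50, 10000] ms. Voxels that are all-zero, non-finite, fail to
    converge, or finish on a T1 bound keep their estimate but are flagged
    invalid.
    """
    data, angles = average_vfa_repeats(vfa)
    if angles.size < 2:
        raise ValueError("at least 2 distinct flip angles are required")
    shape3 = data.shape[:3]
    if mask is None:
        mask = np.ones(shape3, bool)
    mask = np.asarray(mask, bool)

    angles_rad = np.deg2rad(angles)
    t1_map = np.full(shape3, np.nan)
    s0_map = np.full(shape3, np.nan)
    valid = np.zeros(shape3, bool)
    residual = np.full(shape3, np.nan)

    vox = np.argwhere(mask)
    sig = data[mask]  # (n_vox, n_angles)
    finite = np.isfinite(sig).all(axis=1)
    nonzero = np.abs(sig).max(axis=1) > 0
    fit_me = finite & nonzero
    t1_seed, s0_seed = _despot1_seed(
        np.where(fit_me[:, None], sig, 1.0), angles_rad, protocol.tr_msec
    )
    n_bad = int((~fit_me).sum())
    if n_bad:
        log.warning("fit_vfa: %d voxel(s) excluded (all-zero or non-finite)", n_bad)

    for i, (ix, iy, iz) in enumerate(vox):
        if not fit_me[i]:
            continue
        t1, s0, rms, ok = _refine_voxel(
            sig[i], angles_rad, protocol.tr_msec, t1_seed[i], s0_seed[i]
        )
        t1_map[ix, iy, iz] = t1
        s0_map[ix, iy, iz] = s0
        residual[ix, iy, iz] = rms
        valid[ix, iy, iz] = ok and s0 > 0
    return T1FitResult(t1_map, s0_map, valid, residual, affine=vfa.affine)


def compute_qs0(t1fit: T1FitResult, lung_mask: np.ndarray,
                muscle_roi: np.ndarray, mode: str = "per-slice",
                slice_axis: int | None = None) -> QS0Map:
    """Normalize lung S0 to a skeletal-muscle reference.

    In ``per-slice`` mode each slice along ``slice_axis`` uses the median
    valid muscle S0 within that slice (slices with lung but no muscle raise a
    ``ValueError`` naming the slice). ``global`` mode divides by one
    whole-ROI median — the fallback when the muscle ROI does not span all
    lung-bearing slices. ``slice_axis`` defaults to the anterior-posterior
    axis (coronal slices) resolved from the affine when available, else 1.
    """
    lung_mask = np.asarray(lung_mask, bool)
    muscle_roi = np.asarray(muscle_roi, bool)
    s0 = t1fit.s0_map
    usable = t1fit.valid_mask & np.isfinite(s0) & (s0 > 0)

    qs0 = np.full(s0.shape, np.nan)
    if mode == "global":
        muscle_vals = s0[muscle_roi & usable]
        if muscle_vals.size == 0:
            raise ValueError("muscle ROI contains no valid voxels")
        ref = float(np.median(muscle_vals))
        qs0[lung_mask] = s0[lung_mask] / ref
        return QS0Map(qs0, ref, mode="global")

    if mode != "per-slice":
        raise ValueError(f"unknown qS0 mode: {mode}")
    if slice_axis is None:
        if t1fit.affine is not None:
            # anterior-posterior voxel axis = largest |y| component
            yrow = np.abs(np.asarray(t1fit.affine)[1, :3])
            slice_axis = int(np.argmax(yrow))
        else:
            slice_axis = 1
    n_slices = s0.shape[slice_axis]
    refs = np.full(n_slices, np.nan)
    for sl in range(n_slices):
        index = [slice(None)] * 3
        index[slice_axis] = sl
        index = tuple(index)
        lung_here = lung_mask[index]
        if not lung_here.any():
            continue
        muscle_vals = s0[index][muscle_roi[index] & usable[index]]
        if muscle_vals.size == 0:
            raise ValueError(
                f"per-slice qS0: slice {sl} along axis {slice_axis} has lung "
                "voxels but an empty muscle reference"
            )
        refs[sl] = np.median(muscle_vals)
        plane = np.full(lung_here.shape, np.nan)
        plane[lung_here] = s0[index][lung_here] / refs[sl]
        qs0[index] = np.where(lung_here, plane, qs0[index])
    return QS0Map(qs0, refs, mode="per-slice")
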