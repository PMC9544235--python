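"""Synthetic digital lung phantom with known ground truth.

The phantom stands in for a whole-chest DCE acquisition: two ellipsoidal
lungs, a skeletal-muscle reference block, and a pulmonary-artery-like vessel
cylinder, each carrying voxel-wise ground-truth Ktrans / ve / vp / T10 / S0.
Two parameter regimes are provided — an "hv" (healthy-volunteer-like) regime
with median lung ve around 0.33 and an "hf" (heart-failure-like) regime with
median ve around 0.49, matching the magnitudes the measurement is designed to
separate — and the generator forward-simulates both the VFA stack and the
dynamic series through the same SPGR + extended Tofts physics the analysis
inverts, with reproducible Rician noise.

The phantom is deliberately simple: no breathing motion, no coil-sensitivity
field, no k-space effects. It validates the measurement chain, not the
anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VolumeSeries
from .kinetics import PlasmaCurve, extended_tofts_forward
from .protocol import AcquisitionProtocol, DEFAULT_HEMATOCRIT
from .relaxometry import spgr_signal

MIN_SHAPE = (16, 16, 8)

#: Parker-style population AIF shape parameters (time in minutes after
#: bolus arrival), normalized to a 0.1 mmol/kg reference dose.
_AIF_PARAMS = dict(
    a1=0.809, m1=0.17046, s1=0.0563,
    a2=0.330, m2=0.365, s2=0.132,
    alpha=1.050, beta=0.1685, s=38.078, tau=0.483,
)


class GeometryError(ValueError):
    """Raised when the requested grid cannot contain the phantom anatomy."""


@dataclass(frozen=True)
class TissueRegime:
    """Lung-parenchyma parameter regime (medians of the voxel distributions)."""

    ve_median: float
    ktrans_median: float  # min^-1
    vp_median: float
    t1_msec: float
    qs0: float            # lung S0 as a fraction of muscle S0
    ve_spread: float = 0.03
    ktrans_log_spread: float = 0.15
    vp_spread: float = 0.05
    t1_spread_msec: float = 30.0
    s0_spread_frac: float = 0.02


#: Healthy-volunteer-like lungs: ve ~ 0.33, Ktrans ~ 0.25 min^-1.
HV_REGIME = TissueRegime(ve_median=0.33, ktrans_median=0.25, vp_median=0.45,
                         t1_msec=790.0, qs0=0.26)
#: Heart-failure-like lungs: congested interstitium, ve ~ 0.49.
HF_REGIME = TissueRegime(ve_median=0.49, ktrans_median=0.20, vp_median=0.48,
                         t1_msec=760.0, qs0=0.27)
REGIMES = {"hv": HV_REGIME, "hf": HF_REGIME}

MUSCLE_T1_MSEC = 1000.0
MUSCLE_S0 = 1000.0
BLOOD_T1_MSEC = 1440.0
BLOOD_S0 = 1100.0


@dataclass
class RegionSet:
    """Disjoint anatomical masks on a shared grid."""

    lung_left: np.ndarray
    lung_right: np.ndarray
    muscle: np.ndarray
    vessel: np.ndarray
    affine: np.ndarray

    @property
    def lung(self) -> np.ndarray:
        return self.lung_left | self.lung_right


@dataclass
class GroundTruth:
    """Voxel-wise true parameter maps shared by all phantom outputs."""

    ktrans_map: np.ndarray
    ve_map: np.ndarray
    vp_map: np.ndarray
    t10_map: np.ndarray
    s0_map: np.ndarray
    hematocrit: float


def _ellipsoid(shape, center_frac, semi_frac) -> np.ndarray:
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    c = [f * (n - 1) for f, n in zip(center_frac, shape)]
    r = [max(f * n, 1.0) for f, n in zip(semi_frac, shape)]
    return ((ii - c[0]) / r[0]) ** 2 + ((jj - c[1]) / r[1]) ** 2 + \
        ((kk - c[2]) / r[2]) ** 2 <= 1.0


def make_phantom_geometry(
    shape: tuple[int, int, int] = (32, 32, 16),
    voxel_mm: tuple[float, float, float] = (4.0, 4.0, 8.0),
    group: str = "hv",
    seed: int = 0,
    hematocrit: float = DEFAULT_HEMATOCRIT,
    regime: TissueRegime | None = None,
    apical_basal_ve: tuple[float, float] | None = None,
) -> tuple[RegionSet, GroundTruth]:
    """Build masks and ground-truth maps for one synthetic subject.

    Axis convention: axis 0 = left-right, axis 1 = anterior-posterior,
    axis 2 = foot-head (RAS affine with the given voxel sizes). ``group``
    selects the "hv" or "hf" lung regime unless an explicit ``regime`` is
    given. ``apical_basal_ve = (ve_apical, ve_basal)`` overrides the lung ve
    medians above/below each lung's foot-head midpoint, for testing regional
    summaries against known regional truths.

    Raises :class:`GeometryError` when the grid is too small to hold the
    lungs, muscle block and vessel disjointly (minimum 16 x 16 x 8).
    """
    shape = tuple(int(n) for n in shape)
    if any(n < m for n, m in zip(shape, MIN_SHAPE)):
        raise GeometryError(
            f"shape {shape} too small for the lung ellipsoids; minimum "
            f"{MIN_SHAPE} (failing structure: lungs)"
        )
    if regime is None:
        if group not in REGIMES:
            raise ValueError(f"unknown group {group!r}; expected one of "
                             f"{sorted(REGIMES)}")
        regime = REGIMES[group]
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    affine = np.diag([voxel_mm[0], voxel_mm[1], voxel_mm[2], 1.0])

    lung_l = _ellipsoid(shape, (0.30, 0.52, 0.50), (0.14, 0.28, 0.36))
    lung_r = _ellipsoid(shape, (0.72, 0.52, 0.50), (0.14, 0.28, 0.36))
    # chest-wall muscle: thin slab at the left edge, spanning all y and z so
    # every anterior-posterior slice with lung also contains reference muscle
    muscle = np.zeros(shape, bool)
    muscle[: max(1, int(0.05 * nx)) + 1, :, :] = True
    # vessel: cylinder between the lungs along foot-head
    cx, cy = 0.51 * (nx - 1), 0.52 * (ny - 1)
    r_ves = max(0.035 * nx, 0.9)
    dist2 = (np.arange(nx)[:, None] - cx) ** 2 + \
        (np.arange(ny)[None, :] - cy) ** 2
    vessel = np.zeros(shape, bool)
    z_lo, z_hi = int(0.15 * nz), int(np.ceil(0.85 * nz))
    vessel[:, :, z_lo:z_hi] = (dist2 <= r_ves ** 2)[:, :, None]

    for name, m in (("lungs", lung_l), ("lungs", lung_r),
                    ("muscle", muscle), ("vessel", vessel)):
        if not m.any():
            raise GeometryError(f"shape {shape} too small "
                                f"(failing structure: {name})")
    overlaps = {
        "lungs": lung_l & lung_r,
        "muscle": muscle & (lung_l | lung_r | vessel),
        "vessel": vessel & (lung_l | lung_r),
    }
    for name, ov in overlaps.items():
        if ov.any():
            raise GeometryError(f"shape {shape} too small to keep structures "
                                f"disjoint (failing structure: {name})")
    regions = RegionSet(lung_l, lung_r, muscle, vessel, affine)

    # --- ground-truth maps --------------------------------------------------
    ktrans = np.zeros(shape)
    ve = np.zeros(shape)
    vp = np.zeros(shape)
    t10 = np.full(shape, 1000.0)   # background value, never imaged (s0 = 0)
    s0 = np.zeros(shape)

    lung = regions.lung
    n_lung = int(lung.sum())
    ve_vals = rng.normal(regime.ve_median, regime.ve_spread, n_lung)
    if apical_basal_ve is not None:
        ve_ap, ve_ba = apical_basal_ve
        kk_lung = np.argwhere(lung)[:, 2]
        z_mm = kk_lung * voxel_mm[2]
        for side_mask in (regions.lung_left, regions.lung_right):
            side_rows = side_mask[lung]
            z_side = z_mm[side_rows]
            mid = (z_side.max() + z_side.min()) / 2.0
            med = np.where(z_side >= mid, ve_ap, ve_ba)
            ve_vals[side_rows] = med + rng.normal(0, regime.ve_spread,
                                                  side_rows.sum())
    ve_vals = np.clip(ve_vals, 0.05, 0.95)
    kt_vals = np.exp(rng.normal(np.log(regime.ktrans_median),
                                regime.ktrans_log_spread, n_lung))
    vp_vals = np.clip(rng.normal(regime.vp_median, regime.vp_spread, n_lung),
                      0.01, 0.9)
    vp_vals = np.minimum(vp_vals, 0.98 - ve_vals)  # enforce ve + vp <= 1
    ve[lung] = ve_vals
    ktrans[lung] = kt_vals
    vp[lung] = vp_vals
    t10[lung] = np.clip(rng.normal(regime.t1_msec, regime.t1_spread_msec,
                                   n_lung), 200, 3000)
    s0[lung] = regime.qs0 * MUSCLE_S0 * \
        (1.0 + rng.normal(0, regime.s0_spread_frac, n_lung))

    n_mus = int(regions.muscle.sum())
    ktrans[regions.muscle] = 0.03
    ve[regions.muscle] = 0.12
    vp[regions.muscle] = 0.03
    t10[regions.muscle] = np.clip(rng.normal(MUSCLE_T1_MSEC, 20.0, n_mus),
                                  200, 3000)
    s0[regions.muscle] = MUSCLE_S0 * (1.0 + rng.normal(0, 0.01, n_mus))

    t10[regions.vessel] = BLOOD_T1_MSEC
    s0[regions.vessel] = BLOOD_S0
    # vessel kinetics handled specially in simulate_acquisition (blood pool)

    gt = GroundTruth(ktrans, ve, vp, t10, s0, hematocrit=hematocrit)
    return regions, gt


def population_aif(protocol: AcquisitionProtocol,
                   bolus_arrival_sec: float | None = None,
                   dose_mmol_per_kg: float | None = None) -> PlasmaCurve:
    """Generative population plasma curve on the protocol's dynamic grid.

    A mixed-Gaussian first/second-pass bolus plus a sigmoid-gated exponential
    washout (Parker-type shape), linearly scaled by dose relative to the
    0.1 mmol/kg reference, and identically zero before bolus arrival. The
    default arrival is the start of the injection dynamic.
    """
    if bolus_arrival_sec is None:
        bolus_arrival_sec = protocol.injection_time_sec
    times = protocol.dynamic_times_sec
    if bolus_arrival_sec < 0:
        raise ValueError("bolus arrival must be nonnegative")
    if bolus_arrival_sec > times[-1]:
        raise ValueError(
            f"bolus arrival {bolus_arrival_sec} s lies beyond the end of the "
            f"acquisition ({times[-1]} s)"
        )
    dose = protocol.dose_mmol_per_kg if dose_mmol_per_kg is None \
        else dose_mmol_per_kg
    t_min = (times - bolus_arrival_sec) / 60.0
    p = _AIF_PARAMS
    with np.errstate(over="ignore"):
        g1 = p["a1"] / (p["s1"] * np.sqrt(2 * np.pi)) * \
            np.exp(-((t_min - p["m1"]) ** 2) / (2 * p["s1"] ** 2))
        g2 = p["a2"] / (p["s2"] * np.sqrt(2 * np.pi)) * \
            np.exp(-((t_min - p["m2"]) ** 2) / (2 * p["s2"] ** 2))
        washout = p["alpha"] * np.exp(-p["beta"] * t_min) / \
            (1.0 + np.exp(-p["s"] * (t_min - p["tau"])))
    cp = (g1 + g2 + washout) * (dose / 0.1)
    cp[t_min < 0] = 0.0
    return PlasmaCurve(times_sec=times, cp_mM=np.maximum(cp, 0.0))


def _add_noise(rng: np.random.Generator, clean: np.ndarray, sd: float,
               model: str) -> np.ndarray:
    if sd == 0:
        return clean.copy()
    if model == "rician":
        n1 = rng.normal(0.0, sd, clean.shape)
        n2 = rng.normal(0.0, sd, clean.shape)
        return np.sqrt((clean + n1) ** 2 + n2 ** 2)
    if model == "gaussian":
        return clean + rng.normal(0.0, sd, clean.shape)
    raise ValueError(f"unknown noise model {model!r}")


def default_noise_sd(gt: GroundTruth, regions: RegionSet,
                     protocol: AcquisitionProtocol, snr: float = 50.0) -> float:
    """Noise scale giving the requested baseline SNR in the lung parenchyma."""
    lung = regions.lung
    base = spgr_signal(gt.s0_map[lung], gt.t10_map[lung], protocol.tr_msec,
                       protocol.dynamic_flip_deg)
    return float(np.median(base) / snr)


def simulate_acquisition(
    gt: GroundTruth, aif: PlasmaCurve, protocol: AcquisitionProtocol,
    regions: RegionSet, noise_sd: float, seed: int,
    noise_model: str = "rician",
) -> tuple[VolumeSeries, VolumeSeries]:
    """Forward-simulate the VFA stack and dynamic series.

    Tissue concentration follows the extended Tofts forward model from the
    plasma curve; vessel voxels carry the whole-blood concentration
    Cp * (1 - Hct), so the measurement chain must re-apply the hematocrit
    correction. Concentration modulates 1/T1 linearly via the protocol
    relaxivity, and signal follows the SPGR equation. Rician (default) or
    Gaussian noise of scale ``noise_sd`` is added reproducibly from ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if aif.times_sec.shape != protocol.dynamic_times_sec.shape or \
            not np.allclose(aif.times_sec, protocol.dynamic_times_sec):
        raise ValueError("AIF grid inconsistent with protocol timing")
    rng = np.random.default_rng(seed)
    shape = gt.s0_map.shape
    tissue = regions.lung | regions.muscle
    r1 = protocol.relaxivity_per_mM_per_sec

    # --- dynamic series -----------------------------------------------------
    n_t = protocol.n_dynamics
    conc = np.zeros((int(tissue.sum()) + int(regions.vessel.sum()), n_t))
    rows_tissue = slice(0, int(tissue.sum()))
    rows_vessel = slice(int(tissue.sum()), conc.shape[0])
    conc[rows_tissue] = extended_tofts_forward(
        gt.ktrans_map[tissue], gt.ve_map[tissue], gt.vp_map[tissue], aif
    )
    conc[rows_vessel] = aif.cp_mM[None, :] * (1.0 - gt.hematocrit)

    imaged = tissue | regions.vessel
    t10 = np.concatenate([gt.t10_map[tissue], gt.t10_map[regions.vessel]])
    s0 = np.concatenate([gt.s0_map[tissue], gt.s0_map[regions.vessel]])
    with np.errstate(divide="ignore"):
        r1_t = 1000.0 / t10[:, None] + r1 * conc     # s^-1
    t1_t = 1000.0 / r1_t                             # ms
    sig = spgr_signal(s0[:, None], t1_t, protocol.tr_msec,
                      protocol.dynamic_flip_deg)

    dyn_clean = np.zeros(shape + (n_t,))
    stacked = np.vstack([np.argwhere(tissue), np.argwhere(regions.vessel)])
    dyn_clean[stacked[:, 0], stacked[:, 1], stacked[:, 2], :] = sig
    dyn_data = _add_noise(rng, dyn_clean, noise_sd, noise_model)
    dyn = VolumeSeries(dyn_data, regions.affine,
                       times_sec=protocol.dynamic_times_sec)

    # --- VFA stack ----------------------------------------------------------
    angles = np.repeat(np.asarray(protocol.flip_angles_deg, float),
                       protocol.vfa_repeats)
    vfa_clean = np.zeros(shape + (angles.size,))
    t10_full = gt.t10_map
    s0_full = gt.s0_map
    for v, a in enumerate(angles):
        vol = np.zeros(shape)
        vol[imaged] = spgr_signal(s0_full[imaged], t10_full[imaged],
                                  protocol.tr_msec, a)
        vfa_clean[..., v] = vol
    vfa_data = _add_noise(rng, vfa_clean, noise_sd, noise_model)
    vfa = VolumeSeries(vfa_data, regions.affine, flip_angles_deg=angles)
    return vfa, dyn
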