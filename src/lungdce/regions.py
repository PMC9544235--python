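"""Lung subregion partition and per-subject endpoint extraction.

Each lung is split into an apical and a basal segment at the midpoint
between the lung apex and its most inferior extent along the foot-head
direction, computed on voxel-center physical coordinates (mm) so the rule is
robust to anisotropic voxels. Voxel values are then summarized per region —
median for Ktrans, ve, T1, qS0 and qS0*ve; mean for vp — into a tidy
endpoint table, one row per subject x session x region x endpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import foot_head_axis, world_z_coordinates
from .kinetics import ToftsFitResult
from .relaxometry import QS0Map

log = logging.getLogger("lungdce")

SUBREGIONS = ("apical-left", "basal-left", "apical-right", "basal-right")
REGIONS = ("total", "left", "right") + SUBREGIONS
MEDIAN_ENDPOINTS = ("ktrans", "ve", "t1", "qs0", "qs0ve")


@dataclass
class SubregionPartition:
    """Per-voxel subregion labels covering exactly the lung mask.

    ``labels`` maps voxel -> name in :data:`SUBREGIONS` (empty string outside
    the lungs). Apical voxels satisfy foot-head coordinate >= that lung's
    midpoint; ties go apical.
    """

    labels: np.ndarray  # array of str
    midpoint_mm: dict[str, float]  # per lung: "left", "right"

    def region_mask(self, region: str) -> np.ndarray:
        if region == "total":
            return self.labels != ""
        if region == "left":
            return np.isin(self.labels, ["apical-left", "basal-left"])
        if region == "right":
            return np.isin(self.labels, ["apical-right", "basal-right"])
        if region in SUBREGIONS:
            return self.labels == region
        raise ValueError(f"unknown region {region!r}")


def partition_lungs(lung_left: np.ndarray, lung_right: np.ndarray,
                    affine: np.ndarray) -> SubregionPartition:
    """Split each lung into apical/basal halves at its foot-head midpoint.

    The midpoint is ``(max + min) / 2`` of the voxel-center foot-head
    coordinates of that lung's voxels; each lung gets its own midpoint.
    Raises ``ValueError`` for an empty lung mask or an affine from which no
    foot-head axis can be identified.
    """
    lung_left = np.asarray(lung_left, bool)
    lung_right = np.asarray(lung_right, bool)
    if not lung_left.any():
        raise ValueError("left lung mask is empty")
    if not lung_right.any():
        raise ValueError("right lung mask is empty")
    if (lung_left & lung_right).any():
        raise ValueError("left and right lung masks overlap")
    foot_head_axis(affine)  # raises if unidentifiable
    z_mm = world_z_coordinates(affine, lung_left.shape)

    labels = np.full(lung_left.shape, "", dtype=object)
    midpoints: dict[str, float] = {}
    for side, mask in (("left", lung_left), ("right", lung_right)):
        z_side = z_mm[mask]
        mid = (z_side.max() + z_side.min()) / 2.0
        midpoints[side] = float(mid)
        apical = mask & (z_mm >= mid)
        basal = mask & (z_mm < mid)
        labels[apical] = f"apical-{side}"
        labels[basal] = f"basal-{side}"
    return SubregionPartition(labels=labels, midpoint_mm=midpoints)


def compute_qs0ve(qs0: QS0Map, tofts: ToftsFitResult) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise qS0 * ve — extravascular extracellular water content index.

    Returns ``(map, valid)``; a voxel is valid only where both factors are
    finite and the kinetic fit is valid. Raises on grid mismatch.
    """
    if qs0.qs0_map.shape != tofts.ve_map.shape:
        raise ValueError("qS0 and ve maps are on different grids")
    prod = qs0.qs0_map * tofts.ve_map
    valid = np.isfinite(qs0.qs0_map) & np.isfinite(tofts.ve_map) & \
        tofts.valid_mask
    return prod, valid


def summarize_endpoints(
    maps: dict[str, tuple[np.ndarray, np.ndarray]],
    partition: SubregionPartition,
    subject_id: str,
    session: int,
    group: str,
    vp_mode: str = "subregion-means",
) -> pd.DataFrame:
    """Extract the per-region endpoint summaries into tidy rows.

    ``maps`` maps endpoint name ("ktrans", "ve", "vp", "t1", "qs0", "qs0ve")
    to ``(value_map, valid_mask)``. Median endpoints are summarized per
    region directly over valid voxels. vp uses means: with the default
    ``vp_mode="subregion-means"`` the left/right/total vp values average the
    constituent subregion means (the total is the mean across the four
    subregions); ``vp_mode="voxels"`` takes the plain voxel mean over each
    region instead. Regions with no valid voxels are omitted with a warning.
    """
    if vp_mode not in ("subregion-means", "voxels"):
        raise ValueError(f"unknown vp_mode {vp_mode!r}")
    rows = []

    def region_values(vmap, valid, region):
        m = partition.region_mask(region) & valid & np.isfinite(vmap)
        return vmap[m]

    for endpoint, (vmap, valid) in maps.items():
        if endpoint == "vp":
            sub_means = {}
            for sub in SUBREGIONS:
                vals = region_values(vmap, valid, sub)
                if vals.size == 0:
                    log.warning("summarize_endpoints: no valid voxels for %s "
                                "in %s; row omitted", endpoint, sub)
                    continue
                sub_means[sub] = float(np.mean(vals))
                rows.append((subject_id, group, session, sub, endpoint,
                             sub_means[sub], "mean"))
            for region, parts in (
                ("left", ("apical-left", "basal-left")),
                ("right", ("apical-right", "basal-right")),
                ("total", SUBREGIONS),
            ):
                if vp_mode == "subregion-means":
                    have = [sub_means[p] for p in parts if p in sub_means]
                    if not have:
                        log.warning("summarize_endpoints: no valid voxels for "
                                    "%s in %s; row omitted", endpoint, region)
                        continue
                    value = float(np.mean(have))
                else:
                    vals = region_values(vmap, valid, region)
                    if vals.size == 0:
                        log.warning("summarize_endpoints: no valid voxels for "
                                    "%s in %s; row omitted", endpoint, region)
                        continue
                    value = float(np.mean(vals))
                rows.append((subject_id, group, session, region, endpoint,
                             value, "mean"))
        else:
            for region in REGIONS:
                vals = region_values(vmap, valid, region)
                if vals.size == 0:
                    log.warning("summarize_endpoints: no valid voxels for %s "
                                "in %s; row omitted", endpoint, region)
                    continue
                rows.append((subject_id, group, session, region, endpoint,
                             float(np.median(vals)), "median"))
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "session", "region",
                       "endpoint", "value", "summary"],
    )
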