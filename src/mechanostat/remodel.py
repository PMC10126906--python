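"""Surface (re)modeling analysis of registered baseline/follow-up image pairs.

Given two registered binary bone images and a trabecular-compartment mask,
this module classifies each baseline surface voxel as a formation,
quiescence, or resorption site and attaches a signed (re)modeling distance
in voxel units:

1.  Voxel set algebra splits bone into formed (follow-up only), resorbed
    (baseline only) and quiescent (both) clusters (6-connectivity).
2.  A taxicab (city-block) distance transform of the follow-up image gives
    the thickness of formed bone; the transform of the inverted follow-up
    gives the depth of resorption.
3.  Formation surfaces receive distance values by gray-dilating the
    transform over the formed clusters onto the adjacent baseline surface
    (von Neumann neighborhood, maximum aggregator); resorption surfaces
    take their own transform value from the inverted image.
4.  Per cluster, distances are rescaled by a single factor so their sum
    equals the cluster's voxel volume — the surface-distance representation
    conserves (re)modeled volume exactly.

The result is a per-surface-voxel table (pandas DataFrame) with event
labels and signed distances: positive formation, negative resorption, zero
quiescence.  Out-of-bounds voxels count as background throughout (surfaces
and distance transforms), a conservative choice on cropped fields of view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .gridio import BinaryVolume, ScalarVolume

__all__ = [
    "RemodelingVolumes",
    "ClusterLabels",
    "TABLE_COLUMNS",
    "classify_remodeling",
    "surface_mask",
    "label_clusters",
    "label_event_surfaces",
    "taxicab_dt",
    "project_distances",
    "scale_cluster_distances",
    "build_surface_table",
]

logger = logging.getLogger(__name__)

#: 6-connectivity structuring element (von Neumann neighborhood)
STRUCT_6 = ndimage.generate_binary_structure(3, 1)

#: column order of the surface sample table
TABLE_COLUMNS = ["z", "y", "x", "event", "distance_vox", "cluster_id", "signal"]

#: the six face-neighbor offsets, fixed order for deterministic tie-breaks
FACE_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


@dataclass
class RemodelingVolumes:
    """Disjoint formed / resorbed / quiescent bone sets within the mask."""

    formed: BinaryVolume
    resorbed: BinaryVolume
    quiescent_bone: BinaryVolume


@dataclass
class ClusterLabels:
    """Connected-component labels (0 = background) and per-cluster volumes."""

    labels: np.ndarray
    volumes: dict[int, int]


def _check_compatible(*vols: ScalarVolume) -> None:
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ValueError(f"volume shape mismatch: {shapes}")
    sizes = {v.voxel_size for v in vols}
    if len(sizes) != 1:
        raise ValueError(f"voxel size mismatch: {sizes}")


def classify_remodeling(
    baseline: BinaryVolume, followup: BinaryVolume, trab_mask: BinaryVolume
) -> RemodelingVolumes:
    """Split bone voxels into formed, resorbed and quiescent sets.

    All three outputs are restricted to the trabecular mask:
    formed = follow-up AND NOT baseline, resorbed = baseline AND NOT
    follow-up, quiescent = baseline AND follow-up.
    """
    _check_compatible(baseline, followup, trab_mask)
    mask = trab_mask.bool_data
    if not mask.any():
        raise ValueError("empty trabecular mask")
    b = baseline.bool_data & mask
    f = followup.bool_data & mask
    vs = baseline.voxel_size
    return RemodelingVolumes(
        formed=BinaryVolume((f & ~b).astype(np.uint8), vs),
        resorbed=BinaryVolume((b & ~f).astype(np.uint8), vs),
        quiescent_bone=BinaryVolume((b & f).astype(np.uint8), vs),
    )


def surface_mask(bone: BinaryVolume) -> BinaryVolume:
    """Surface voxels: bone voxels with >= 1 background face-neighbor.

    Out-of-bounds counts as background, so voxels on the volume boundary
    are surface.
    """
    fg = bone.bool_data
    interior = ndimage.binary_erosion(fg, structure=STRUCT_6, border_value=0)
    return BinaryVolume((fg & ~interior).astype(np.uint8), bone.voxel_size)


def label_clusters(vol: BinaryVolume) -> ClusterLabels:
    """6-connected component labeling with per-cluster voxel counts."""
    labels, n = ndimage.label(vol.bool_data, structure=STRUCT_6)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    return ClusterLabels(labels, {k: int(counts[k]) for k in range(1, n + 1)})


def label_event_surfaces(
    baseline_surface: BinaryVolume, rem: RemodelingVolumes
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Partition the baseline surface into formation/resorption/quiescence.

    Formation surface: baseline surface voxels touching a formed cluster
    (von Neumann dilation overlap).  Resorption surface: baseline surface
    voxels that are themselves resorbed.  Quiescent: the rest.  A voxel
    qualifying as both is labeled resorption (the voxel itself changed);
    the number of such collisions is returned and logged.

    Returns ``(formation, resorption, quiescence)`` boolean arrays and the
    collision count.
    """
    surf = baseline_surface.bool_data
    formed_dil = ndimage.binary_dilation(rem.formed.bool_data, structure=STRUCT_6)
    formation = surf & formed_dil
    resorption = surf & rem.resorbed.bool_data
    collisions = int((formation & resorption).sum())
    if collisions:
        logger.warning(
            "%d surface voxels qualify as both formation and resorption; "
            "labeled resorption",
            collisions,
        )
    formation &= ~resorption
    quiescence = surf & ~formation & ~resorption
    return formation, resorption, quiescence, collisions


def taxicab_dt(bone: BinaryVolume) -> ScalarVolume:
    """City-block (L1) distance to the nearest background voxel.

    Background voxels get 0; out-of-bounds is treated as background, which
    is enforced by zero-padding before the transform.
    """
    padded = np.pad(bone.bool_data, 1)
    dt = ndimage.distance_transform_cdt(padded, metric="taxicab")
    return ScalarVolume(
        dt[1:-1, 1:-1, 1:-1].astype(np.float64), bone.voxel_size
    )


def _shifted(arr: np.ndarray, off: tuple[int, int, int], fill=0) -> np.ndarray:
    """Array of neighbor values: out[i] = arr[i + off], out-of-bounds = fill."""
    out = np.full_like(arr, fill)
    src = tuple(
        slice(max(o, 0), arr.shape[a] + min(o, 0)) for a, o in enumerate(off)
    )
    dst = tuple(
        slice(max(-o, 0), arr.shape[a] + min(-o, 0)) for a, o in enumerate(off)
    )
    out[dst] = arr[src]
    return out


def project_distances(
    dt: ScalarVolume,
    clusters: ClusterLabels,
    event_surface: np.ndarray,
    event: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collect raw (re)modeling distances on an event surface.

    ``event="formation"``: each formation surface voxel takes the maximum
    distance-transform value among its 6-neighbors inside a formed cluster
    (gray dilation restricted to the clusters), attributed to the cluster
    of the maximizing neighbor (smallest cluster id on ties).

    ``event="resorption"``: each resorption surface voxel takes its own
    value from ``dt`` (computed on the inverted follow-up) and its own
    cluster id.

    Returns flat arrays ``(zyx_indices [n,3], raw_distance [n],
    cluster_id [n])`` over the event-surface voxels, in C scan order.
    """
    surf = np.asarray(event_surface, dtype=bool)
    idx = np.argwhere(surf)
    if event == "resorption":
        raw = dt.data[surf]
        cid = clusters.labels[surf]
        return idx, raw.astype(np.float64), cid.astype(np.int64)
    if event != "formation":
        raise ValueError(f"unknown event: {event}")

    in_cluster = clusters.labels > 0
    masked_dt = np.where(in_cluster, dt.data, -np.inf)
    best = np.full(dt.data.shape, -np.inf)
    best_label = np.zeros(dt.data.shape, dtype=np.int64)
    for off in FACE_OFFSETS:
        nb_dt = _shifted(masked_dt, off, fill=-np.inf)
        nb_lab = _shifted(clusters.labels, off, fill=0)
        better = nb_dt > best
        tie = (nb_dt == best) & (nb_lab > 0) & (
            (best_label == 0) | (nb_lab < best_label)
        )
        take = better | tie
        best = np.where(take, nb_dt, best)
        best_label = np.where(take, nb_lab, best_label)
    raw = best[surf]
    cid = best_label[surf]
    if np.any(~np.isfinite(raw)):
        raise ValueError(
            "formation surface voxel with no formed 6-neighbor "
            "(inconsistent inputs)"
        )
    return idx, raw.astype(np.float64), cid.astype(np.int64)


def scale_cluster_distances(
    raw: np.ndarray, cluster_ids: np.ndarray, volumes: dict[int, int]
) -> tuple[np.ndarray, list[int]]:
    """Rescale raw distances so each cluster's sum equals its voxel volume.

    Per cluster k the factor is ``volume(k) / sum(raw distances of k)``;
    afterwards the scaled distances of k sum to volume(k) exactly.  Clusters
    with no projected surface voxel (orphans, e.g. free-floating islands)
    cannot be represented on the surface; their ids are returned for QC
    instead of distorting other clusters.
    """
    raw = np.asarray(raw, dtype=np.float64)
    cluster_ids = np.asarray(cluster_ids)
    scaled = np.zeros_like(raw)
    seen = set()
    for k in np.unique(cluster_ids):
        if k == 0:
            continue
        sel = cluster_ids == k
        s = raw[sel].sum()
        if s <= 0:
            raise ValueError(f"cluster {k} has zero projected distance sum")
        scaled[sel] = raw[sel] * (volumes[int(k)] / s)
        seen.add(int(k))
    orphans = sorted(set(volumes) - seen)
    return scaled, orphans


def build_surface_table(
    baseline: BinaryVolume,
    followup: BinaryVolume,
    trab_mask: BinaryVolume,
) -> tuple[pd.DataFrame, dict]:
    """Full surface (re)modeling table for a registered image pair.

    Returns a DataFrame with one row per baseline trabecular surface voxel
    (columns ``z, y, x, event, distance_vox, cluster_id, signal``; signal
    is NaN until filled by the mechanical-signal sampler) and a QC dict
    with event counts, label collisions and orphan-cluster volumes.
    """
    rem = classify_remodeling(baseline, followup, trab_mask)
    vs = baseline.voxel_size
    mask = trab_mask.bool_data
    base_bone = BinaryVolume(
        (baseline.bool_data & mask).astype(np.uint8), vs
    )
    follow_bone = BinaryVolume(
        (followup.bool_data & mask).astype(np.uint8), vs
    )
    bsurf = surface_mask(base_bone)
    formation, resorption, quiescence, collisions = label_event_surfaces(bsurf, rem)

    formed_clusters = label_clusters(rem.formed)
    resorbed_clusters = label_clusters(rem.resorbed)

    dt_follow = taxicab_dt(follow_bone)
    inv_follow = BinaryVolume((1 - follow_bone.data).astype(np.uint8), vs)
    dt_inv = taxicab_dt(inv_follow)

    parts = []
    qc: dict = {"label_collisions": collisions}
    for event, surf, dt, clusters in (
        ("formation", formation, dt_follow, formed_clusters),
        ("resorption", resorption, dt_inv, resorbed_clusters),
    ):
        idx, raw, cid = project_distances(dt, clusters, surf, event)
        if len(raw):
            scaled, orphans = scale_cluster_distances(raw, cid, clusters.volumes)
        else:
            scaled, orphans = raw, sorted(clusters.volumes)
        sign = 1.0 if event == "formation" else -1.0
        parts.append(
            pd.DataFrame(
                {
                    "z": idx[:, 0],
                    "y": idx[:, 1],
                    "x": idx[:, 2],
                    "event": event,
                    "distance_vox": sign * scaled,
                    "cluster_id": cid,
                }
            )
        )
        qc[f"orphan_{event}_clusters"] = {
            int(k): clusters.volumes[int(k)] for k in orphans
        }
        qc[f"n_{event}_surface"] = int(len(raw))
    qidx = np.argwhere(quiescence)
    parts.append(
        pd.DataFrame(
            {
                "z": qidx[:, 0],
                "y": qidx[:, 1],
                "x": qidx[:, 2],
                "event": "quiescence",
                "distance_vox": 0.0,
                "cluster_id": -1,
            }
        )
    )
    qc["n_quiescence_surface"] = int(len(qidx))
    qc["n_formed_voxels"] = int(rem.formed.data.sum())
    qc["n_resorbed_voxels"] = int(rem.resorbed.data.sum())
    table = pd.concat(parts, ignore_index=True)
    table["signal"] = np.nan
    for orphans in (qc["orphan_formation_clusters"], qc["orphan_resorption_clusters"]):
        if orphans:
            logger.warning("orphan clusters (no surface voxel): %s", orphans)
    return table[TABLE_COLUMNS], qc
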