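"""Network-node construction from a thresholded ALE map.

Three filters turn the suprathreshold ALE landscape into nodes:

1. *Region rule*: an atlas region counts as altered only if at least
   ``min_region_voxels`` (default 20) of its voxels are suprathreshold.
2. *Peak filter*: local maxima (26-connectivity) with ALE value above the
   90th percentile of the suprathreshold value distribution.
3. *Interpeak distance*: greedy suppression so every kept peak is at least
   ``min_interpeak_mm`` (default 10 mm, the mean spatial-location
   uncertainty of reported coordinates) from every other.

Surviving peaks become atlas-labeled nodes, numbered within each region by
a rostrocaudal (descending y) criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .ale import AleMap
from .io import AtlasVolume

logger = logging.getLogger(__name__)

#: 26-connectivity structure for local-maximum detection.
PEAK_STRUCTURE = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class RegionAlteration:
    """Suprathreshold voxel count of one atlas region."""

    atlas_label: int
    region_name: str
    altered_voxel_count: int
    passes: bool


@dataclass(frozen=True)
class Peak:
    """A suprathreshold local maximum of the ALE map."""

    voxel: tuple[int, int, int]
    xyz: tuple[float, float, float]
    ale_value: float


@dataclass(frozen=True)
class NetworkNode:
    """An atlas-labeled ALE peak — the unit of the coalteration analysis."""

    id: str
    region_name: str
    hemisphere: str
    x: float
    y: float
    z: float
    ale_value: float
    atlas_label: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


def altered_regions(thresholded_ale: AleMap, atlas: AtlasVolume,
                    min_region_voxels: int = 20) -> list[RegionAlteration]:
    """Count suprathreshold voxels per atlas region and apply the region rule.

    A region passes iff at least ``min_region_voxels`` of its voxels carry a
    nonzero (surviving) ALE value; background (label 0) is excluded.
    """
    if not thresholded_ale.grid.same_geometry(atlas.grid):
        raise ValueError("ALE map and atlas do not share a grid")
    supra = thresholded_ale.values > 0
    counts = np.bincount(atlas.labels[supra].ravel(),
                         minlength=max(atlas.label_table, default=0) + 1)
    out = []
    for label in sorted(atlas.label_table):
        c = int(counts[label]) if label < len(counts) else 0
        out.append(RegionAlteration(
            atlas_label=label, region_name=atlas.name_of(label),
            altered_voxel_count=c, passes=c >= min_region_voxels))
    return out


def detect_peaks(thresholded_ale: AleMap, percentile: float = 90.0,
                 basis: str = "voxels") -> list[Peak]:
    """Suprathreshold local maxima above a value-distribution percentile.

    Local maxima are voxels whose value is >= all 26 neighbors; a connected
    plateau of equal-valued maxima contributes a single peak at the voxel
    nearest its centroid.  Peaks are kept when their value is strictly
    greater than the ``percentile`` of the suprathreshold voxel values
    (``basis="voxels"``) or of the candidate peak values
    (``basis="peaks"``).
    """
    if not 0.0 <= percentile < 100.0:
        raise ValueError("percentile must be in [0, 100)")
    if basis not in ("voxels", "peaks"):
        raise ValueError(f"unknown percentile basis {basis!r}")
    values = thresholded_ale.values
    supra = values > 0
    if not np.any(supra):
        return []
    local_max = (values == ndimage.maximum_filter(
        values, footprint=PEAK_STRUCTURE, mode="constant", cval=-np.inf))
    candidates = local_max & supra

    # collapse plateaus: one peak per connected component of candidates
    labeled, n_comp = ndimage.label(candidates, structure=PEAK_STRUCTURE)
    peaks: list[Peak] = []
    grid = thresholded_ale.grid
    for comp in range(1, n_comp + 1):
        vox = np.argwhere(labeled == comp)
        if vox.shape[0] == 1:
            chosen = vox[0]
        else:
            centroid = vox.mean(axis=0)
            d2 = np.sum((vox - centroid) ** 2, axis=1)
            order = np.lexsort((vox[:, 2], vox[:, 1], vox[:, 0], d2))
            chosen = vox[order[0]]
        xyz = grid.voxel_to_world(chosen)
        peaks.append(Peak(voxel=tuple(int(v) for v in chosen),
                          xyz=tuple(float(v) for v in xyz),
                          ale_value=float(values[tuple(chosen)])))

    if percentile == 0:  # comparison is strict, so 0 means "no filter"
        return _sorted_peaks(peaks)
    if basis == "voxels":
        cutoff = float(np.percentile(values[supra], percentile))
    else:
        cutoff = float(np.percentile([p.ale_value for p in peaks], percentile))
    kept = [p for p in peaks if p.ale_value > cutoff]
    return _sorted_peaks(kept)


def _sorted_peaks(peaks: list[Peak]) -> list[Peak]:
    """Canonical order: descending value, ties lexicographic by voxel index."""
    return sorted(peaks, key=lambda p: (-p.ale_value, p.voxel))


def enforce_interpeak_distance(peaks: list[Peak],
                               min_interpeak_mm: float = 10.0) -> list[Peak]:
    """Greedy non-maximum suppression at a minimum peak separation.

    Peaks are visited in descending value order (ties broken by voxel
    index, so the result is independent of input order); a peak is kept iff
    its Euclidean distance to every already-kept peak is >=
    ``min_interpeak_mm`` (inclusive at the boundary).
    """
    kept: list[Peak] = []
    kept_xyz: list[np.ndarray] = []
    for p in _sorted_peaks(peaks):
        xyz = np.asarray(p.xyz)
        if all(np.linalg.norm(xyz - q) >= min_interpeak_mm for q in kept_xyz):
            kept.append(p)
            kept_xyz.append(xyz)
    return kept


def label_nodes(peaks: list[Peak], atlas: AtlasVolume,
                regions: list[RegionAlteration]) -> list[NetworkNode]:
    """Turn distance-filtered peaks into atlas-labeled nodes.

    Peaks in background or in regions failing the region rule are dropped
    (logged).  Within each region, nodes are numbered ``_1, _2, ...`` by
    descending y (anterior to posterior); equal-y ties break by descending
    ALE value.
    """
    passing = {r.atlas_label for r in regions if r.passes}
    by_region: dict[int, list[Peak]] = {}
    for p in peaks:
        label = int(atlas.labels[p.voxel])
        if label == 0:
            logger.warning("peak at %s lies in background; dropped", p.xyz)
            continue
        if label not in passing:
            logger.info("peak at %s lies in non-passing region %s; dropped",
                        p.xyz, atlas.name_of(label))
            continue
        by_region.setdefault(label, []).append(p)

    nodes: list[NetworkNode] = []
    for label in sorted(by_region):
        name = atlas.name_of(label)
        hemi = atlas.hemisphere_of(label)
        ordered = sorted(by_region[label],
                         key=lambda p: (-p.xyz[1], -p.ale_value, p.voxel))
        for k, p in enumerate(ordered, start=1):
            nodes.append(NetworkNode(
                id=f"{name}_{k}", region_name=name, hemisphere=hemi,
                x=p.xyz[0], y=p.xyz[1], z=p.xyz[2],
                ale_value=p.ale_value, atlas_label=label))
    return nodes


def build_nodes(thresholded_ale: AleMap, atlas: AtlasVolume,
                min_region_voxels: int = 20, percentile: float = 90.0,
                min_interpeak_mm: float = 10.0, basis: str = "voxels",
                region_filter: str = "after") -> list[NetworkNode]:
    """Full node-construction chain.

    ``region_filter`` controls whether peaks in non-passing regions are
    removed after the interpeak-distance filter (default: a strong peak in
    a failing region still suppresses nearby peaks) or before it.
    """
    if region_filter not in ("after", "before"):
        raise ValueError(f"unknown region_filter {region_filter!r}")
    regions = altered_regions(thresholded_ale, atlas, min_region_voxels)
    peaks = detect_peaks(thresholded_ale, percentile, basis=basis)
    if region_filter == "before":
        passing = {r.atlas_label for r in regions if r.passes}
        peaks = [p for p in peaks if int(atlas.labels[p.voxel]) in passing]
    peaks = enforce_interpeak_distance(peaks, min_interpeak_mm)
    return label_nodes(peaks, atlas, regions)
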