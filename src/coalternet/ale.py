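"""Anatomical likelihood estimation (ALE).

Each experiment's foci are smoothed with an isotropic 3-D Gaussian kernel to
form a modeled-alteration (MA) map: per voxel, the probability that the
experiment's alteration lies there, combined across the experiment's foci by
voxel-wise maximum so repeated reports of the same locus are not double
counted.  MA maps are united across experiments by the probabilistic union
``ALE = 1 - prod(1 - MA_i)``, and the ALE map is thresholded against a
Monte-Carlo null built from experiments with the same foci counts but
uniformly random in-mask locations (voxel-level FWE via the max statistic,
or a cluster-size null).

Kernel values are converted from density to per-voxel probability by
multiplying by the voxel volume, which keeps MA values in [0, 1] as the
union formula requires; :func:`gaussian_prob` itself returns the raw
density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid
from .io import Experiment

logger = logging.getLogger(__name__)

#: 6-connectivity structure used for cluster formation in the cluster-size null.
CLUSTER_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def sigma_from_fwhm(fwhm_mm: float) -> float:
    """Gaussian SD from full-width-half-maximum: FWHM / sqrt(8 ln 2)."""
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    return float(fwhm_mm) / np.sqrt(8.0 * np.log(2.0))


def gaussian_prob(d, sigma_mm: float):
    """Isotropic 3-D Gaussian density at Euclidean distance ``d`` (mm).

    ``p(d) = (sigma^3 (2 pi)^{3/2})^{-1} exp(-d^2 / (2 sigma^2))`` — a
    density over R^3 (integrates to 1), strictly decreasing in ``d``.
    """
    d = np.asarray(d, dtype=float)
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    norm = 1.0 / (sigma_mm ** 3 * (2.0 * np.pi) ** 1.5)
    out = norm * np.exp(-(d ** 2) / (2.0 * sigma_mm ** 2))
    return float(out) if out.ndim == 0 else out


@dataclass
class MaMap:
    """Modeled-alteration map of one experiment (per-voxel probability)."""

    grid: VolumeGrid
    values: np.ndarray
    experiment_id: str


@dataclass
class AleMap:
    """ALE map: probabilistic union of MA maps over experiments."""

    grid: VolumeGrid
    values: np.ndarray
    n_experiments: int
    fwhm_mm: float
    threshold_value: float | None = None
    mask: np.ndarray | None = None

    @property
    def n_suprathreshold(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass
class NullDistribution:
    """Monte-Carlo null of an ALE summary statistic."""

    kind: str  # "voxel_max" or "cluster_size"
    samples: np.ndarray
    n_iterations: int
    seed: int | None
    cluster_forming: float | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (self.n_iterations,):
            raise ValueError("samples length must equal n_iterations")


def _kernel_offsets(grid: VolumeGrid, fwhm_mm: float,
                    trunc_factor: float) -> tuple[int, np.ndarray]:
    """Per-voxel kernel probabilities on a cubic stencil.

    Returns the stencil half-width in voxels and a (2r+1)^3 array of
    ``density * voxel_volume``, zeroed beyond the truncation radius.
    """
    sigma = sigma_from_fwhm(fwhm_mm)
    radius_mm = trunc_factor * fwhm_mm
    r = int(np.floor(radius_mm / grid.voxel_size))
    ax = np.arange(-r, r + 1) * grid.voxel_size
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    dist = np.sqrt(dx ** 2 + dy ** 2 + dz ** 2)
    kern = gaussian_prob(dist, sigma) * grid.voxel_volume
    kern[dist > radius_mm] = 0.0
    return r, kern


def _stamp_max(values: np.ndarray, vox: np.ndarray, r: int,
               kern: np.ndarray, dims: tuple[int, int, int]) -> None:
    """Max-accumulate the kernel stencil centered at voxel ``vox`` in place."""
    lo = vox - r
    hi = vox + r + 1
    klo = np.maximum(0, -lo)
    khi = (2 * r + 1) - np.maximum(0, hi - np.asarray(dims))
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, dims)
    if np.any(lo >= hi):
        return
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    ksl = tuple(slice(a, b) for a, b in zip(klo, khi))
    np.maximum(values[sl], kern[ksl], out=values[sl])


def _ma_values_from_voxels(vox_list: np.ndarray, grid: VolumeGrid, r: int,
                           kern: np.ndarray) -> np.ndarray:
    values = np.zeros(grid.dims, dtype=float)
    for vox in vox_list:
        _stamp_max(values, vox, r, kern, grid.dims)
    return values


def ma_map(experiment: Experiment, grid: VolumeGrid, fwhm_mm: float = 10.0,
           mask: np.ndarray | None = None,
           trunc_factor: float = 3.0) -> MaMap:
    """Modeled-alteration map of one experiment.

    Foci are snapped to the nearest voxel center; per voxel, the MA value
    is the maximum over the experiment's per-focus kernel probabilities.
    Out-of-grid foci are dropped with a warning; if none remain an error
    is raised.
    """
    vox = grid.world_to_voxel(experiment.foci_array)
    inside = grid.contains_voxel(vox)
    if not np.all(inside):
        logger.warning("experiment %s: dropping %d out-of-box foci",
                       experiment.id, int(np.sum(~inside)))
    vox = vox[inside]
    if vox.shape[0] == 0:
        raise ValueError(
            f"experiment {experiment.id}: all foci outside the bounding box")
    r, kern = _kernel_offsets(grid, fwhm_mm, trunc_factor)
    values = _ma_values_from_voxels(vox, grid, r, kern)
    if mask is not None:
        values = np.where(mask, values, 0.0)
    return MaMap(grid=grid, values=values, experiment_id=experiment.id)


def ale_union(ma_maps: list[MaMap], fwhm_mm: float = 10.0,
              mask: np.ndarray | None = None) -> AleMap:
    """Unite MA maps into an ALE map: ``ALE = 1 - prod_i (1 - MA_i)``.

    Commutative in experiment order and monotone: adding an experiment
    never decreases any voxel.
    """
    if not ma_maps:
        raise ValueError("need at least one MA map")
    grid = ma_maps[0].grid
    for m in ma_maps[1:]:
        if not grid.same_geometry(m.grid):
            raise ValueError("MA maps do not share one grid")
    survival = np.ones(grid.dims, dtype=float)
    for m in ma_maps:
        survival *= 1.0 - m.values
    values = 1.0 - survival
    if mask is not None:
        values = np.where(mask, values, 0.0)
    return AleMap(grid=grid, values=values, n_experiments=len(ma_maps),
                  fwhm_mm=fwhm_mm, mask=mask)


def compute_ale(experiments: list[Experiment], grid: VolumeGrid,
                fwhm_mm: float = 10.0, mask: np.ndarray | None = None,
                trunc_factor: float = 3.0) -> AleMap:
    """Convenience: MA maps for all experiments, then their union."""
    mas = [ma_map(e, grid, fwhm_mm, mask=mask, trunc_factor=trunc_factor)
           for e in experiments]
    return ale_union(mas, fwhm_mm=fwhm_mm, mask=mask)


def _largest_cluster_size(values: np.ndarray, forming: float) -> int:
    binary = values >= forming
    labeled, n = ndimage.label(binary, structure=CLUSTER_STRUCTURE)
    if n == 0:
        return 0
    return int(np.max(np.bincount(labeled.ravel())[1:]))


def build_null(dataset_shape: list[int], grid: VolumeGrid, mask: np.ndarray,
               fwhm_mm: float = 10.0, n_iterations: int = 1000,
               seed: int | None = None, kind: str = "voxel_max",
               cluster_forming: float | None = None,
               trunc_factor: float = 3.0) -> NullDistribution:
    """Simulate the ALE null by redrawing every experiment's foci uniformly
    over in-mask voxels.

    ``dataset_shape`` gives the per-experiment foci counts of the real
    dataset, so each null ALE map has the same characteristics (number of
    experiments and foci per experiment).  Records per iteration either the
    maximum in-mask ALE value (``kind="voxel_max"``, for voxel-level FWE)
    or the largest 6-connected suprathreshold cluster size at the given
    cluster-forming ALE value (``kind="cluster_size"``).
    """
    if kind not in ("voxel_max", "cluster_size"):
        raise ValueError(f"unknown null kind {kind!r}")
    if kind == "cluster_size" and cluster_forming is None:
        raise ValueError("cluster_size null requires a cluster_forming value")
    if n_iterations < 100:
        raise ValueError("n_iterations must be >= 100")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.dims:
        raise ValueError("mask shape does not match grid dims")
    mask_vox = np.argwhere(mask)
    if mask_vox.shape[0] == 0:
        raise ValueError("mask is empty")
    if not dataset_shape or any(c < 1 for c in dataset_shape):
        raise ValueError("dataset_shape must be positive foci counts")

    rng = np.random.default_rng(seed)
    r, kern = _kernel_offsets(grid, fwhm_mm, trunc_factor)
    samples = np.empty(n_iterations, dtype=float)
    for it in range(n_iterations):
        survival = np.ones(grid.dims, dtype=float)
        for count in dataset_shape:
            picks = mask_vox[rng.integers(0, mask_vox.shape[0], size=count)]
            ma = _ma_values_from_voxels(picks, grid, r, kern)
            survival *= 1.0 - ma
        ale = 1.0 - survival
        ale[~mask] = 0.0
        if kind == "voxel_max":
            samples[it] = float(ale.max())
        else:
            samples[it] = _largest_cluster_size(ale, cluster_forming)
    return NullDistribution(kind=kind, samples=samples,
                            n_iterations=n_iterations, seed=seed,
                            cluster_forming=cluster_forming)


def threshold_map(ale_map: AleMap, null: NullDistribution,
                  alpha: float = 0.05) -> AleMap:
    """Voxel-level FWE threshold at the (1 - alpha) null quantile.

    The threshold is the empirical quantile of the null voxel-max samples
    with conservative ("higher") interpolation; voxels with ALE below it
    are zeroed.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if null.kind != "voxel_max":
        raise ValueError("voxel-level FWE thresholding requires a voxel_max null")
    thr = float(np.quantile(null.samples, 1.0 - alpha, method="higher"))
    values = np.where(ale_map.values >= thr, ale_map.values, 0.0)
    out = AleMap(grid=ale_map.grid, values=values,
                 n_experiments=ale_map.n_experiments,
                 fwhm_mm=ale_map.fwhm_mm, threshold_value=thr,
                 mask=ale_map.mask)
    logger.info("FWE threshold %.3g: %d voxels survive", thr,
                out.n_suprathreshold)
    return out
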