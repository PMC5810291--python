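"""Synthetic dataset generator with known ground truth.

The generator realizes the multinomial/Bernoulli model under which the
coalteration statistics are defined: each experiment independently draws a
binary alteration pattern over a set of toy atlas regions, with planted
pairwise couplings that raise the joint alteration probability theta1 of
chosen pairs above the independence product.  Couplings are induced by
thresholding latent correlated Gaussians (a Gaussian copula), so any
feasible 4-cell theta table is attainable and the population Patel's kappa
of every pair is available in closed form.

For each altered region an experiment reports a handful of foci scattered
isotropically around the region center (truncated to the region's cuboid);
uniform noise foci over the brain mask model incidental reports that the
20-voxel region rule should remove.  Everything is reproducible from the
spec's seed, down to byte-identical foci files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .coalteration import ThetaEstimate, patel_kappa
from .grid import VolumeGrid
from .io import AtlasVolume, Experiment, Focus, foci_file_text

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticRegion:
    """An axis-aligned cuboid region: voxel centers in [c-h, c+h) per axis."""

    name: str
    hemisphere: str
    center: tuple[float, float, float]
    half_size: tuple[float, float, float] = (8.0, 8.0, 8.0)

    def contains(self, xyz) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        lo = np.asarray(self.center) - np.asarray(self.half_size)
        hi = np.asarray(self.center) + np.asarray(self.half_size)
        return np.all((xyz >= lo) & (xyz < hi), axis=-1)

    def overlaps(self, other: "SyntheticRegion") -> bool:
        a_lo = np.asarray(self.center) - np.asarray(self.half_size)
        a_hi = np.asarray(self.center) + np.asarray(self.half_size)
        b_lo = np.asarray(other.center) - np.asarray(other.half_size)
        b_hi = np.asarray(other.center) + np.asarray(other.half_size)
        return bool(np.all((a_lo < b_hi) & (b_lo < a_hi)))


@dataclass(frozen=True)
class Coupling:
    """Planted pairwise coupling: theta1 = p_a * p_b + joint_excess."""

    region_a: str
    region_b: str
    joint_excess: float


def _default_regions() -> list[SyntheticRegion]:
    # 5 mirrored L/R pairs in Talairach-like medial-temporal / parietal spots
    layout = [
        ("Hipp", (28.0, -24.0, -12.0)),
        ("Amyg", (22.0, -4.0, -16.0)),
        ("ParaHipp", (26.0, -44.0, -8.0)),
        ("TempInf", (50.0, -30.0, -20.0)),
        ("Precun", (10.0, -60.0, 40.0)),
    ]
    regions = []
    for name, (x, y, z) in layout:
        regions.append(SyntheticRegion(f"{name}_L", "L", (-x, y, z)))
        regions.append(SyntheticRegion(f"{name}_R", "R", (x, y, z)))
    return regions


def _default_couplings() -> list[Coupling]:
    # population kappa = 0.17 / (0.4 - 0.16) ~= 0.708 at base prob 0.4
    return [
        Coupling("Hipp_L", "Amyg_L", 0.17),
        Coupling("Hipp_R", "ParaHipp_R", 0.17),
        Coupling("Amyg_R", "TempInf_R", 0.17),
        Coupling("ParaHipp_L", "TempInf_L", 0.17),
    ]


@dataclass
class GenerativeSpec:
    """Ground-truth description of a synthetic coalteration dataset."""

    n_experiments: int = 60
    regions: list[SyntheticRegion] = field(default_factory=_default_regions)
    base_alteration_prob: float | dict[str, float] = 0.4
    couplings: list[Coupling] = field(default_factory=_default_couplings)
    foci_per_altered_region: tuple[int, int] = (2, 6)
    noise_foci: tuple[int, int] = (0, 3)
    focus_scatter_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def prob(self, region_name: str) -> float:
        if isinstance(self.base_alteration_prob, dict):
            return float(self.base_alteration_prob[region_name])
        return float(self.base_alteration_prob)

    def region_names(self) -> list[str]:
        return [r.name for r in self.regions]

    def coupling_for(self, a: str, b: str) -> Coupling | None:
        for c in self.couplings:
            if {c.region_a, c.region_b} == {a, b}:
                return c
        return None

    def pair_thetas(self, a: str, b: str) -> ThetaEstimate:
        """Exact 4-cell joint distribution of a region pair."""
        pa, pb = self.prob(a), self.prob(b)
        coup = self.coupling_for(a, b)
        theta1 = pa * pb + (coup.joint_excess if coup else 0.0)
        theta = ThetaEstimate(theta1, pa - theta1, pb - theta1,
                              1.0 - pa - pb + theta1)
        return theta

    def validate(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be positive")
        if len(self.regions) < 2:
            raise ValueError("need at least two regions")
        names = self.region_names()
        if len(names) != len(set(names)):
            raise ValueError("region names must be unique")
        for name in names:
            if not 0.0 <= self.prob(name) <= 1.0:
                raise ValueError(f"alteration probability of {name} not in [0,1]")
        for i, ra in enumerate(self.regions):
            for rb in self.regions[i + 1:]:
                if ra.overlaps(rb):
                    raise ValueError(
                        f"regions {ra.name} and {rb.name} overlap")
        for c in self.couplings:
            if c.region_a not in names or c.region_b not in names:
                raise ValueError(f"coupling references unknown region: {c}")
            th = self.pair_thetas(c.region_a, c.region_b)
            if min(th) < -1e-12 or max(th) > 1.0 + 1e-12:
                raise ValueError(
                    f"coupling {c.region_a}-{c.region_b}: implied theta "
                    f"{tuple(round(t, 4) for t in th)} is outside the simplex")
        # latent correlation matrix must be positive semidefinite
        R = self.latent_correlation()
        if np.min(np.linalg.eigvalsh(R)) < -1e-8:
            raise ValueError("couplings imply a non-PSD latent correlation")
        lo, hi = self.foci_per_altered_region
        if not (0 < lo <= hi):
            raise ValueError("foci_per_altered_region must be a positive range")
        lo, hi = self.noise_foci
        if not (0 <= lo <= hi):
            raise ValueError("noise_foci must be a non-negative range")
        if self.focus_scatter_sd <= 0:
            raise ValueError("focus_scatter_sd must be positive")

    # -- Gaussian copula calibration ------------------------------------

    def latent_threshold(self, region_name: str) -> float:
        """Latent z threshold: region altered iff z > Phi^-1(1 - p)."""
        return float(stats.norm.ppf(1.0 - self.prob(region_name)))

    def _solve_rho(self, coupling: Coupling) -> float:
        a, b = coupling.region_a, coupling.region_b
        pa, pb = self.prob(a), self.prob(b)
        target = pa * pb + coupling.joint_excess
        lo_bound = max(0.0, pa + pb - 1.0)
        hi_bound = min(pa, pb)
        eps = 1e-12
        if target < lo_bound - eps or target > hi_bound + eps:
            raise ValueError(
                f"coupling {a}-{b}: theta1={target:.4f} outside the Frechet "
                f"bounds [{lo_bound:.4f}, {hi_bound:.4f}]")
        if target >= hi_bound - eps:
            return 1.0
        if target <= lo_bound + eps:
            return -1.0
        ta, tb = self.latent_threshold(a), self.latent_threshold(b)

        def survival(rho: float) -> float:
            cov = [[1.0, rho], [rho, 1.0]]
            return float(stats.multivariate_normal(
                mean=[0.0, 0.0], cov=cov, allow_singular=True
            ).cdf([-ta, -tb]))

        return float(optimize.brentq(
            lambda r: survival(r) - target, -0.9999, 0.9999, xtol=1e-10))

    def latent_correlation(self) -> np.ndarray:
        names = self.region_names()
        R = np.eye(len(names))
        idx = {n: i for i, n in enumerate(names)}
        for c in self.couplings:
            rho = self._solve_rho(c)
            i, j = idx[c.region_a], idx[c.region_b]
            R[i, j] = R[j, i] = rho
        return R


@dataclass
class GroundTruth:
    """What the generator actually planted."""

    alteration: np.ndarray  # (n_experiments, n_regions) binary
    region_names: list[str]
    region_centers: np.ndarray  # (n_regions, 3) mm
    planted_pairs: list[tuple[str, str, float]]  # (a, b, population kappa)


@dataclass
class SimulatedDataset:
    experiments: list[Experiment]
    truth: GroundTruth
    atlas: AtlasVolume
    foci_text: str


def population_kappa(spec: GenerativeSpec, pair: tuple[str, str]) -> float:
    """Patel's kappa of the true generating distribution of a region pair."""
    a, b = pair
    if a not in spec.region_names() or b not in spec.region_names():
        raise ValueError(f"pair {pair} not defined in spec")
    return patel_kappa(spec.pair_thetas(a, b))


def make_toy_atlas(spec: GenerativeSpec, grid: VolumeGrid) -> AtlasVolume:
    """Rasterize the spec's cuboid regions onto a grid (labels 1..n)."""
    centers = grid.all_voxel_centers()
    labels = np.zeros(grid.n_voxels, dtype=np.int32)
    table: dict[int, tuple[str, str]] = {}
    for i, region in enumerate(spec.regions, start=1):
        lo = np.asarray(region.center) - np.asarray(region.half_size)
        hi = np.asarray(region.center) + np.asarray(region.half_size)
        if np.any(lo < grid.voxel_to_world((0, 0, 0)) - grid.voxel_size / 2) or \
           np.any(hi > grid.voxel_to_world(np.asarray(grid.dims) - 1)
                  + grid.voxel_size / 2):
            raise ValueError(f"region {region.name} extends outside the grid")
        inside = region.contains(centers)
        if np.any(labels[inside] != 0):
            other = int(labels[inside][labels[inside] != 0][0])
            raise ValueError(
                f"regions {table[other][0]} and {region.name} overlap on the grid")
        labels[inside] = i
        table[i] = (region.name, region.hemisphere)
    return AtlasVolume(grid=grid,
                       labels=labels.reshape(grid.dims), label_table=table)


def _sample_alterations(spec: GenerativeSpec,
                        rng: np.random.Generator) -> np.ndarray:
    R = spec.latent_correlation()
    z = rng.multivariate_normal(np.zeros(len(spec.regions)), R,
                                size=spec.n_experiments, method="svd")
    thresholds = np.array([spec.latent_threshold(n)
                           for n in spec.region_names()])
    return (z > thresholds).astype(np.uint8)


def _truncated_gaussian_focus(center, half_size, sd: float,
                              rng: np.random.Generator) -> np.ndarray:
    center = np.asarray(center)
    half = np.asarray(half_size)
    for _ in range(1000):
        pt = rng.normal(center, sd)
        if np.all(np.abs(pt - center) < half):
            return pt
    raise RuntimeError("truncated Gaussian sampling failed to converge")


def simulate_dataset(spec: GenerativeSpec,
                     grid: VolumeGrid | None = None) -> SimulatedDataset:
    """Draw a full synthetic dataset: atlas, experiments, ground truth.

    Alteration patterns come from the coupled multinomial model; each
    altered region contributes Uniform{lo..hi} foci scattered
    Gaussian(center, scatter_sd) truncated to the region cuboid; noise foci
    are uniform over the whole bounding box — they model incidental reports
    outside the regions of interest, which the region rule should remove.
    An experiment that would end up with zero foci receives one noise
    focus, since an experiment enters a meta-analysis only by reporting
    something.
    """
    if grid is None:
        grid = VolumeGrid.talairach()
    atlas = make_toy_atlas(spec, grid)
    rng = np.random.default_rng(spec.seed)
    alteration = _sample_alterations(spec, rng)
    mask_vox = np.argwhere(np.ones(grid.dims, dtype=bool))

    lo_f, hi_f = spec.foci_per_altered_region
    lo_n, hi_n = spec.noise_foci
    experiments: list[Experiment] = []
    for i in range(spec.n_experiments):
        foci: list[Focus] = []
        for j, region in enumerate(spec.regions):
            if not alteration[i, j]:
                continue
            k = int(rng.integers(lo_f, hi_f + 1))
            for _ in range(k):
                pt = _truncated_gaussian_focus(
                    region.center, region.half_size, spec.focus_scatter_sd, rng)
                foci.append(Focus(*pt))
        n_noise = int(rng.integers(lo_n, hi_n + 1))
        if not foci and n_noise == 0:
            n_noise = 1
        for _ in range(n_noise):
            vox = mask_vox[int(rng.integers(0, mask_vox.shape[0]))]
            foci.append(Focus(*grid.voxel_to_world(vox)))
        experiments.append(Experiment(
            id=f"E{i + 1:03d}", label=f"SynthStudy{i + 1:02d}",
            foci=foci, n_subjects=int(rng.integers(8, 61))))

    planted = [(c.region_a, c.region_b,
                population_kappa(spec, (c.region_a, c.region_b)))
               for c in spec.couplings]
    truth = GroundTruth(
        alteration=alteration, region_names=spec.region_names(),
        region_centers=np.array([r.center for r in spec.regions]),
        planted_pairs=planted)
    return SimulatedDataset(experiments=experiments, truth=truth, atlas=atlas,
                            foci_text=foci_file_text(experiments))
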