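"""End-to-end run: foci file -> ALE -> nodes -> coalteration network -> outputs."""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import ale as ale_mod
from . import coalteration as co
from . import io
from . import network as net
from . import nodes as nodes_mod
from .grid import VolumeGrid

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable thresholds of a run, with the standard defaults.

    Defaults follow the method's stated values: FWHM 10 mm (mean spatial
    uncertainty of reported coordinates ~10.2 mm), voxel-level FWE alpha
    0.05, 20-voxel region rule, 90th-percentile peak filter, 10 mm
    interpeak distance and focus-assignment radius, per-edge p < 0.01 with
    10^4 Dirichlet draws.
    """

    fwhm_mm: float = 10.0
    trunc_factor: float = 3.0
    alpha: float = 0.05
    null_kind: str = "voxel_max"
    n_null_iterations: int = 1000
    cluster_forming: float | None = None
    mask_mode: str = "atlas"
    mask_dilation: int = 1
    min_region_voxels: int = 20
    peak_percentile: float = 90.0
    peak_percentile_basis: str = "voxels"
    min_interpeak_mm: float = 10.0
    region_filter_order: str = "after"
    assign_rule: str = "radius"
    assign_radius_mm: float = 10.0
    e_threshold: float = 0.0
    p_threshold: float = 0.01
    n_mc_samples: int = 10_000
    prior_alpha: float = 1.0
    bonferroni: bool = False
    betweenness_tie_mode: str = "fractional"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunResult:
    """Everything a full run produces, stage by stage."""

    config: PipelineConfig
    seed: int | None
    ale_map: ale_mod.AleMap
    thresholded: ale_mod.AleMap
    null: ale_mod.NullDistribution
    regions: list[nodes_mod.RegionAlteration]
    nodes: list[nodes_mod.NetworkNode]
    matrix: co.CoalterationMatrix
    network: co.CoalterationNetwork
    topology: net.TopologyReport
    manifest: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, Path]:
        return io.write_outputs(
            out_dir, nodes=self.nodes, matrix=self.matrix,
            network=self.network, ale_map=self.thresholded,
            topology=self.topology, manifest=self.manifest)


def run_pipeline(experiments: list[io.Experiment], atlas: io.AtlasVolume,
                 config: PipelineConfig | None = None,
                 seed: int | None = None) -> RunResult:
    """Run every stage on parsed experiments and a loaded atlas.

    ``seed`` drives both the ALE null simulation and the per-edge
    Monte-Carlo (two independent streams are spawned from it).
    """
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    null_seed, net_seed = (int(s.generate_state(1)[0] % (2 ** 31))
                           for s in ss.spawn(2))

    grid = atlas.grid
    if config.mask_mode == "atlas":
        mask = atlas.mask(dilate=config.mask_dilation)
    elif config.mask_mode == "full":
        # whole bounding box: for atlases whose labeled regions do not tile
        # the brain (e.g. synthetic toy atlases)
        mask = np.ones(grid.dims, dtype=bool)
    else:
        raise ValueError(f"unknown mask_mode {config.mask_mode!r}")
    ale_map = ale_mod.compute_ale(experiments, grid, fwhm_mm=config.fwhm_mm,
                                  mask=mask, trunc_factor=config.trunc_factor)
    null = ale_mod.build_null(
        [len(e.foci) for e in experiments], grid, mask,
        fwhm_mm=config.fwhm_mm, n_iterations=config.n_null_iterations,
        seed=null_seed, kind=config.null_kind,
        cluster_forming=config.cluster_forming,
        trunc_factor=config.trunc_factor)
    thresholded = ale_mod.threshold_map(ale_map, null, alpha=config.alpha)

    regions = nodes_mod.altered_regions(thresholded, atlas,
                                        config.min_region_voxels)
    nodes = nodes_mod.build_nodes(
        thresholded, atlas, min_region_voxels=config.min_region_voxels,
        percentile=config.peak_percentile,
        min_interpeak_mm=config.min_interpeak_mm,
        basis=config.peak_percentile_basis,
        region_filter=config.region_filter_order)
    if not nodes:
        raise ValueError("no nodes survived the construction thresholds")

    matrix = co.build_matrix(experiments, nodes,
                             assign_radius_mm=config.assign_radius_mm,
                             assign_rule=config.assign_rule, atlas=atlas)
    network = co.build_network(matrix, nodes, e_threshold=config.e_threshold,
                               p_threshold=config.p_threshold,
                               n_samples=config.n_mc_samples, seed=net_seed,
                               prior_alpha=config.prior_alpha,
                               bonferroni=config.bonferroni)
    topology = net.analyze_topology(network,
                                    tie_mode=config.betweenness_tie_mode)

    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "null_seed": null_seed,
        "network_seed": net_seed,
        "n_experiments": len(experiments),
        "n_foci": int(sum(len(e.foci) for e in experiments)),
        "fwe_threshold": thresholded.threshold_value,
        "n_suprathreshold_voxels": thresholded.n_suprathreshold,
        "n_nodes": len(nodes),
        "n_edges": network.graph.number_of_edges(),
        "conventions": {
            "maxima_connectivity": 26,
            "cluster_connectivity": 6,
            "dirichlet_prior": config.prior_alpha,
            "quantile_interpolation": "higher",
            "betweenness_tie_mode": config.betweenness_tie_mode,
            "interpeak_boundary": "inclusive (>=)",
        },
    }
    return RunResult(config=config, seed=seed, ale_map=ale_map,
                     thresholded=thresholded, null=null, regions=regions,
                     nodes=nodes, matrix=matrix, network=network,
                     topology=topology, manifest=manifest)


def run_from_files(foci_path, atlas_path, labels_path,
                   config: PipelineConfig | None = None,
                   seed: int | None = None,
                   out_dir=None) -> RunResult:
    """File-level entry point used by the CLI."""
    experiments = io.read_foci_file(foci_path)
    atlas = io.read_atlas(atlas_path, labels_path)
    result = run_pipeline(experiments, atlas, config=config, seed=seed)
    if out_dir is not None:
        result.write(out_dir)
    return result


def default_grid(voxel_size: float = 2.0) -> VolumeGrid:
    return VolumeGrid.talairach(voxel_size)
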