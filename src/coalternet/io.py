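"""Readers and writers for foci files, labeled atlases, and run outputs.

The foci format is a Sleuth-style plain-text dialect: each experiment is a
block opened by ``//``-comment lines (first comment line = label, optional
``// Subjects=<n>``), followed by whitespace-separated x y z millimetre
triples, one focus per line; a blank line closes the block.  Coordinates are
taken to be Talairach mm; a ``// Reference=<space>`` annotation naming a
different space only triggers a warning.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import VolumeGrid

logger = logging.getLogger(__name__)

_KEYVAL_RE = re.compile(r"^\s*(\w+)\s*=\s*(.+?)\s*$")


@dataclass(frozen=True)
class Focus:
    """A reported alteration peak in stereotaxic (Talairach) mm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.x, self.y, self.z])):
            raise ValueError("focus coordinates must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Experiment:
    """One VBM contrast's reported foci plus metadata."""

    id: str
    label: str
    foci: list[Focus]
    n_subjects: int | None = None

    def __post_init__(self) -> None:
        if len(self.foci) == 0:
            raise ValueError(f"experiment {self.id!r} has no foci")
        if self.n_subjects is not None and self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")

    @property
    def foci_array(self) -> np.ndarray:
        """(n_foci, 3) mm coordinates."""
        return np.array([f.xyz for f in self.foci], dtype=float)


class FociParseError(ValueError):
    pass


def read_foci_file(path) -> list[Experiment]:
    """Parse a Sleuth-dialect foci file into experiments, in file order.

    Raises
    ------
    FociParseError
        On an empty file, a block with zero foci, or a malformed
        coordinate line (reported with its line number).
    """
    path = Path(path)
    experiments: list[Experiment] = []
    label: str | None = None
    n_subjects: int | None = None
    foci: list[Focus] = []
    block_open = False

    def close_block(line_no: int) -> None:
        nonlocal label, n_subjects, foci, block_open
        if not block_open:
            return
        name = label if label is not None else f"experiment_{len(experiments) + 1}"
        if not foci:
            raise FociParseError(
                f"{path}: block {name!r} ending before line {line_no} has no foci")
        experiments.append(Experiment(
            id=f"E{len(experiments) + 1:03d}", label=name,
            foci=list(foci), n_subjects=n_subjects))
        label, n_subjects, foci, block_open = None, None, [], False

    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                close_block(line_no)
                continue
            if line.startswith("//"):
                body = line[2:].strip()
                m = _KEYVAL_RE.match(body)
                if m:
                    key, value = m.group(1).lower(), m.group(2)
                    if key == "reference":
                        # file-level space declaration; not part of a block
                        if value.strip().lower() != "talairach":
                            logger.warning(
                                "%s:%d: coordinates declared in %r, not "
                                "Talairach; no transform is applied",
                                path, line_no, value)
                        continue
                    block_open = True
                    if key == "subjects":
                        try:
                            n_subjects = int(value)
                        except ValueError as exc:
                            raise FociParseError(
                                f"{path}:{line_no}: bad Subjects value {value!r}"
                            ) from exc
                    else:
                        logger.warning("%s:%d: ignoring unknown annotation %r",
                                       path, line_no, body)
                    continue
                block_open = True
                if label is None and body:
                    label = body
                elif body:
                    logger.warning("%s:%d: ignoring extra annotation %r",
                                   path, line_no, body)
                continue
            # a bare coordinate line also opens a block
            block_open = True
            tokens = line.split()
            if len(tokens) != 3:
                raise FociParseError(
                    f"{path}:{line_no}: expected 3 coordinates, got "
                    f"{len(tokens)}: {line!r}")
            try:
                x, y, z = (float(t) for t in tokens)
            except ValueError as exc:
                raise FociParseError(
                    f"{path}:{line_no}: non-numeric coordinate in {line!r}"
                ) from exc
            foci.append(Focus(x, y, z))
    close_block(line_no=-1)

    if not experiments:
        raise FociParseError(f"{path}: no experiments")
    return experiments


def foci_file_text(experiments: list[Experiment],
                   reference: str = "Talairach") -> str:
    """Render experiments in the Sleuth dialect read by :func:`read_foci_file`."""
    lines = [f"// Reference={reference}", ""]
    for exp in experiments:
        lines.append(f"// {exp.label}")
        if exp.n_subjects is not None:
            lines.append(f"// Subjects={exp.n_subjects}")
        for f in exp.foci:
            lines.append(f"{f.x:.2f}\t{f.y:.2f}\t{f.z:.2f}")
        lines.append("")
    return "\n".join(lines) + "\n"


def write_foci_file(experiments: list[Experiment], path,
                    reference: str = "Talairach") -> None:
    Path(path).write_text(foci_file_text(experiments, reference))


# ---------------------------------------------------------------------------
# Atlas volumes
# ---------------------------------------------------------------------------

@dataclass
class AtlasVolume:
    """Integer-labeled volume plus a label table (0 = background).

    ``label_table`` maps integer label -> (region name, hemisphere tag);
    hemisphere tags are 'L', 'R' or 'M' (midline).
    """

    grid: VolumeGrid
    labels: np.ndarray
    label_table: dict[int, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.shape != self.grid.dims:
            raise ValueError("label array shape does not match grid dims")
        present = set(np.unique(self.labels)) - {0}
        missing = sorted(present - set(self.label_table))
        if missing:
            raise ValueError(
                f"labels present in volume but missing from table: {missing}")
        names = [name for name, _ in self.label_table.values()]
        if len(names) != len(set(names)):
            raise ValueError("label table region names are not unique")
        if not present:
            logger.warning("atlas volume contains only background voxels")

    @property
    def region_labels(self) -> list[int]:
        """Labels actually present in the volume, ascending."""
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def name_of(self, label: int) -> str:
        return self.label_table[label][0]

    def hemisphere_of(self, label: int) -> str:
        return self.label_table[label][1]

    def mask(self, dilate: int = 0) -> np.ndarray:
        """Boolean in-brain mask: nonzero voxels, optionally dilated."""
        m = self.labels != 0
        if dilate > 0:
            from scipy import ndimage
            m = ndimage.binary_dilation(m, iterations=dilate)
        return m


def read_atlas(volume_path, label_table_path) -> AtlasVolume:
    """Load a labeled NIfTI atlas and its TSV label table.

    The TSV must have columns ``label``, ``name``, ``hemisphere``.  The
    affine must be axis-aligned RAS+ with isotropic voxels (no resampling
    is done here).
    """
    img = nib.load(str(volume_path))
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-4):
        raise ValueError("atlas affine is not axis-aligned; resampling is "
                         "out of scope")
    diag = np.diag(rot)
    if np.any(diag <= 0):
        raise ValueError("atlas affine must be RAS+ (positive diagonal)")
    if not np.allclose(diag, diag[0], atol=1e-4):
        raise ValueError("atlas voxels must be isotropic")
    data = np.asarray(img.dataobj)
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError("atlas volume contains non-integer voxel values")
    labels = rounded.astype(np.int32)

    table = pd.read_csv(label_table_path, sep="\t")
    required = {"label", "name", "hemisphere"}
    if not required.issubset(table.columns):
        raise ValueError(f"label table must have columns {sorted(required)}")
    label_table = {int(r.label): (str(r.name), str(r.hemisphere))
                   for r in table.itertuples(index=False)}

    grid = VolumeGrid(origin=tuple(aff[:3, 3]), voxel_size=float(diag[0]),
                      dims=labels.shape)
    return AtlasVolume(grid=grid, labels=labels, label_table=label_table)


def write_atlas(atlas: AtlasVolume, volume_path, label_table_path) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), atlas.grid.affine)
    nib.save(img, str(volume_path))
    rows = [{"label": lab, "name": name, "hemisphere": hemi}
            for lab, (name, hemi) in sorted(atlas.label_table.items())]
    pd.DataFrame(rows, columns=["label", "name", "hemisphere"]).to_csv(
        label_table_path, sep="\t", index=False)


def write_nifti(values: np.ndarray, grid: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                             grid.affine), str(path))


# ---------------------------------------------------------------------------
# Run outputs
# ---------------------------------------------------------------------------

def write_matrix_tsv(matrix, path) -> None:
    """Write a coalteration matrix as TSV (rows = experiments)."""
    df = pd.DataFrame(matrix.values, index=matrix.experiment_ids,
                      columns=matrix.node_ids)
    df.index.name = "experiment"
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path):
    """Inverse of :func:`write_matrix_tsv`."""
    from .coalteration import CoalterationMatrix
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CoalterationMatrix(
        experiment_ids=[str(i) for i in df.index],
        node_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=np.uint8))


def write_outputs(out_dir, *, nodes, matrix, network, ale_map=None,
                  topology=None, manifest: dict | None = None) -> dict[str, Path]:
    """Serialize a full run: node table, matrix, edge list, GraphML,
    optional ALE volume, and a JSON manifest.

    ``network`` is a :class:`~coalternet.coalteration.CoalterationNetwork`;
    ``topology`` an optional :class:`~coalternet.network.TopologyReport`
    supplying degree and edge-betweenness annotations (computed here if
    omitted).
    """
    import networkx as nx

    from .network import analyze_topology

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    node_ids = [n.id for n in nodes]
    if list(matrix.node_ids) != node_ids:
        raise ValueError("matrix columns do not match the node list")
    if topology is None:
        topology = analyze_topology(network)
    written: dict[str, Path] = {}

    nodes_df = pd.DataFrame([
        {"id": n.id, "label": n.region_name, "hemisphere": n.hemisphere,
         "x": n.x, "y": n.y, "z": n.z, "ale_value": n.ale_value,
         "degree": topology.degree.get(n.id, 0)}
        for n in nodes])
    written["nodes"] = out_dir / "nodes.tsv"
    nodes_df.to_csv(written["nodes"], sep="\t", index=False)

    written["matrix"] = out_dir / "matrix.tsv"
    write_matrix_tsv(matrix, written["matrix"])

    rows = []
    for res in network.results:
        key = frozenset((res.node_a, res.node_b))
        rows.append({
            "node_a": res.node_a, "node_b": res.node_b,
            "kappa": res.kappa, "posterior_prob": res.posterior_prob,
            "significant": bool(res.significant),
            "edge_betweenness": topology.edge_betweenness.get(key, ""),
        })
    written["edges"] = out_dir / "edges.tsv"
    pd.DataFrame(rows, columns=["node_a", "node_b", "kappa", "posterior_prob",
                                "significant", "edge_betweenness"]).to_csv(
        written["edges"], sep="\t", index=False)

    written["graphml"] = out_dir / "network.graphml"
    nx.write_graphml(network.graph, written["graphml"])

    if ale_map is not None:
        written["ale_map"] = out_dir / "ale_map.nii.gz"
        write_nifti(ale_map.values, ale_map.grid, written["ale_map"])

    written["manifest"] = out_dir / "manifest.json"
    with open(written["manifest"], "w") as fh:
        json.dump(manifest or {}, fh, indent=2, default=str)
    return written
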