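"""Peak-by-cell matrix I/O, Newick parsing, reference filtering and configuration.

Counts are stored sparse (peaks x cells) with BED-convention peak intervals
(0-based half-open). On disk the canonical layout of a dataset directory is::

    matrix.mtx          Matrix Market coordinate file (1-based, converted here)
    peaks.bed           chrom  start  end  peak_id
    barcodes.tsv        one barcode per line
    cell_metadata.tsv   barcode + cell_type / ground-truth columns (header)
    peak_metadata.tsv   peak table + hub/interactive columns (header)
"""

from __future__ import annotations


import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .exceptions import (
    EmptyResultError,
    FormatError,
    ParameterError,
    ValidationError,
)

__all__ = [
    "CountMatrix",
    "Branch",
    "Tree",
    "SimConfig",
    "read_count_matrix",
    "read_count_matrix_dir",
    "write_count_matrix",
    "parse_newick",
    "filter_reference",
    "load_config",
]


# ---------------------------------------------------------------------------
# CountMatrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """A peaks x cells non-negative integer count matrix with metadata tables.

    Parameters
    ----------
    counts
        Sparse CSR matrix, shape (npeak, ncell), non-negative integers.
    peaks
        DataFrame with columns chrom, start, end, peak_id (unique); extra
        ground-truth columns (hub_id, interactive) may be present.
    cells
        DataFrame with column barcode (unique); cell_type and ground-truth
        columns (population, branch, pseudotime, batch) may be present.
    binarized
        True when every entry is 0/1 and the matrix represents accessibility
        events rather than read counts (Bernoulli framework).
    """

    counts: sp.csr_matrix
    peaks: pd.DataFrame
    cells: pd.DataFrame
    binarized: bool = False

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.validate()

    # -- properties ---------------------------------------------------------
    @property
    def npeak(self) -> int:
        return self.counts.shape[0]

    @property
    def ncell(self) -> int:
        return self.counts.shape[1]

    def validate(self) -> None:
        data = self.counts.data
        if data.size and data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValidationError("count matrix contains non-integer entries")
        if self.binarized and data.size and data.max() > 1:
            raise ValidationError("binarized matrix has entries > 1")
        if len(self.peaks) != self.npeak:
            raise ValidationError(
                f"peak table has {len(self.peaks)} rows, matrix has {self.npeak}"
            )
        if len(self.cells) != self.ncell:
            raise ValidationError(
                f"cell table has {len(self.cells)} rows, matrix has {self.ncell}"
            )
        if self.peaks["peak_id"].duplicated().any():
            raise ValidationError("duplicate peak_id values")
        if self.cells["barcode"].duplicated().any():
            raise ValidationError("duplicate barcodes")

    def subset(
        self,
        peak_idx: Optional[np.ndarray] = None,
        cell_idx: Optional[np.ndarray] = None,
    ) -> "CountMatrix":
        """Return a copy restricted to the given peak/cell integer indices."""
        counts = self.counts
        peaks, cells = self.peaks, self.cells
        if peak_idx is not None:
            counts = counts[peak_idx, :]
            peaks = peaks.iloc[peak_idx].reset_index(drop=True)
        if cell_idx is not None:
            counts = counts[:, cell_idx]
            cells = cells.iloc[cell_idx].reset_index(drop=True)
        return CountMatrix(counts.tocsr(), peaks.copy(), cells.copy(), self.binarized)


def default_peak_table(npeak: int, width: int = 500, gap: int = 500) -> pd.DataFrame:
    """Synthetic non-overlapping peak intervals on a single chromosome."""
    start = np.arange(npeak, dtype=np.int64) * (width + gap)
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": start,
            "end": start + width,
            "peak_id": [f"peak_{i}" for i in range(npeak)],
        }
    )


def default_cell_table(ncell: int, prefix: str = "cell") -> pd.DataFrame:
    return pd.DataFrame({"barcode": [f"{prefix}_{j}" for j in range(ncell)]})


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _read_matrix_file(matrix_path: os.PathLike) -> sp.csr_matrix:
    path = Path(matrix_path)
    if path.stat().st_size == 0:
        raise FormatError(f"{path}: matrix file is empty")
    if path.suffix == ".mtx":
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # scipy raises bare ValueError
            raise FormatError(f"{path}: not a valid Matrix Market file ({exc})") from exc
        mat = sp.coo_matrix(mat)
        dense_data = mat.data
    else:  # dense TSV fallback for small fixtures
        frame = pd.read_csv(path, sep="\t", header=None)
        mat = sp.coo_matrix(frame.to_numpy())
        dense_data = mat.data
    if dense_data.size and dense_data.min() < 0:
        raise ValidationError(f"{path}: negative entries")
    if dense_data.size and not np.allclose(dense_data, np.round(dense_data)):
        raise ValidationError(f"{path}: non-integer entries")
    return sp.csr_matrix(mat, dtype=np.int64)


def read_count_matrix(
    matrix_path: os.PathLike,
    peaks_path: os.PathLike,
    barcodes_path: os.PathLike,
    labels_path: Optional[os.PathLike] = None,
) -> CountMatrix:
    """Read a count matrix from MTX (or dense TSV) + BED peaks + barcodes.

    ``labels_path`` may be a one-column file (cell types in barcode order) or
    a two-column barcode/cell_type file (headerless, tab-separated).
    """
    counts = _read_matrix_file(matrix_path)

    peaks = pd.read_csv(peaks_path, sep="\t", header=None)
    if peaks.shape[1] < 3:
        raise FormatError(f"{peaks_path}: expected >= 3 BED columns")
    peaks = peaks.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "peak_id"})
    if "peak_id" not in peaks.columns:
        peaks["peak_id"] = [
            f"{c}:{s}-{e}" for c, s, e in zip(peaks["chrom"], peaks["start"], peaks["end"])
        ]
    peaks = peaks[["chrom", "start", "end", "peak_id"]]
    if len(peaks) != counts.shape[0]:
        raise FormatError(
            f"{peaks_path}: {len(peaks)} peaks but matrix has {counts.shape[0]} rows"
        )

    barcodes = pd.read_csv(barcodes_path, header=None, names=["barcode"])["barcode"]
    if len(barcodes) != counts.shape[1]:
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix has "
            f"{counts.shape[1]} columns"
        )
    cells = pd.DataFrame({"barcode": barcodes.astype(str)})

    if labels_path is not None:
        labels = pd.read_csv(labels_path, sep="\t", header=None)
        if labels.shape[1] == 1:
            if len(labels) != len(cells):
                raise FormatError(
                    f"{labels_path}: {len(labels)} labels for {len(cells)} cells"
                )
            cells["cell_type"] = labels[0].astype(str).to_numpy()
        else:
            mapping = dict(zip(labels[0].astype(str), labels[1].astype(str)))
            missing = [b for b in cells["barcode"] if b not in mapping]
            if missing:
                raise FormatError(
                    f"{labels_path}: no label for barcode {missing[0]!r}"
                )
            cells["cell_type"] = [mapping[b] for b in cells["barcode"]]

    binarized = bool(counts.data.size) and int(counts.data.max()) == 1
    return CountMatrix(counts, peaks, cells, binarized=binarized)


def read_count_matrix_dir(directory: os.PathLike) -> CountMatrix:
    """Read a dataset directory written by :func:`write_count_matrix`."""
    d = Path(directory)
    cm = read_count_matrix(d / "matrix.mtx", d / "peaks.bed", d / "barcodes.tsv")
    meta = d / "cell_metadata.tsv"
    if meta.exists():
        cells = pd.read_csv(meta, sep="\t")
        if len(cells) != cm.ncell or "barcode" not in cells.columns:
            raise FormatError(f"{meta}: inconsistent cell metadata")
        cm.cells = cells
        cm.validate()
    pmeta = d / "peak_metadata.tsv"
    if pmeta.exists():
        peaks = pd.read_csv(pmeta, sep="\t")
        if len(peaks) == cm.npeak and "peak_id" in peaks.columns:
            cm.peaks = peaks
            cm.validate()
    return cm


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_count_matrix(cm: CountMatrix, out_dir: os.PathLike) -> dict:
    """Write a dataset directory; read_count_matrix_dir round-trips exactly.

    Returns a dict of the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "peaks": out / "peaks.bed",
        "barcodes": out / "barcodes.tsv",
        "cell_metadata": out / "cell_metadata.tsv",
        "peak_metadata": out / "peak_metadata.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), cm.counts.tocoo(), field="integer")
    cm.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        paths["peaks"], sep="\t", header=False, index=False
    )
    cm.cells["barcode"].to_csv(paths["barcodes"], header=False, index=False)
    cm.cells.to_csv(paths["cell_metadata"], sep="\t", index=False)
    cm.peaks.to_csv(paths["peak_metadata"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Branch:
    parent: str
    child: str
    length: float


@dataclass
class Tree:
    """Rooted tree with strictly positive branch lengths.

    ``branches`` are stored in Newick preorder (the order branch-proportional
    cell allocation and predecessor chaining use).
    """

    root: str
    branches: list  # list[Branch]

    @property
    def total_length(self) -> float:
        return float(sum(b.length for b in self.branches))

    def node_depths(self) -> dict:
        """Distance of every node from the root."""
        depth = {self.root: 0.0}
        for b in self.branches:
            depth[b.child] = depth[b.parent] + b.length
        return depth

    def children(self, node: str) -> list:
        return [b.child for b in self.branches if b.parent == node]


def parse_newick(newick: str) -> Tree:
    """Parse a Newick string with branch lengths into a :class:`Tree`.

    Every edge must carry a strictly positive branch length; a missing length
    raises :class:`FormatError` naming the node, a non-positive one raises
    :class:`ValidationError`.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise FormatError(f"invalid Newick string: {exc}") from exc

    names: dict = {}
    counter = 0
    for node in dtree.preorder_node_iter():
        if node.taxon is not None and node.taxon.label:
            name = str(node.taxon.label)
        elif node.label:
            name = str(node.label)
        else:
            name = f"node{counter}"
        while name in names.values():
            counter += 1
            name = f"node{counter}"
        names[id(node)] = name
        counter += 1

    root = dtree.seed_node
    branches = []
    for node in dtree.preorder_node_iter():
        if node is root:
            continue
        if node.edge.length is None:
            raise FormatError(
                f"node {names[id(node)]!r} has no branch length"
            )
        length = float(node.edge.length)
        if length <= 0:
            raise ValidationError(
                f"node {names[id(node)]!r} has non-positive branch length {length}"
            )
        branches.append(
            Branch(parent=names[id(node.parent_node)], child=names[id(node)], length=length)
        )
    if not branches:
        raise FormatError("tree has no branches")
    return Tree(root=names[id(root)], branches=branches)


# ---------------------------------------------------------------------------
# Reference filtering
# ---------------------------------------------------------------------------

def filter_reference(
    cm: CountMatrix,
    min_cells_per_type: int = 50,
    min_cells_per_peak: int = 0,
    min_peaks_per_cell: int = 0,
) -> CountMatrix:
    """Filter a reference matrix: small cell types, sparse peaks, empty cells.

    Filters are applied in the order type -> peak -> cell and the pass is
    repeated until nothing changes, so the result is a fixed point (applying
    the filter twice equals applying it once). The type filter only applies
    when a ``cell_type`` column is present.
    """
    current = cm
    while True:
        peak_keep = np.ones(current.npeak, dtype=bool)
        cell_keep = np.ones(current.ncell, dtype=bool)

        if min_cells_per_type > 0 and "cell_type" in current.cells.columns:
            sizes = current.cells["cell_type"].value_counts()
            small = set(sizes[sizes < min_cells_per_type].index)
            cell_keep &= ~current.cells["cell_type"].isin(small).to_numpy()

        csc = current.counts.tocsc()
        sub = csc[:, np.flatnonzero(cell_keep)]
        cells_per_peak = np.asarray((sub > 0).sum(axis=1)).ravel()
        peak_keep &= cells_per_peak >= min_cells_per_peak

        sub2 = current.counts[np.flatnonzero(peak_keep), :]
        peaks_per_cell = np.asarray((sub2 > 0).sum(axis=0)).ravel()
        cell_keep &= peaks_per_cell >= min_peaks_per_cell

        if cell_keep.all() and peak_keep.all():
            return current
        if not cell_keep.any():
            raise EmptyResultError("filtering removed every cell")
        current = current.subset(np.flatnonzero(peak_keep), np.flatnonzero(cell_keep))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

MODES = ("pseudo_cell_type", "discrete", "continuous")
ACTIVATIONS = ("softplus", "exponential")
COUNT_MODELS = ("poisson", "bernoulli")


@dataclass
class SimConfig:
    """Full specification of one simulation run.

    ``sigma`` is the standard deviation of the Gaussian cell-embedding noise
    (the paper-facing dispersion knob); ``eta`` the probability of zeroing a
    peak-effect entry; ``nembed``/``nhete`` the total and heterogeneous
    embedding dimensions.
    """

    mode: str = "discrete"
    ncell: Optional[int] = None  # default: mirror the reference
    npeak: Optional[int] = None
    nembed: int = 12
    nhete: int = 10
    sigma: float = 0.5
    eta: float = 0.5
    activation: str = "softplus"
    count_model: str = "poisson"
    covariance: Optional[np.ndarray] = None  # discrete mode, npop x npop
    pop_sizes: Optional[Sequence[int]] = None
    tree: Optional[str] = None  # Newick string, continuous mode
    batches: list = field(default_factory=list)  # list[BatchSpec]
    hubs: list = field(default_factory=list)  # list[HubSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def npop(self) -> Optional[int]:
        if self.covariance is not None:
            return int(np.asarray(self.covariance).shape[0])
        if self.pop_sizes is not None:
            return len(self.pop_sizes)
        return None

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ParameterError(f"unknown mode {self.mode!r}")
        if self.activation not in ACTIVATIONS:
            raise ParameterError(f"unknown activation {self.activation!r}")
        if self.count_model not in COUNT_MODELS:
            raise ParameterError(f"unknown count model {self.count_model!r}")
        for name in ("nembed", "nhete"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        if self.mode != "pseudo_cell_type" and self.nhete >= self.nembed:
            raise ParameterError("nhete must be < nembed")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ParameterError("eta must lie in [0, 1]")
        if self.mode == "discrete":
            if self.covariance is None:
                raise ParameterError("discrete mode requires a covariance matrix")
            cov = np.asarray(self.covariance, dtype=float)
            if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
                raise ValidationError("covariance must be square")
            if not np.allclose(cov, cov.T):
                raise ValidationError("covariance must be symmetric")
            eig = np.linalg.eigvalsh(cov)
            if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
                raise ValidationError(
                    f"covariance is not positive semi-definite "
                    f"(smallest eigenvalue {eig.min():.3g})"
                )
            self.covariance = cov
            if self.pop_sizes is not None and len(self.pop_sizes) != cov.shape[0]:
                raise ValidationError("pop_sizes length must equal covariance size")
        if self.mode == "continuous" and self.tree is None:
            raise ParameterError("continuous mode requires a Newick tree")

    def resolve_pop_sizes(self, ncell: int) -> np.ndarray:
        """Equal split of ncell with the remainder going to earlier populations."""
        if self.pop_sizes is not None:
            sizes = np.asarray(self.pop_sizes, dtype=int)
            if sizes.sum() != ncell:
                raise ValidationError(
                    f"pop_sizes sum to {sizes.sum()}, expected ncell={ncell}"
                )
            return sizes
        npop = self.npop
        if npop is None:
            raise ParameterError("cannot infer the number of populations")
        base = ncell // npop
        sizes = np.full(npop, base, dtype=int)
        sizes[: ncell - base * npop] += 1
        return sizes


def load_config(path: os.PathLike) -> SimConfig:
    """Load a SimConfig from a YAML file."""
    from .effects import BatchSpec, HubSpec  # local import: avoids a cycle

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "covariance" in raw and raw["covariance"] is not None:
        cov = raw["covariance"]
        if isinstance(cov, str):
            cov = pd.read_csv(cov, sep="\t", header=None).to_numpy(dtype=float)
        raw["covariance"] = np.asarray(cov, dtype=float)
    if "tree" in raw and raw["tree"] is not None and os.path.exists(str(raw["tree"])):
        raw["tree"] = Path(raw["tree"]).read_text().strip()
    raw["batches"] = [BatchSpec(**b) for b in raw.get("batches", [])]
    raw["hubs"] = [
        HubSpec(
            hub_id=h["hub_id"],
            peak_indices=np.asarray(h["peak_indices"], dtype=int),
            interactive_indices=np.asarray(h["interactive_indices"], dtype=int),
            effect_sd=float(h.get("effect_sd", 0.1)),
        )
        for h in raw.get("hubs", [])
    ]
    return SimConfig(**raw)
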