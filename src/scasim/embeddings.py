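"""Latent embedding generation.

The simulator represents cells and peaks in a shared latent space:

* CEM (cell embedding matrix), ``C`` (nembed x ncell) — split into a
  homogeneous block shared by all cells and a heterogeneous block carrying
  cell-state structure (discrete population centers or Brownian trajectories).
* PEM (peak-wise effect matrix), ``P`` (npeak x nembed) — maps embeddings to
  peak-level accessibility propensity; sparsified entrywise with rate ``eta``.
* CEV (cell-wise effect vector), ``l`` (nembed) — its projection ``l @ C``
  ranks cells by intended library size.

All generators take an explicit ``numpy.random.Generator`` and are
bit-deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import ParameterError, ValidationError
from .io_formats import Tree

__all__ = [
    "EmbeddingSet",
    "TreePlacement",
    "generate_homogeneous_cem",
    "generate_pem",
    "generate_cev",
    "generate_discrete_centers",
    "generate_discrete_cem",
    "place_cells_on_tree",
    "generate_continuous_cem",
    "assemble_cem",
]


@dataclass
class EmbeddingSet:
    """All latent factors of one simulation, plus the mode tag.

    ``H`` (nhete x npop population centers) is retained in discrete mode so
    parameter recovery can be tested against it.
    """

    C_homo: np.ndarray
    P: np.ndarray
    l: np.ndarray
    mode: str
    C_hete: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None

    @property
    def C(self) -> np.ndarray:
        return assemble_cem(self.C_homo, self.C_hete)


def generate_homogeneous_cem(
    n_homo: int, ncell: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """I.i.d. Normal(1, sigma^2) entries — shared cellular background."""
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if n_homo < 1 or ncell < 1:
        raise ParameterError("n_homo and ncell must be >= 1")
    return rng.normal(1.0, sigma, size=(n_homo, ncell))


def generate_pem(
    npeak: int, nembed: int, eta: float, rng: np.random.Generator
) -> np.ndarray:
    """Standard-normal entries, then zeroed with probability ``eta``.

    The zeroing mask is drawn row-major (one row of Bernoulli decisions at a
    time), so results are independent of how callers batch the rows.
    """
    if not 0.0 <= eta <= 1.0:
        raise ParameterError("eta must lie in [0, 1]")
    P = rng.standard_normal(size=(npeak, nembed))
    mask = rng.random(size=(npeak, nembed)) < eta
    P[mask] = 0.0
    return P


def generate_cev(nembed: int, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal effect weights controlling library-size ordering."""
    if nembed < 1:
        raise ParameterError("nembed must be >= 1")
    return rng.standard_normal(nembed)


def generate_discrete_centers(
    npop: int,
    nhete: int,
    covariance: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Population centers H (nhete x npop).

    Each of the nhete rows is an independent draw from a multivariate normal
    with mean the all-ones vector and the user covariance, so off-diagonal
    covariance entries control how similar two populations' center
    coordinates are.
    """
    cov = np.asarray(covariance, dtype=float)
    if npop < 2:
        raise ParameterError("npop must be >= 2")
    if cov.shape != (npop, npop) or not np.allclose(cov, cov.T):
        raise ValidationError("covariance must be a symmetric npop x npop matrix")
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-8 * max(1.0, abs(eig).max()):
        raise ValidationError(
            f"covariance not PSD (smallest eigenvalue {eig.min():.3g})"
        )
    return rng.multivariate_normal(np.ones(npop), cov, size=nhete)


def generate_discrete_cem(
    H: np.ndarray,
    pop_sizes,
    sigma: float,
    rng: np.random.Generator,
):
    """Heterogeneous CEM for discrete populations.

    Cell j in population k receives entry i ~ Normal(H[i, k], sigma^2).
    Returns ``(C_hete, labels)`` with integer population labels.
    """
    H = np.asarray(H, dtype=float)
    sizes = np.asarray(pop_sizes, dtype=int)
    if (sizes <= 0).any():
        raise ValidationError("every population must receive >= 1 cell")
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    if sizes.shape[0] != H.shape[1]:
        raise ValidationError("pop_sizes length must equal the number of centers")
    labels = np.repeat(np.arange(sizes.shape[0]), sizes)
    C = H[:, labels] + rng.normal(0.0, sigma, size=(H.shape[0], labels.size))
    return C, labels


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class TreePlacement:
    """Cells laid out along the branches of a rooted tree.

    Cells are emitted branch-by-branch in Newick preorder, within a branch at
    uniform spacing length/n from the branch's parent node. ``predecessor``
    points at the previous cell along the path from the root (-1 for the
    virtual root cell, which is not itself a data cell); ``interval`` is the
    tree distance to that predecessor and is the Brownian increment variance.
    """

    branch: np.ndarray  # branch (child-node) name per cell
    position: np.ndarray  # distance from the branch's parent node
    pseudotime: np.ndarray  # distance from the root
    predecessor: np.ndarray  # index of previous cell, -1 = virtual root
    interval: np.ndarray

    @property
    def ncell(self) -> int:
        return self.branch.shape[0]


def _allocate_cells(lengths: np.ndarray, ncell: int) -> np.ndarray:
    """Largest-remainder allocation proportional to branch length, >= 1 each.

    Ties in the fractional remainders are broken by branch (Newick) order;
    empty branches steal one cell from the currently largest branch.
    """
    total = lengths.sum()
    quota = ncell * lengths / total
    n = np.floor(quota).astype(int)
    remainder = quota - n
    leftover = ncell - n.sum()
    # stable argsort descending on remainder -> earlier branches win ties
    order = np.argsort(-remainder, kind="stable")
    for b in order[:leftover]:
        n[b] += 1
    while (n == 0).any():
        empty = int(np.flatnonzero(n == 0)[0])
        donor = int(np.argmax(n))
        n[donor] -= 1
        n[empty] += 1
    return n


def place_cells_on_tree(
    tree: Tree, ncell: int, rng: Optional[np.random.Generator] = None
) -> TreePlacement:
    """Assign ``ncell`` cells to branches proportionally to branch length.

    The rng argument is accepted for interface symmetry; the placement itself
    is deterministic (uniform spacing, largest-remainder rounding).
    """
    branches = tree.branches
    if ncell < len(branches):
        raise ParameterError(
            f"ncell={ncell} but the tree has {len(branches)} branches; "
            "every branch must hold at least one cell"
        )
    lengths = np.array([b.length for b in branches], dtype=float)
    counts = _allocate_cells(lengths, ncell)
    depths = tree.node_depths()

    branch_names, positions, pseudotimes, predecessors, intervals = [], [], [], [], []
    last_cell_of_branch: dict = {}  # child-node name -> index of its last cell
    for b, nb in zip(branches, counts):
        spacing = b.length / nb
        # predecessor of this branch's first cell: last cell of parent branch
        prev = last_cell_of_branch.get(b.parent, -1)
        for k in range(1, nb + 1):
            idx = len(branch_names)
            branch_names.append(b.child)
            positions.append(k * spacing)
            pseudotimes.append(depths[b.parent] + k * spacing)
            predecessors.append(prev)
            intervals.append(spacing)
            prev = idx
        last_cell_of_branch[b.child] = prev
    return TreePlacement(
        branch=np.array(branch_names),
        position=np.array(positions),
        pseudotime=np.array(pseudotimes),
        predecessor=np.array(predecessors, dtype=int),
        interval=np.array(intervals),
    )


def generate_continuous_cem(
    placement: TreePlacement,
    nhete: int,
    sigma: float,
    rng: np.random.Generator,
):
    """Brownian-motion heterogeneous CEM along a tree placement.

    Per dimension independently: the virtual root value ~ Normal(1, sigma^2);
    each cell's value is its predecessor's value plus a zero-mean Gaussian
    increment whose variance equals the tree distance between them. Returns
    ``(C_hete, branch_labels, pseudotime)``.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    ncell = placement.ncell
    root = rng.normal(1.0, sigma, size=nhete)
    C = np.empty((nhete, ncell))
    sd = np.sqrt(placement.interval)
    for j in range(ncell):
        prev = root if placement.predecessor[j] < 0 else C[:, placement.predecessor[j]]
        C[:, j] = prev + rng.normal(0.0, sd[j], size=nhete)
    return C, placement.branch.copy(), placement.pseudotime.copy()


def assemble_cem(
    C_homo: np.ndarray, C_hete: Optional[np.ndarray] = None
) -> np.ndarray:
    """Stack homogeneous over heterogeneous blocks; hete may be absent."""
    if C_hete is None:
        return np.asarray(C_homo)
    C_homo = np.asarray(C_homo)
    C_hete = np.asarray(C_hete)
    if C_homo.shape[1] != C_hete.shape[1]:
        raise ValidationError(
            f"column mismatch: homogeneous block has {C_homo.shape[1]} cells, "
            f"heterogeneous block has {C_hete.shape[1]}"
        )
    return np.vstack([C_homo, C_hete])
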