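"""Optional ground-truth structure: batch effects and cis-regulatory hubs.

Biological batch effects perturb the peak-effect matrix (PEM) with Gaussian
noise before correction, so batches differ in which peaks respond to which
embedding while cell populations stay aligned (population centers are shared
across batches). Technical batch effects perturb the final Poisson mean
matrix, after all corrections, so they survive into the output.

Interaction hubs remodel the PEM: every peak flagged interactive within a
hub has its row replaced by a shared hub effect vector plus a small
peak-specific deviation, making those peaks co-accessible by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError
from .correction import ParamMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BatchSpec",
    "HubSpec",
    "add_biological_batch",
    "add_technical_batch",
    "inject_interaction_hubs",
    "simulate_batches",
    "hubs_from_regions",
]


@dataclass
class BatchSpec:
    """One batch: Gaussian noise parameters and optional population sizes.

    ``ncell_per_pop`` overrides the per-population cell counts for this batch
    (a zero drops that population from the batch, mimicking batch-specific
    rare cell types).
    """

    batch_id: str
    kind: str = "biological"  # or "technical"
    noise_mean: float = 0.0
    noise_sd: float = 0.0
    ncell_per_pop: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.kind not in ("biological", "technical"):
            raise ParameterError(f"unknown batch kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass
class HubSpec:
    """A peak hub with a designated interactive subset.

    ``accessibility_quantile`` pins the hub's peaks to that quantile of the
    simulated peak-summation profile (real benchmark hubs are built on
    accessible gene-region peaks, not on near-silent ones; a co-accessibility
    signal is only observable where counts are non-trivial).
    """

    hub_id: str
    peak_indices: np.ndarray
    interactive_indices: np.ndarray
    effect_sd: float = 0.1
    accessibility_quantile: float = 0.98

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=int)
        self.interactive_indices = np.asarray(self.interactive_indices, dtype=int)
        if self.effect_sd <= 0:
            raise ParameterError("effect_sd must be > 0")
        if not 0.0 <= self.accessibility_quantile <= 1.0:
            raise ParameterError("accessibility_quantile must lie in [0, 1]")
        if not np.isin(self.interactive_indices, self.peak_indices).all():
            raise ValidationError(
                f"hub {self.hub_id!r}: interactive peaks must belong to the hub"
            )


def add_biological_batch(
    P: np.ndarray, spec: BatchSpec, rng: np.random.Generator
) -> np.ndarray:
    """PEM plus elementwise Gaussian noise; the CEM is left untouched."""
    if spec.kind != "biological":
        raise ParameterError(f"batch {spec.batch_id!r} is not biological")
    return np.asarray(P, dtype=float) + rng.normal(
        spec.noise_mean, spec.noise_sd, size=np.shape(P)
    )


def add_technical_batch(
    m: ParamMatrix, spec: BatchSpec, rng: np.random.Generator
) -> ParamMatrix:
    """Final mean matrix plus Gaussian noise, clamped at zero."""
    if spec.kind != "technical":
        raise ParameterError(f"batch {spec.batch_id!r} is not technical")
    if m.stage != "final":
        raise ParameterError("technical noise applies to the final matrix")
    noisy = m.values + rng.normal(spec.noise_mean, spec.noise_sd, size=m.values.shape)
    n_clamped = int((noisy < 0).sum())
    if n_clamped:
        logger.warning(
            "technical batch %s: clamped %d negative entries to zero",
            spec.batch_id, n_clamped,
        )
    return ParamMatrix(np.maximum(noisy, 0.0), "final")


def inject_interaction_hubs(
    P: np.ndarray,
    hubs: List[HubSpec],
    rng: np.random.Generator,
    eta: float = 0.5,
    orthogonal_to: Optional[np.ndarray] = None,
):
    """Remodel the PEM so each hub's interactive peaks share an effect vector.

    For every hub one effect vector is drawn like a PEM row (standard normal,
    entries zeroed with probability ``eta``); each interactive peak's row is
    replaced by that vector plus Normal(0, effect_sd^2) per-entry deviations.

    ``orthogonal_to`` (typically the cell-wise effect vector that orders
    library sizes) removes that direction from every hub effect vector, so
    the encoded co-accessibility is not confounded with sequencing depth —
    a depth-aligned hub signal would be erased by the depth normalization
    every co-accessibility method applies, making the ground truth
    unrecoverable in principle.

    Returns ``(P', truth)`` where truth is a per-peak DataFrame with hub_id
    and interactive columns.
    """
    P = np.array(P, dtype=float, copy=True)
    npeak, nembed = P.shape
    seen = np.zeros(npeak, dtype=bool)
    hub_id = np.array([""] * npeak, dtype=object)
    interactive = np.zeros(npeak, dtype=bool)
    for hub in hubs:
        if hub.peak_indices.size and (
            hub.peak_indices.min() < 0 or hub.peak_indices.max() >= npeak
        ):
            raise ValidationError(f"hub {hub.hub_id!r}: peak index out of range")
        if seen[hub.peak_indices].any():
            raise ValidationError(f"hub {hub.hub_id!r} overlaps another hub")
        seen[hub.peak_indices] = True
        w = rng.standard_normal(nembed)
        w[rng.random(nembed) < eta] = 0.0
        if orthogonal_to is not None:
            u = np.asarray(orthogonal_to, dtype=float)
            u = u / np.linalg.norm(u)
            w = w - (w @ u) * u
        # fixed effect strength: the eta mask leaves the vector norm to
        # chance, but a ground-truth program must have controlled, dominant
        # signal; effect_sd stays the difficulty knob
        norm = np.linalg.norm(w)
        if norm > 1e-12:
            w *= np.sqrt(nembed) / norm
        dev = rng.normal(0.0, hub.effect_sd, size=(hub.interactive_indices.size, nembed))
        P[hub.interactive_indices, :] = w[None, :] + dev
        hub_id[hub.peak_indices] = hub.hub_id
        interactive[hub.interactive_indices] = True
    truth = pd.DataFrame({"hub_id": hub_id, "interactive": interactive})
    return P, truth


def hubs_from_regions(
    peaks: pd.DataFrame,
    regions: pd.DataFrame,
    rng: np.random.Generator,
    flank: int = 50_000,
    min_peaks: int = 50,
    n_interactive: int = 40,
    effect_sd: float = 0.1,
) -> List[HubSpec]:
    """Build hubs from genomic regions (e.g. gene bodies extended by a flank).

    Each region is extended by ``flank`` on both sides; peaks fully inside
    the extended region form a candidate hub. Hubs with fewer than
    ``min_peaks`` peaks or overlapping a previously accepted hub are dropped;
    ``n_interactive`` peaks per hub are chosen at random as interactive.
    """
    hubs: List[HubSpec] = []
    used = np.zeros(len(peaks), dtype=bool)
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    chroms = peaks["chrom"].to_numpy()
    for _, region in regions.iterrows():
        lo = int(region["start"]) - flank
        hi = int(region["end"]) + flank
        inside = np.flatnonzero(
            (chroms == region["chrom"]) & (starts >= lo) & (ends <= hi)
        )
        if inside.size < min_peaks or used[inside].any():
            continue
        used[inside] = True
        interactive = rng.choice(
            inside, size=min(n_interactive, inside.size), replace=False
        )
        hubs.append(
            HubSpec(
                hub_id=str(region.get("name", f"hub_{len(hubs) + 1}")),
                peak_indices=inside,
                interactive_indices=np.sort(interactive),
                effect_sd=effect_sd,
            )
        )
    return hubs


def simulate_batches(reference, config, specs: Optional[List[BatchSpec]] = None):
    """Generate one discrete-mode dataset per batch and concatenate columns.

    Population centers and the base PEM are shared across batches; biological
    specs perturb the PEM per batch, technical specs perturb the final mean
    matrix. Cell metadata gains ``batch`` and ``population`` columns; clashing
    barcodes are suffixed with the batch id. Requires >= 2 batch specs.
    """
    from . import pipeline  # local import: pipeline imports this module

    specs = list(specs if specs is not None else config.batches)
    if len(specs) < 2:
        raise ParameterError("simulate_batches requires at least two batch specs")
    return pipeline._simulate_discrete_batches(reference, config, specs)
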