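"""End-to-end simulation drivers for the three modes, plus fixtures.

Every run derives all randomness from ``config.seed`` through named stage
streams (see :mod:`scasim._rng`), so identical configs give bit-identical
outputs and adding a stage never perturbs the others.

Sampled library-size and sparsity targets are paired comonotonically (the
cell ranked larger in library size also ranks larger in non-zero
proportion). The marginal distributions are the fitted ones either way; the
coupling mirrors the tight empirical dependence between the two statistics
in real data and keeps the per-cell targets jointly attainable.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._rng import stage_rng
from .correction import (
    CellwiseReport,
    CorrectionTargets,
    ParamMatrix,
    activate,
    correct_joint,
    raw_param_matrix,
    sample_counts_bernoulli,
    sample_counts_poisson,
)
from .effects import BatchSpec, add_biological_batch, add_technical_batch, inject_interaction_hubs
from .embeddings import (
    EmbeddingSet,
    assemble_cem,
    generate_cev,
    generate_continuous_cem,
    generate_discrete_cem,
    generate_discrete_centers,
    generate_homogeneous_cem,
    generate_pem,
    place_cells_on_tree,
)
from .exceptions import ParameterError
from .io_formats import (
    CountMatrix,
    SimConfig,
    default_cell_table,
    default_peak_table,
    parse_newick,
    write_count_matrix,
)
from .stat_fit import StatModels, TripleSampler, build_stat_models

__all__ = [
    "SimulationResult",
    "SimulationRun",
    "simulate_pseudo",
    "simulate_discrete",
    "simulate_continuous",
    "make_fixture",
    "run_simulation",
]


@dataclass
class SimulationResult:
    """A simulated matrix plus everything needed to audit it."""

    cm: CountMatrix
    embeddings: object  # EmbeddingSet or dict of them (pseudo mode)
    targets: object  # CorrectionTargets or dict of them
    report: object  # CellwiseReport or dict of them
    models: StatModels
    final_lambda: object = None  # ParamMatrix or dict of them


def _comonotone_targets(
    sampler: TripleSampler,
    npeak: int,
    ncell: int,
    cev_scores: np.ndarray,
    rng: np.random.Generator,
    peak_targets: Optional[np.ndarray] = None,
) -> CorrectionTargets:
    """Sample targets; couple library-size and sparsity ranks comonotonically.

    The peak targets are rescaled to the sampled library total: the row and
    column sums of one mean matrix necessarily share a single total, so the
    two independently sampled margins must be reconciled before correction.
    ``peak_targets`` may be pre-sampled (batch simulation shares one draw of
    the dataset-level peak profile across batches).
    """
    if peak_targets is None:
        peak_targets = sampler.sample_peak(npeak, rng)
    lib = np.sort(sampler.sample_lib(ncell, rng))
    prop = np.sort(sampler.sample_prop(ncell, rng))
    if peak_targets.sum() > 0:
        peak_targets = peak_targets * (lib.sum() / peak_targets.sum())
    # place both in the cev order correct_cellwise will reproduce: the cell
    # with the r-th largest score gets the r-th largest lib AND prop target
    order = np.argsort(np.asarray(cev_scores), kind="stable")
    lib_targets = np.empty(ncell)
    prop_targets = np.empty(ncell)
    lib_targets[order] = lib
    prop_targets[order] = prop
    return CorrectionTargets(
        lib_targets=lib_targets,
        sparsity_targets=prop_targets,
        peak_targets=peak_targets,
        cev_scores=np.asarray(cev_scores, dtype=float),
        provenance=sampler.backend,
    )


def _generate_counts(
    P: np.ndarray,
    C: np.ndarray,
    l: np.ndarray,
    sampler: TripleSampler,
    config: SimConfig,
    rng_targets: np.random.Generator,
    rng_counts: np.random.Generator,
    peaks: Optional[pd.DataFrame] = None,
    cells: Optional[pd.DataFrame] = None,
    technical_specs: Optional[List[BatchSpec]] = None,
    rng_noise: Optional[np.random.Generator] = None,
    peak_targets: Optional[np.ndarray] = None,
    peak_rank_order: Optional[np.ndarray] = None,
):
    """Shared tail of every mode: activate, correct, (perturb), sample."""
    act = activate(raw_param_matrix(P, C), config.activation)
    npeak, ncell = act.values.shape
    cev_scores = np.asarray(l) @ np.asarray(C)
    targets = _comonotone_targets(
        sampler, npeak, ncell, cev_scores, rng_targets, peak_targets=peak_targets
    )
    final, report, spars_used = correct_joint(
        act,
        targets.peak_targets,
        targets.lib_targets,
        targets.sparsity_targets,
        targets.cev_scores,
        peak_rank_order=peak_rank_order,
    )
    targets.sparsity_targets = spars_used  # reflects any feasibility clamp
    for spec in technical_specs or []:
        final = add_technical_batch(final, spec, rng_noise)
    sample = (
        sample_counts_bernoulli
        if config.count_model == "bernoulli"
        else sample_counts_poisson
    )
    cm = sample(final, rng_counts, peaks=peaks, cells=cells)
    return cm, targets, report, final


# ---------------------------------------------------------------------------
# Pseudo-cell-type mode
# ---------------------------------------------------------------------------

def simulate_pseudo(
    reference: CountMatrix,
    config: SimConfig,
    details: bool = False,
):
    """Per cell type: homogeneous-only embeddings, per-type statistic models.

    Output cell counts per type default to the reference's counts. The cell
    table keeps the ``cell_type`` labels.
    """
    if "cell_type" not in reference.cells.columns:
        raise ParameterError("pseudo_cell_type mode requires reference cell labels")
    npeak = config.npeak or reference.npeak
    models = build_stat_models(reference, "pseudo_cell_type")
    type_sizes = reference.cells["cell_type"].value_counts(sort=False)

    parts, cell_tables = [], []
    emb_map: Dict[str, EmbeddingSet] = {}
    tgt_map, rep_map = {}, {}
    for t in models.cell_types:
        nt = int(type_sizes[t])
        rng_cem = stage_rng(config.seed, f"cem_homo:{t}")
        rng_pem = stage_rng(config.seed, f"pem:{t}")
        rng_cev = stage_rng(config.seed, f"cev:{t}")
        rng_tgt = stage_rng(config.seed, f"targets:{t}")
        rng_cnt = stage_rng(config.seed, f"counts:{t}")
        # no heterogeneous block: the reference labels carry the heterogeneity
        C = generate_homogeneous_cem(config.nembed, nt, config.sigma, rng_cem)
        P = generate_pem(npeak, config.nembed, config.eta, rng_pem)
        l = generate_cev(config.nembed, rng_cev)
        cells = pd.DataFrame(
            {"barcode": [f"{t}_cell_{j}" for j in range(nt)], "cell_type": t}
        )
        cm_t, targets, report, final = _generate_counts(
            P, C, l, models.get(t), config, rng_tgt, rng_cnt,
            peaks=default_peak_table(npeak), cells=cells,
        )
        parts.append(cm_t.counts)
        cell_tables.append(cm_t.cells)
        emb_map[t] = EmbeddingSet(C_homo=C, P=P, l=l, mode="pseudo_cell_type")
        tgt_map[t], rep_map[t] = targets, report

    cm = CountMatrix(
        sp.hstack(parts, format="csr"),
        default_peak_table(npeak),
        pd.concat(cell_tables, ignore_index=True),
    )
    if details:
        return SimulationResult(cm, emb_map, tgt_map, rep_map, models)
    return cm


# ---------------------------------------------------------------------------
# Discrete mode
# ---------------------------------------------------------------------------

def _discrete_embeddings(config: SimConfig, ncell: int, pop_sizes, seed_suffix=""):
    rng_centers = stage_rng(config.seed, f"centers{seed_suffix}")
    rng_hete = stage_rng(config.seed, f"cem_hete{seed_suffix}")
    rng_homo = stage_rng(config.seed, f"cem_homo{seed_suffix}")
    H = generate_discrete_centers(
        len(pop_sizes), config.nhete, _subset_cov(config.covariance, pop_sizes), rng_centers
    )
    C_hete, labels = generate_discrete_cem(H, pop_sizes, config.sigma, rng_hete)
    C_homo = generate_homogeneous_cem(
        config.nembed - config.nhete, ncell, config.sigma, rng_homo
    )
    return H, C_homo, C_hete, labels


def _subset_cov(cov, pop_sizes):
    return np.asarray(cov, dtype=float)[: len(pop_sizes), : len(pop_sizes)]


def _hub_rank_order(row_sums: np.ndarray, hubs) -> np.ndarray:
    """Accessibility rank order with each hub pinned at its target quantile.

    Non-hub peaks keep their activated-row-sum ranks; each hub's peaks are
    inserted as one block at ``accessibility_quantile`` of the ranking, so
    the peak-wise correction assigns them peak-summation targets around that
    quantile of the fitted profile.
    """
    npeak = row_sums.shape[0]
    order = np.argsort(row_sums, kind="stable")
    all_hub = np.concatenate([h.peak_indices for h in hubs])
    out = list(order[~np.isin(order, all_hub)])
    for hub in sorted(hubs, key=lambda h: h.accessibility_quantile):
        at = int(round(hub.accessibility_quantile * len(out)))
        block = hub.peak_indices[np.argsort(row_sums[hub.peak_indices], kind="stable")]
        out[at:at] = list(block)
    assert len(out) == npeak
    return np.asarray(out, dtype=int)


def simulate_discrete(
    reference: CountMatrix,
    config: SimConfig,
    models: Optional[StatModels] = None,
    details: bool = False,
):
    """Discrete populations: MVN centers + Gaussian per-cell noise.

    Ground-truth ``population`` labels are written into the cell table; hub
    ground truth (if any) into the peak table.
    """
    ncell = config.ncell or reference.ncell
    npeak = config.npeak or reference.npeak
    if models is None:
        models = build_stat_models(reference, "discrete")
    pop_sizes = config.resolve_pop_sizes(ncell)
    H, C_homo, C_hete, labels = _discrete_embeddings(config, ncell, pop_sizes)
    C = assemble_cem(C_homo, C_hete)
    P = generate_pem(npeak, config.nembed, config.eta, stage_rng(config.seed, "pem"))
    l = generate_cev(config.nembed, stage_rng(config.seed, "cev"))

    peaks = default_peak_table(npeak)
    rank_order = None
    if config.hubs:
        P, peak_truth = inject_interaction_hubs(
            P, config.hubs, stage_rng(config.seed, "hubs"), eta=config.eta,
            orthogonal_to=l,
        )
        peaks = pd.concat([peaks, peak_truth], axis=1)
        row_sums = activate(raw_param_matrix(P, C), config.activation).values.sum(axis=1)
        rank_order = _hub_rank_order(row_sums, config.hubs)

    cells = default_cell_table(ncell)
    cells["population"] = [f"pop{k}" for k in labels]
    cm, targets, report, final = _generate_counts(
        P, C, l, models.get(), config,
        stage_rng(config.seed, "targets"), stage_rng(config.seed, "counts"),
        peaks=peaks, cells=cells, peak_rank_order=rank_order,
    )
    if details:
        emb = EmbeddingSet(
            C_homo=C_homo, P=P, l=l, mode="discrete", C_hete=C_hete, H=H
        )
        return SimulationResult(cm, emb, targets, report, models, final)
    return cm


def _simulate_discrete_batches(
    reference: CountMatrix, config: SimConfig, specs: List[BatchSpec]
):
    """Shared centers/PEM across batches; per-batch noise, cells and counts."""
    models = build_stat_models(reference, "discrete")
    npeak = config.npeak or reference.npeak
    base_ncell = config.ncell or reference.ncell
    P_base = generate_pem(
        npeak, config.nembed, config.eta, stage_rng(config.seed, "pem")
    )
    l = generate_cev(config.nembed, stage_rng(config.seed, "cev"))
    # centers shared across batches so the same populations exist everywhere
    full_sizes = config.resolve_pop_sizes(base_ncell)
    H = generate_discrete_centers(
        len(full_sizes), config.nhete, config.covariance,
        stage_rng(config.seed, "centers"),
    )
    # one draw of the dataset-level peak profile, shared by all batches:
    # batches differ in cells and injected noise, not in which peaks are open
    shared_peaks = models.get().sample_peak(
        npeak, stage_rng(config.seed, "targets:shared")
    )

    # per-batch cell embeddings first: the dataset-level peak rank order is
    # derived from the first batch's noise-free activated matrix and shared,
    # so batches differ only through their cells and the injected noise
    prepared = []
    for spec in specs:
        sizes = (
            np.asarray(spec.ncell_per_pop, dtype=int)
            if spec.ncell_per_pop is not None
            else full_sizes
        )
        present = np.flatnonzero(sizes > 0)
        ncell_b = int(sizes[present].sum())
        rng_hete = stage_rng(config.seed, f"cem_hete:{spec.batch_id}")
        rng_homo = stage_rng(config.seed, f"cem_homo:{spec.batch_id}")
        C_hete, local_labels = generate_discrete_cem(
            H[:, present], sizes[present], config.sigma, rng_hete
        )
        labels = present[local_labels]
        C = assemble_cem(
            generate_homogeneous_cem(
                config.nembed - config.nhete, ncell_b, config.sigma, rng_homo
            ),
            C_hete,
        )
        prepared.append((spec, C, labels, ncell_b))

    base_act = activate(raw_param_matrix(P_base, prepared[0][1]), config.activation)
    shared_order = np.argsort(base_act.values.sum(axis=1), kind="stable")

    parts, cell_tables = [], []
    for spec, C, labels, ncell_b in prepared:
        rng_noise = stage_rng(config.seed, f"noise:{spec.batch_id}")
        P = P_base
        technical = []
        if spec.kind == "biological":
            P = add_biological_batch(P_base, spec, rng_noise)
        else:
            technical = [spec]
        cells = pd.DataFrame(
            {
                "barcode": [f"{spec.batch_id}_cell_{j}" for j in range(ncell_b)],
                "population": [f"pop{k}" for k in labels],
                "batch": spec.batch_id,
            }
        )
        cm_b, _, _, _ = _generate_counts(
            P, C, l, models.get(), config,
            stage_rng(config.seed, f"targets:{spec.batch_id}"),
            stage_rng(config.seed, f"counts:{spec.batch_id}"),
            peaks=default_peak_table(npeak), cells=cells,
            technical_specs=technical, rng_noise=rng_noise,
            peak_targets=shared_peaks, peak_rank_order=shared_order,
        )
        parts.append(cm_b.counts)
        cell_tables.append(cm_b.cells)
    return CountMatrix(
        sp.hstack(parts, format="csr"),
        default_peak_table(npeak),
        pd.concat(cell_tables, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# Continuous mode
# ---------------------------------------------------------------------------

def simulate_continuous(
    reference: CountMatrix,
    config: SimConfig,
    models: Optional[StatModels] = None,
    details: bool = False,
):
    """Brownian-motion trajectories on a Newick tree.

    Cells are allocated to branches proportionally to branch length and carry
    ``branch`` and ``pseudotime`` ground truth.
    """
    ncell = config.ncell or reference.ncell
    npeak = config.npeak or reference.npeak
    if models is None:
        models = build_stat_models(reference, "continuous")
    tree = parse_newick(config.tree)
    placement = place_cells_on_tree(tree, ncell)
    C_hete, branches, pseudotime = generate_continuous_cem(
        placement, config.nhete, config.sigma, stage_rng(config.seed, "cem_hete")
    )
    C_homo = generate_homogeneous_cem(
        config.nembed - config.nhete, ncell, config.sigma,
        stage_rng(config.seed, "cem_homo"),
    )
    C = assemble_cem(C_homo, C_hete)
    P = generate_pem(npeak, config.nembed, config.eta, stage_rng(config.seed, "pem"))
    l = generate_cev(config.nembed, stage_rng(config.seed, "cev"))
    cells = default_cell_table(ncell)
    cells["branch"] = branches
    cells["pseudotime"] = pseudotime
    cm, targets, report, final = _generate_counts(
        P, C, l, models.get(), config,
        stage_rng(config.seed, "targets"), stage_rng(config.seed, "counts"),
        peaks=default_peak_table(npeak), cells=cells,
    )
    if details:
        emb = EmbeddingSet(C_homo=C_homo, P=P, l=l, mode="continuous", C_hete=C_hete)
        return SimulationResult(cm, emb, targets, report, models, final)
    return cm


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

def make_fixture(
    npeak: int = 2000,
    ncell: int = 500,
    n_types: int = 2,
    seed: int = 0,
) -> CountMatrix:
    """A reference matrix with known, recoverable statistics.

    Gamma-Poisson counts: long-tailed per-peak propensities (Gamma with shape
    < 1, offset away from zero to emulate a coverage-filtered reference in
    which peaks detected in too few cells have already been removed),
    type-specific boosted peak programs, and per-cell library sizes drawn
    from an equal mixture of two log-normal modes (exp-scale medians 500 and
    2000, log-sd 0.25) so the log library sizes are cleanly bimodal.
    """
    rng = stage_rng(seed, "fixture")
    base = 0.05 + rng.gamma(shape=0.6, scale=2.0, size=npeak)

    boosts = np.ones((n_types, npeak))
    n_program = max(npeak // 10, 1)
    for t in range(n_types):
        idx = rng.choice(npeak, size=n_program, replace=False)
        boosts[t, idx] = 1.0 + rng.gamma(shape=4.0, scale=1.0, size=n_program)

    types = np.repeat(np.arange(n_types), np.diff(np.linspace(0, ncell, n_types + 1).astype(int)))
    mode = rng.random(ncell) < 0.5
    log_lib = np.where(
        mode,
        rng.normal(np.log(500.0), 0.25, size=ncell),
        rng.normal(np.log(2000.0), 0.25, size=ncell),
    )
    lib = np.exp(log_lib)

    rate = base[None, :] * boosts[types, :]  # ncell x npeak
    rate /= rate.sum(axis=1, keepdims=True)
    lam = (rate * lib[:, None]).T  # npeak x ncell
    counts = rng.poisson(lam).astype(np.int64)

    cells = default_cell_table(ncell)
    cells["cell_type"] = [f"type{t}" for t in types]
    return CountMatrix(sp.csr_matrix(counts), default_peak_table(npeak), cells)


# ---------------------------------------------------------------------------
# Run orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationRun:
    """Record of one simulation: config, timings and output paths."""

    config: SimConfig
    seed: int
    stage_seconds: Dict[str, float] = field(default_factory=dict)
    output_paths: Dict[str, object] = field(default_factory=dict)


_MODE_DRIVERS = {
    "pseudo_cell_type": simulate_pseudo,
    "discrete": simulate_discrete,
    "continuous": simulate_continuous,
}


def run_simulation(
    reference: CountMatrix,
    config: SimConfig,
    out_dir=None,
) -> tuple:
    """Dispatch on mode, optionally write the dataset directory.

    Returns ``(CountMatrix, SimulationRun)``.
    """
    run = SimulationRun(config=config, seed=config.seed)
    t0 = time.perf_counter()
    if config.mode == "discrete" and len(config.batches) >= 2:
        from .effects import simulate_batches

        cm = simulate_batches(reference, config)
    else:
        cm = _MODE_DRIVERS[config.mode](reference, config)
    run.stage_seconds["simulate"] = time.perf_counter() - t0
    if out_dir is not None:
        t0 = time.perf_counter()
        run.output_paths = write_count_matrix(cm, out_dir)
        run.stage_seconds["write"] = time.perf_counter() - t0
    return cm, run
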