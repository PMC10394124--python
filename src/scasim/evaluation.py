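"""Statistical and biological evaluation metrics.

Quantile-based comparison of summary statistics (MAD/MAE/RMSE/1-PCC/JSD/KSS),
peak-pair Spearman correlation distributions, the median integration local
inverse Simpson's index (miLISI) for real/synthetic mixing, clustering
agreement scores, and F1 recovery of interactive peaks within hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import scipy.stats
from sklearn.decomposition import TruncatedSVD
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    homogeneity_score,
)
from sklearn.neighbors import NearestNeighbors

from .exceptions import ParameterError, ValidationError
from .io_formats import CountMatrix

__all__ = [
    "QuantileComparison",
    "quantile_compare",
    "peak_pair_correlation",
    "milisi",
    "clustering_scores",
    "interaction_f1",
    "f1_score_sets",
    "lsi_embedding",
    "predict_hub_interactive",
    "batch_separation_test",
]


# ---------------------------------------------------------------------------
# Quantile comparison
# ---------------------------------------------------------------------------

@dataclass
class QuantileComparison:
    statistic: str
    n_quantiles: int
    metrics: Dict[str, float]


_LOG_STATISTICS = {"library_size"}


def quantile_compare(
    real_values: np.ndarray,
    synth_values: np.ndarray,
    statistic: str = "generic",
    n_quantiles: int = 100,
) -> QuantileComparison:
    """Compare two samples of one statistic on paired sample quantiles.

    Library sizes are log-transformed before the quantile metrics (KSS is
    computed on the raw samples; it is invariant to the transform anyway).
    JSD uses histogram densities on a shared 100-bin grid spanning the pooled
    range, in nats, with a 1e-12 floor.
    """
    if n_quantiles < 2:
        raise ParameterError("n_quantiles must be >= 2")
    real_raw = np.asarray(real_values, dtype=float)
    synth_raw = np.asarray(synth_values, dtype=float)
    if real_raw.size == 0 or synth_raw.size == 0:
        raise ValidationError("both samples must be non-empty")
    real = np.log(real_raw) if statistic in _LOG_STATISTICS else real_raw
    synth = np.log(synth_raw) if statistic in _LOG_STATISTICS else synth_raw

    q = np.linspace(0.0, 1.0, n_quantiles)
    qr = np.quantile(real, q)
    qs = np.quantile(synth, q)
    diff = qr - qs

    if np.std(qr) > 0 and np.std(qs) > 0:
        one_minus_pcc = 1.0 - float(scipy.stats.pearsonr(qr, qs).statistic)
    else:  # degenerate: define 0 when the quantile vectors coincide
        one_minus_pcc = 0.0 if np.allclose(qr, qs) else 1.0

    lo = min(real.min(), synth.min())
    hi = max(real.max(), synth.max())
    if hi == lo:
        hi = lo + 1.0
    bins = np.linspace(lo, hi, 101)
    p = np.histogram(real, bins=bins)[0].astype(float)
    qh = np.histogram(synth, bins=bins)[0].astype(float)
    p = np.maximum(p / p.sum(), 1e-12)
    qh = np.maximum(qh / qh.sum(), 1e-12)
    m = 0.5 * (p + qh)
    jsd = 0.5 * float(scipy.stats.entropy(p, m) + scipy.stats.entropy(qh, m))

    kss = float(scipy.stats.ks_2samp(real_raw, synth_raw).statistic)

    return QuantileComparison(
        statistic=statistic,
        n_quantiles=n_quantiles,
        metrics={
            "MAD": float(np.median(np.abs(diff))),
            "MAE": float(np.mean(np.abs(diff))),
            "RMSE": float(np.sqrt(np.mean(diff**2))),
            "one_minus_PCC": one_minus_pcc,
            "JSD": jsd,
            "KSS": kss,
        },
    )


# ---------------------------------------------------------------------------
# Peak-pair correlations
# ---------------------------------------------------------------------------

def _pairwise_spearman(dense: np.ndarray) -> np.ndarray:
    """Full Spearman correlation matrix between rows (average ranks)."""
    ranks = scipy.stats.rankdata(dense, axis=1)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks)
    return np.nan_to_num(corr, nan=0.0)


def peak_pair_correlation(
    real: CountMatrix,
    synth: CountMatrix,
    top_k: int = 2000,
    max_pairs: int = 10**6,
    rng: Optional[np.random.Generator] = None,
):
    """Spearman correlations of all pairs of the top-k accessible peaks.

    Peaks are selected by total accessibility in the real matrix and the same
    peaks are used in the synthetic one. Above ``max_pairs`` pairs a seeded
    subsample is taken (identical pairs in both outputs). Returns
    ``(real_corrs, synth_corrs)``.
    """
    if real.npeak != synth.npeak:
        raise ValidationError("matrices must share the peak space")
    if top_k > real.npeak:
        warnings.warn(f"top_k={top_k} > npeak={real.npeak}; clamped")
        top_k = real.npeak
    sums = np.asarray(real.counts.sum(axis=1)).ravel()
    order = np.argsort(-sums, kind="stable")[:top_k]
    cr = _pairwise_spearman(np.asarray(real.counts[order, :].todense()))
    cs = _pairwise_spearman(np.asarray(synth.counts[order, :].todense()))
    iu = np.triu_indices(top_k, k=1)
    if iu[0].size > max_pairs:
        rng = rng if rng is not None else np.random.default_rng(0)
        keep = rng.choice(iu[0].size, size=max_pairs, replace=False)
        iu = (iu[0][keep], iu[1][keep])
    return cr[iu], cs[iu]


# ---------------------------------------------------------------------------
# miLISI
# ---------------------------------------------------------------------------

def lsi_embedding(counts, n_dims: int = 30, random_state: int = 0) -> np.ndarray:
    """TF-IDF + truncated SVD (LSI), the standard scATAC reduction.

    ``counts`` is peaks x cells (sparse or dense); returns cells x n_dims.
    """
    import scipy.sparse as sp

    X = sp.csr_matrix(counts, dtype=float).T  # cells x peaks
    lib = np.asarray(X.sum(axis=1)).ravel()
    lib = np.maximum(lib, 1.0)
    tf = sp.diags(1.0 / lib) @ X
    df = np.asarray((X > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + X.shape[0] / (1.0 + df))
    tfidf = tf @ sp.diags(idf)
    k = min(n_dims, min(tfidf.shape) - 1)
    svd = TruncatedSVD(n_components=k, random_state=random_state)
    return svd.fit_transform(tfidf)


def _lisi_scores(
    embedding: np.ndarray, labels: np.ndarray, perplexity: int = 30
) -> np.ndarray:
    """Per-cell local inverse Simpson's index with perplexity-calibrated
    Gaussian neighborhood weights over 3*perplexity nearest neighbors."""
    n = embedding.shape[0]
    k = min(3 * perplexity, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dist, idx = nn.kneighbors(embedding)
    dist, idx = dist[:, 1:], idx[:, 1:]  # drop self

    codes = np.unique(labels, return_inverse=True)[1]
    n_labels = codes.max() + 1
    target_entropy = np.log(perplexity)
    scores = np.empty(n)
    for i in range(n):
        d2 = dist[i] ** 2
        lo, hi = 1e-10, 1e10
        beta = 1.0
        for _ in range(60):
            w = np.exp(-beta * (d2 - d2.min()))
            w_sum = w.sum()
            p = w / w_sum
            entropy = -np.sum(p * np.log(np.maximum(p, 1e-300)))
            if abs(entropy - target_entropy) < 1e-5:
                break
            if entropy > target_entropy:  # too flat -> sharpen
                lo = beta
                beta = beta * 2 if hi >= 1e10 else 0.5 * (beta + hi)
            else:
                hi = beta
                beta = 0.5 * (beta + lo)
        label_p = np.bincount(codes[idx[i]], weights=p, minlength=n_labels)
        scores[i] = 1.0 / np.sum(label_p**2)
    return scores


def milisi(
    real: CountMatrix,
    synth: CountMatrix,
    n_dims: int = 30,
    perplexity: int = 30,
    random_state: int = 0,
) -> float:
    """Median LISI over the real/synthetic label in a joint LSI embedding.

    2 means synthetic cells mix perfectly with real cells in every local
    neighborhood; 1 means complete separation.
    """
    import scipy.sparse as sp

    if real.npeak != synth.npeak:
        raise ValidationError("matrices must share the peak space")
    n_total = real.ncell + synth.ncell
    if n_total < 3 * perplexity:
        raise ParameterError(
            f"need at least {3 * perplexity} cells total, got {n_total}"
        )
    joint = sp.hstack([real.counts, synth.counts], format="csr")
    emb = lsi_embedding(joint, n_dims=n_dims, random_state=random_state)
    labels = np.array(["real"] * real.ncell + ["synthetic"] * synth.ncell)
    return float(np.median(_lisi_scores(emb, labels, perplexity=perplexity)))


# ---------------------------------------------------------------------------
# Clustering and interaction scores
# ---------------------------------------------------------------------------

def clustering_scores(truth_labels, pred_labels) -> Dict[str, float]:
    """AMI, ARI and homogeneity between two partitions."""
    truth = np.asarray(truth_labels)
    pred = np.asarray(pred_labels)
    if truth.shape[0] != pred.shape[0]:
        raise ValidationError("label vectors must have equal length")
    return {
        "AMI": float(adjusted_mutual_info_score(truth, pred)),
        "ARI": float(adjusted_rand_score(truth, pred)),
        "Homo": float(homogeneity_score(truth, pred)),
    }


def f1_score_sets(positives: set, predicted: set) -> float:
    """Plain F1 of a predicted set against a positive set."""
    if not predicted:
        return 0.0
    tp = len(positives & predicted)
    if tp == 0:
        return 0.0
    precision = tp / len(predicted)
    recall = tp / len(positives)
    return 2.0 * precision * recall / (precision + recall)


def interaction_f1(
    hubs: Sequence, predicted_sets: List[Sequence[int]]
) -> Dict[str, float]:
    """Best F1 per hub over all predicted peak sets.

    Interactive peaks are positives, the rest of the hub's peaks negatives;
    each predicted set is restricted to the hub's peak universe first.
    """
    if not predicted_sets:
        warnings.warn("empty prediction list: every hub scores F1 = 0")
    out: Dict[str, float] = {}
    for hub in hubs:
        universe = set(int(i) for i in hub.peak_indices)
        positives = set(int(i) for i in hub.interactive_indices)
        best = 0.0
        for pred in predicted_sets:
            restricted = set(int(i) for i in pred) & universe
            best = max(best, f1_score_sets(positives, restricted))
        out[hub.hub_id] = best
    return out


def predict_hub_interactive(cm: CountMatrix, hub) -> np.ndarray:
    """Correlation-threshold oracle for a hub's interactive peaks.

    Computes each hub peak's mean correlation with the other hub peaks on
    depth-normalized log counts (the normalization every co-accessibility
    method applies, so depth-driven common variation does not masquerade as
    interaction) and splits the values at the threshold maximizing the
    between-class variance (Otsu's criterion, robust to single outliers);
    peaks above it are predicted interactive. Intended as an independent
    recovery check, not as an inference method.
    """
    idx = np.asarray(hub.peak_indices, dtype=int)
    dense = np.asarray(cm.counts[idx, :].todense(), dtype=float)
    lib = np.asarray(cm.counts.sum(axis=0), dtype=float).ravel()
    lib = np.maximum(lib, 1.0)
    norm = np.log1p(dense / lib[None, :] * np.median(lib))
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(norm)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, np.nan)
    mean_corr = np.nanmean(corr, axis=1)
    v = np.sort(mean_corr)
    n = v.size
    best, threshold = -np.inf, v[0]
    for k in range(1, n):
        between = k * (n - k) * (v[:k].mean() - v[k:].mean()) ** 2
        if between > best:
            best, threshold = between, 0.5 * (v[k - 1] + v[k])
    return idx[mean_corr > threshold]


def batch_separation_test(
    cm: CountMatrix,
    batch_labels: np.ndarray,
    n_permutations: int = 199,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, float]:
    """Permutation test for batch structure in a joint LSI embedding.

    Batch effects shift cell profiles in the reduced space (the standard
    UMAP/LSI view of integration problems), so the statistic is the squared
    Euclidean distance between the two batches' centroids in the 30-dim LSI
    embedding of the combined matrix. The p-value is the fraction of label
    permutations with a statistic at least as large (add-one estimator).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    labels = np.asarray(batch_labels)
    names = np.unique(labels)
    if names.size != 2:
        raise ParameterError("batch_separation_test expects exactly 2 batches")
    emb = lsi_embedding(cm.counts, n_dims=30, random_state=0)
    mask = labels == names[0]

    def stat(m):
        return float(((emb[m].mean(axis=0) - emb[~m].mean(axis=0)) ** 2).sum())

    observed = stat(mask)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(mask)
        if stat(perm) >= observed:
            hits += 1
    return {
        "statistic": observed,
        "p_value": (1 + hits) / (1 + n_permutations),
    }
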