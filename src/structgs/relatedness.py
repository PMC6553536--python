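"""Genome-wide relatedness and structure summaries.

The genomic relationship matrix follows VanRaden method 1 with in-sample
allele frequencies: W = M - 2p, K = W W' / (2 sum p(1-p)).  Identity-by-state
is the per-pair proportion of shared alleles averaged over markers.  PCA is
run on the column-centred dosage matrix.  LD decay bins squared dosage
correlations of intra-chromosome marker pairs by physical distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, KernelMatrix, PcScores

__all__ = ["grm", "ibs", "pca", "ld_decay", "maf_spectrum"]


def _require_imputed(G: GenotypeMatrix) -> np.ndarray:
    if G.missing.any():
        raise ValueError("genotype matrix must be imputed (no missing calls)")
    return G.dosage


def grm(G: GenotypeMatrix) -> KernelMatrix:
    """VanRaden method-1 genomic relationship matrix.

    Centres each marker by twice its in-sample allele frequency and scales
    the cross-product by 2 * sum p(1-p).  With in-sample frequencies the
    rows and columns of K sum to ~0.  Monomorphic markers contribute
    nothing to either the numerator or the scaling.
    """
    d = _require_imputed(G)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; GRM undefined")
    W = d[:, poly] - 2.0 * p[poly]
    c = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = (W @ W.T) / c
    K = (K + K.T) / 2.0
    return KernelMatrix(values=K, ids=G.individual_ids, kind="GRM")


def ibs(G: GenotypeMatrix) -> KernelMatrix:
    """Pairwise allele-sharing proportion from dosages.

    Per marker a dosage pair contributes 1 - |di - dj| / 2 (1 for equal
    genotypes, 0.5 for one shared allele, 0 for opposite homozygotes),
    averaged over markers.
    """
    d = _require_imputed(G)
    n, m = d.shape
    # mean over markers of 1 - |di-dj|/2, computed blockwise to stay O(n^2 m)
    K = np.empty((n, n))
    for i in range(n):
        K[i] = 1.0 - np.abs(d[i] - d).mean(axis=1) / 2.0
    K = (K + K.T) / 2.0
    return KernelMatrix(values=K, ids=G.individual_ids, kind="IBS")


def pca(G: GenotypeMatrix, d: int) -> PcScores:
    """Top-d principal components of the column-centred dosage matrix.

    Scores are deterministic up to sign (sign fixed so each component's
    largest-magnitude loading is positive).
    """
    X = _require_imputed(G)
    Xc = X - X.mean(axis=0)
    if d < 1 or d > min(G.n_individuals, G.n_markers):
        raise ValueError("d must be in [1, min(n, m)]")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if d > rank:
        raise ValueError(f"d={d} exceeds rank {rank}")
    # deterministic sign: largest-|entry| of each score column positive
    scores = U[:, :d] * s[:d]
    for j in range(d):
        k = np.argmax(np.abs(scores[:, j]))
        if scores[k, j] < 0:
            scores[:, j] *= -1
    eigvals = s[:d] ** 2 / max(G.n_individuals - 1, 1)
    total_var = np.sum(s ** 2) / max(G.n_individuals - 1, 1)
    return PcScores(scores=scores, eigenvalues=eigvals,
                    var_explained=eigvals / total_var, ids=G.individual_ids)


def ld_decay(G: GenotypeMatrix, max_dist: float, n_bins: int = 20) -> pd.DataFrame:
    """Mean squared dosage correlation of intra-chromosome pairs by distance.

    Bins are half-open [lo, hi) over [0, max_dist); pairs at or beyond
    max_dist are skipped.  Returns a DataFrame with columns
    ``bin_lo, bin_hi, n_pairs, mean_r2`` (empty when no chromosome holds
    two markers).
    """
    d = _require_imputed(G)
    edges = np.linspace(0.0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for ch in np.unique(G.chrom):
        idx = np.flatnonzero(G.chrom == ch)
        if idx.size < 2:
            continue
        X = d[:, idx]
        pos = G.pos[idx].astype(float)
        sd = X.std(axis=0)
        ok = sd > 0
        X, pos = X[:, ok], pos[ok]
        if X.shape[1] < 2:
            continue
        Xs = (X - X.mean(axis=0)) / X.std(axis=0)
        R = (Xs.T @ Xs) / X.shape[0]
        iu, ju = np.triu_indices(X.shape[1], k=1)
        dist = np.abs(pos[iu] - pos[ju])
        r2 = R[iu, ju] ** 2
        keep = dist < max_dist
        b = np.searchsorted(edges, dist[keep], side="right") - 1
        b = np.clip(b, 0, n_bins - 1)
        np.add.at(sums, b, r2[keep])
        np.add.at(counts, b, 1)
    rows = [(edges[i], edges[i + 1], counts[i], sums[i] / counts[i])
            for i in range(n_bins) if counts[i] > 0]
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n_pairs", "mean_r2"])


def maf_spectrum(G: GenotypeMatrix, group_labels,
                 percentiles=(5, 25, 50, 75, 95)) -> pd.DataFrame:
    """Per-group minor-allele-frequency percentiles.

    MAF is computed within each group from that group's calls, so the
    spectra reflect group-specific allele-frequency distributions.
    """
    group_labels = np.asarray(group_labels)
    if group_labels.shape[0] != G.n_individuals:
        raise ValueError("one group label per individual required")
    d = G.filled()
    rows = []
    for grp in dict.fromkeys(group_labels):
        sub = d[group_labels == grp]
        if sub.shape[0] == 0:
            raise ValueError(f"empty group {grp!r}")
        n_obs = np.sum(~np.isnan(sub), axis=0)
        with np.errstate(invalid="ignore"):
            freq = np.nansum(sub, axis=0) / (2.0 * n_obs)
        maf = np.minimum(freq, 1 - freq)
        maf = maf[~np.isnan(maf)]
        for q in percentiles:
            rows.append((grp, q, float(np.percentile(maf, q))))
    return pd.DataFrame(rows, columns=["group", "percentile", "maf"])
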