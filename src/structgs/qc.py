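"""Marker quality control: missingness, MAF, Hardy-Weinberg filtering, imputation.

A biallelic marker survives QC iff its missingness is below 20%, its minor
allele frequency exceeds 1/(2N) with N the total number of genotyped
individuals, and its Hardy-Weinberg chi-squared p-value exceeds 1e-4 (all
strict inequalities).  Remaining missing calls are imputed by the mean
dosage, either over the whole panel or within population labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix

__all__ = ["MarkerStats", "compute_marker_stats", "hwe_test",
           "filter_markers", "impute_missing"]


@dataclass
class MarkerStats:
    """Per-marker QC statistics.

    ``n_obs`` counts non-missing individuals per marker; the MAF filter
    threshold 1/(2N) uses the total panel size N instead.
    """

    missingness: np.ndarray
    maf: np.ndarray
    hwe_chi2: np.ndarray
    hwe_p: np.ndarray
    n_obs: np.ndarray
    n_total: int

    def to_frame(self, marker_ids=None) -> pd.DataFrame:
        df = pd.DataFrame({
            "missingness": self.missingness,
            "maf": self.maf,
            "hwe_chi2": self.hwe_chi2,
            "hwe_p": self.hwe_p,
            "n_obs": self.n_obs,
        })
        if marker_ids is not None:
            df.insert(0, "marker", np.asarray(marker_ids))
        return df


def hwe_test(n_AA: int, n_Aa: int, n_aa: int):
    """One-degree-of-freedom chi-squared test of Hardy-Weinberg proportions.

    Expected genotype counts are computed from the observed allele frequency
    (p^2, 2pq, q^2) with no continuity correction.  A monomorphic sample
    gives chi2 = 0, p = 1.

    Returns ``(chi2, p)``.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 0.0, 1.0
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    pval = float(stats.chi2.sf(chi2, df=1))
    return chi2, pval


def compute_marker_stats(G: GenotypeMatrix) -> MarkerStats:
    """Missingness, MAF and HWE test per marker from non-missing calls."""
    if G.n_markers == 0 or G.n_individuals == 0:
        raise ValueError("empty genotype matrix")
    d = G.filled()
    n_total = G.n_individuals
    n_obs = np.sum(~np.isnan(d), axis=0)
    missingness = (n_total - n_obs) / n_total

    with np.errstate(invalid="ignore"):
        alt_freq = np.nansum(d, axis=0) / (2.0 * n_obs)
    maf = np.minimum(alt_freq, 1.0 - alt_freq)
    maf[n_obs == 0] = np.nan   # undefined; flagged for removal downstream

    chi2 = np.zeros(G.n_markers)
    pval = np.ones(G.n_markers)
    for j in range(G.n_markers):
        if n_obs[j] == 0:
            chi2[j], pval[j] = np.nan, np.nan
            continue
        col = d[:, j]
        col = col[~np.isnan(col)]
        chi2[j], pval[j] = hwe_test(int(np.sum(col == 0)),
                                    int(np.sum(col == 1)),
                                    int(np.sum(col == 2)))
    return MarkerStats(missingness=missingness, maf=maf, hwe_chi2=chi2,
                       hwe_p=pval, n_obs=n_obs, n_total=n_total)


def filter_markers(G: GenotypeMatrix, miss_max: float = 0.20,
                   maf_rule: str = "gt_1_over_2N", hwe_p_min: float = 1e-4):
    """Apply the three QC criteria; all comparisons are strict.

    ``maf_rule`` is either ``"gt_1_over_2N"`` (threshold 1/(2N), N = panel
    size) or a float threshold.  Returns ``(filtered GenotypeMatrix,
    report DataFrame)`` where the report counts removals per criterion
    (a marker may fail several).
    """
    st = compute_marker_stats(G)
    if maf_rule == "gt_1_over_2N":
        maf_min = 1.0 / (2.0 * st.n_total)
    else:
        maf_min = float(maf_rule)

    undefined = st.n_obs == 0
    fail_miss = st.missingness >= miss_max
    with np.errstate(invalid="ignore"):
        fail_maf = ~(st.maf > maf_min)
        fail_hwe = ~(st.hwe_p > hwe_p_min)
    fail_maf |= undefined
    fail_hwe |= undefined
    keep = ~(fail_miss | fail_maf | fail_hwe)

    report = pd.DataFrame({
        "criterion": ["missingness", "maf", "hwe", "no_calls", "kept", "total"],
        "count": [int(fail_miss.sum()), int(fail_maf.sum()), int(fail_hwe.sum()),
                  int(undefined.sum()), int(keep.sum()), G.n_markers],
    })
    if keep.sum() == 0:
        import warnings
        warnings.warn("all markers removed by QC filters")
    return G.subset_markers(np.flatnonzero(keep)), report


def impute_missing(G: GenotypeMatrix, scope: str = "panel") -> GenotypeMatrix:
    """Replace missing dosages by the per-marker mean over the chosen scope.

    ``scope="panel"`` uses the whole-panel mean; ``scope="population"`` uses
    within-label means (falling back to the panel mean when a population has
    no call at a marker).  Imputed values may be fractional; the output has
    no missing cells and the per-marker mean dosage is preserved.
    """
    import warnings
    d = G.filled()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)   # all-NaN columns
        panel_mean = np.nanmean(d, axis=0)
    if np.any(np.isnan(panel_mean)):
        raise ValueError("marker with zero non-missing calls; filter first")

    if scope == "panel":
        filled = np.where(np.isnan(d), panel_mean, d)
    elif scope == "population":
        if G.populations is None:
            raise ValueError("population scope requires population labels")
        filled = d.copy()
        for pop in np.unique(G.populations):
            rows = G.populations == pop
            with np.errstate(invalid="ignore"):
                pop_mean = np.nanmean(d[rows], axis=0)
            pop_mean = np.where(np.isnan(pop_mean), panel_mean, pop_mean)
            block = filled[rows]
            block[np.isnan(block)] = np.broadcast_to(pop_mean, block.shape)[np.isnan(block)]
            filled[rows] = block
    else:
        raise ValueError(f"unknown imputation scope: {scope!r}")

    return GenotypeMatrix(
        dosage=filled,
        missing=np.zeros_like(G.missing),
        individual_ids=G.individual_ids,
        marker_ids=G.marker_ids,
        chrom=G.chrom,
        pos=G.pos,
        populations=G.populations,
    )
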