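"""Synthetic structured-population data generator.

Emulates the statistical structure of a multi-population genomic-selection
study in a perennial grass: several diverged subpopulations with distinct
allele-frequency spectra (Balding-Nichols divergence with FST as the single
structure knob), half-sib family trial phenotypes scored 0-20 across
locations and blocks, geography-linked breeding values that increase from
south to north and from west to east, and per-site allelic read depths that
separate tetraploid from octoploid heterozygote allele-fraction peaks.

Markers are independent given subpopulation frequencies (no LD along
chromosomes); half-sib family genotypes are the maternal-parent dosages, so
no within-family segregation is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_structured_genotypes",
    "simulate_trial_phenotypes",
    "assign_geography",
    "simulate_allelic_depths",
]

# fixed spawn keys so each stage draws from an independent, reproducible stream
_STAGE_GENO, _STAGE_PHENO, _STAGE_GEO, _STAGE_DEPTH = 0, 1, 2, 3


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror a multi-population half-sib trial: three diverged
    lowland-type subpopulations of 100 families each, a polygenic trait
    (100 QTL), family-mean heritability 0.6, two locations with three
    blocks, 5% missing genotype calls, and 20x mean read depth.
    """

    n_subpops: int = 3
    n_per_subpop: int = 100
    n_markers: int = 2000
    fst: float = 0.2
    ancestral_maf_range: tuple = (0.05, 0.5)
    n_qtl: int = 100
    h2_target: float = 0.6
    n_locations: int = 2
    n_blocks: int = 3
    missing_rate: float = 0.05
    geo_gradient: tuple = (0.1, 0.1)   # BV shift per degree (latitude, longitude)
    mean_depth: float = 20.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subpops", "n_per_subpop", "n_markers", "n_qtl",
                     "n_locations", "n_blocks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must be in [0, 1]")
        if not 0.0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")


@dataclass
class SimTruth:
    """Ground truth carried alongside simulated data."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    true_bv: np.ndarray
    subpop_freqs: np.ndarray        # n_subpops x n_markers
    ploidy: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.ploidy is None:
            self.ploidy = np.array(["tetraploid"] * len(self.true_bv))


def simulate_structured_genotypes(config: SimConfig):
    """Draw dosages for diverged subpopulations under the Balding-Nichols model.

    Ancestral frequency p ~ Uniform(ancestral_maf_range); each subpopulation
    frequency ~ Beta(p(1-F)/F, (1-p)(1-F)/F); dosage ~ Binomial(2, subpop
    frequency), so HWE holds within each subpopulation by construction.
    F -> 0 recovers panmixia (all subpop frequencies equal the ancestral one).

    Returns
    -------
    (GenotypeMatrix, SimTruth)
    """
    cfg = config
    rng = _stage_rng(cfg.seed, _STAGE_GENO)
    k, npop, m = cfg.n_subpops, cfg.n_per_subpop, cfg.n_markers
    lo, hi = cfg.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    if cfg.fst > 0:
        a = p_anc * (1 - cfg.fst) / cfg.fst
        b = (1 - p_anc) * (1 - cfg.fst) / cfg.fst
        freqs = rng.beta(a, b, size=(k, m))
        freqs = np.clip(freqs, 1e-6, 1 - 1e-6)
    else:
        freqs = np.tile(p_anc, (k, 1))

    n = k * npop
    dosage = np.empty((n, m), dtype=float)
    labels = np.empty(n, dtype=object)
    for s in range(k):
        rows = slice(s * npop, (s + 1) * npop)
        dosage[rows] = rng.binomial(2, freqs[s], size=(npop, m))
        labels[s * npop:(s + 1) * npop] = f"pop{s + 1}"

    missing = rng.random((n, m)) < cfg.missing_rate

    G = GenotypeMatrix(
        dosage=dosage,
        missing=missing,
        individual_ids=np.array([f"{labels[i]}_ind{i}" for i in range(n)]),
        marker_ids=np.array([f"snp{j}" for j in range(m)]),
        chrom=np.repeat("1", m),
        pos=np.arange(1, m + 1) * 1000,
        populations=labels,
    )

    n_qtl = min(cfg.n_qtl, m)
    qtl_idx = rng.choice(m, size=n_qtl, replace=False)
    effects = rng.normal(size=n_qtl)
    W = np.where(missing[:, qtl_idx], 2 * freqs.mean(0)[qtl_idx], dosage[:, qtl_idx])
    bv = W @ effects
    bv = bv - bv.mean()
    sd = bv.std()
    if sd > 0:
        bv = bv / sd          # unit-variance BV scale; phenotype noise is set relative to it
        effects = effects / sd
    truth = SimTruth(qtl_indices=qtl_idx, qtl_effects=effects,
                     true_bv=bv, subpop_freqs=freqs)
    return G, truth


def simulate_trial_phenotypes(G: GenotypeMatrix, truth: SimTruth, config: SimConfig,
                              loc_sd: float = 1.0, block_sd: float = 0.5,
                              score_intercept: float = 10.0, score_slope: float = 2.0):
    """Generate plot-level 0-20 survival scores from true breeding values.

    Each family (one row of ``G``, the maternal parent) is scored once per
    location x block.  The latent plot value is
    BV + location + block(location) + family-x-location + residual; the
    family-x-location and residual variances are set so the family-mean
    narrow-sense heritability equals ``h2_target``.  The latent value is
    mapped to the score scale by ``score_intercept + score_slope * latent``
    and clipped to [0, 20].

    Returns a long-format DataFrame with columns
    ``location, block, family, score``.
    """
    cfg = config
    t = cfg.h2_target
    if t >= 1.0 and (loc_sd > 0 or block_sd > 0):
        raise ValueError("h2_target = 1 requires zero non-genetic variances "
                         "(pass loc_sd=0, block_sd=0)")
    rng = _stage_rng(cfg.seed, _STAGE_PHENO)
    bv = np.asarray(truth.true_bv, dtype=float)
    nfam = len(bv)
    l, r = cfg.n_locations, cfg.n_blocks
    var_bv = bv.var()
    if t > 0 and var_bv > 0:
        denom_extra = var_bv * (1 - t) / t
    elif t == 0:
        denom_extra = max(var_bv, 1.0) * 50.0   # drown the signal
    else:
        denom_extra = 1.0
    # split the family-mean non-genetic variance evenly between the
    # family-x-location term and plot residual
    var_fl = denom_extra * l / 2.0
    var_eps = denom_extra * l * r / 2.0
    if t >= 1.0:
        var_fl = var_eps = 0.0

    loc_eff = rng.normal(0, loc_sd, size=l)
    blk_eff = rng.normal(0, block_sd, size=(l, r))
    fl_eff = rng.normal(0, np.sqrt(var_fl), size=(l, nfam)) if var_fl > 0 else np.zeros((l, nfam))

    rows = []
    for i in range(l):
        for k in range(r):
            eps = rng.normal(0, np.sqrt(var_eps), size=nfam) if var_eps > 0 else np.zeros(nfam)
            latent = bv + loc_eff[i] + blk_eff[i, k] + fl_eff[i] + eps
            score = np.clip(score_intercept + score_slope * latent, 0.0, 20.0)
            for j in range(nfam):
                rows.append((f"loc{i + 1}", f"block{k + 1}", G.individual_ids[j], score[j]))
    return pd.DataFrame(rows, columns=["location", "block", "family", "score"])


def assign_geography(pop_labels, config: SimConfig, truth: SimTruth = None):
    """Place populations on a south/north x west/east grid and link BVs to it.

    Each population receives a latitude (degrees N), a signed longitude
    (degrees, negative = west of Greenwich) and a 30-yr minimum temperature
    of the coldest month generated to correlate strongly (|r| ~ 0.9,
    negative) with latitude.  When ``truth`` is given, each individual's
    breeding value is shifted by ``geo_gradient . (lat, lon)`` of its
    population (centred), so BVs increase from south to north and, with the
    signed-longitude convention, from west to east.

    Returns a DataFrame with columns
    ``population, latitude, longitude, min_temp, group, ploidy``.
    """
    cfg = config
    rng = _stage_rng(cfg.seed, _STAGE_GEO)
    pop_labels = np.asarray(pop_labels)
    pops = list(dict.fromkeys(pop_labels))   # stable order of appearance
    npop = len(pops)
    lat = rng.uniform(27.0, 45.0, size=npop)
    lon = rng.uniform(-100.0, -76.0, size=npop)
    min_temp = 20.0 - 0.9 * lat + rng.normal(0, 2.0, size=npop)

    g_lat, g_lon = cfg.geo_gradient
    shift = g_lat * lat + g_lon * lon
    shift = shift - shift.mean()
    if truth is not None:
        for p, s in zip(pops, shift):
            truth.true_bv[pop_labels == p] += s

    ploidy = ["tetraploid"] * npop
    if truth is not None and len(truth.ploidy) == len(pop_labels):
        for i, p in enumerate(pops):
            members = truth.ploidy[pop_labels == p]
            if len(members) and (members == "octoploid").mean() > 0.5:
                ploidy[i] = "octoploid"

    return pd.DataFrame({
        "population": pops,
        "latitude": lat,
        "longitude": lon,
        "min_temp": min_temp,
        "group": pops,
        "ploidy": ploidy,
    })


_HET_CLASSES = {"tetraploid": ([0.5], [1.0]),
                "octoploid": ([0.25, 0.5, 0.75], [1 / 3, 1 / 3, 1 / 3])}


def simulate_allelic_depths(G: GenotypeMatrix, ploidy_labels, mean_depth: float,
                            seed: int = 0, class_weights: dict = None):
    """Draw reference/total read depths at heterozygous calls.

    Per heterozygous site, total depth ~ Poisson(mean_depth) and reference
    reads ~ Binomial(total, f) where f is the dosage-class reference
    fraction: 0.5 for tetraploids; drawn from {0.25, 0.5, 0.75} (equal
    weights by default) for octoploids.

    Returns a DataFrame with columns
    ``individual, marker, ref_depth, total_depth, is_het``.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    ploidy_labels = np.asarray(ploidy_labels)
    unknown = set(ploidy_labels) - set(_HET_CLASSES)
    if unknown:
        raise ValueError(f"unknown ploidy labels: {sorted(unknown)}")
    rng = _stage_rng(seed, _STAGE_DEPTH)
    frames = []
    for i in range(G.n_individuals):
        het = np.flatnonzero((G.dosage[i] == 1) & ~G.missing[i])
        if het.size == 0:
            continue
        classes, weights = _HET_CLASSES[ploidy_labels[i]]
        if class_weights is not None and ploidy_labels[i] in class_weights:
            classes, weights = class_weights[ploidy_labels[i]]
        total = rng.poisson(mean_depth, size=het.size)
        frac = rng.choice(classes, p=np.asarray(weights) / np.sum(weights), size=het.size)
        ref = rng.binomial(total, frac)
        frames.append(pd.DataFrame({
            "individual": G.individual_ids[i],
            "marker": G.marker_ids[het],
            "ref_depth": ref,
            "total_depth": total,
            "is_het": True,
        }))
    if not frames:
        return pd.DataFrame(columns=["individual", "marker", "ref_depth",
                                     "total_depth", "is_het"])
    return pd.concat(frames, ignore_index=True)
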