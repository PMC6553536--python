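"""Ploidy inference from reference-allele read-depth fractions.

At a truly diploid-behaving (tetraploid, disomic) heterozygous call the
reference-allele fraction of sequencing reads concentrates near 0.5; in an
octoploid, heterozygous dosage classes also produce peaks near 0.25 and
0.75.  Individuals are classified by comparing the histogram mass of their
heterozygous-site reference fractions in windows around 0.25/0.75 against
the window around 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PloidyCall", "ref_allele_fractions", "classify_ploidy",
           "classify_panel"]


@dataclass
class PloidyCall:
    """Classification of one individual."""

    individual: str
    label: str                  # tetraploid | octoploid | ambiguous
    n_sites: int
    mass_half: float            # fraction of sites in the 0.5 window
    mass_quarters: float        # fraction in the 0.25 and 0.75 windows
    modes: tuple = ()


def ref_allele_fractions(table: pd.DataFrame, min_depth: int = 10) -> dict:
    """Per-individual reference-allele fractions at qualifying het sites.

    ``table`` needs columns ``individual, ref_depth, total_depth, is_het``.
    Only heterozygous calls with total depth >= min_depth contribute.
    Returns a dict individual -> fraction ndarray (possibly empty).
    """
    req = {"individual", "ref_depth", "total_depth", "is_het"}
    if not req.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(req)}")
    sub = table[(table["is_het"]) & (table["total_depth"] >= min_depth)
                & (table["total_depth"] > 0)]
    out = {}
    for ind, grp in sub.groupby("individual", sort=False):
        out[ind] = (grp["ref_depth"] / grp["total_depth"]).to_numpy(dtype=float)
    for ind in table["individual"].unique():
        out.setdefault(ind, np.array([]))
    return out


def classify_ploidy(fractions, individual: str = "", min_sites: int = 200,
                    window: float = 0.08, ratio: float = 1.0) -> PloidyCall:
    """Label one individual from its het-site reference-fraction spectrum.

    The combined mass within ``0.25 +/- window`` and ``0.75 +/- window`` is
    compared with the mass within ``0.5 +/- window``: octoploid when the
    quarter mass exceeds ``ratio`` times the half mass, tetraploid for the
    reverse, ambiguous for ties or too few sites.
    """
    f = np.asarray(fractions, dtype=float)
    if f.size < min_sites:
        return PloidyCall(individual=individual, label="ambiguous",
                          n_sites=int(f.size), mass_half=np.nan,
                          mass_quarters=np.nan)
    mass_half = float(np.mean(np.abs(f - 0.5) <= window))
    mass_quart = float(np.mean((np.abs(f - 0.25) <= window)
                               | (np.abs(f - 0.75) <= window)))
    hist, edges = np.histogram(f, bins=25, range=(0.0, 1.0))
    top = np.argsort(hist)[::-1][:3]
    modes = tuple(np.round((edges[i] + edges[i + 1]) / 2, 3) for i in sorted(top))
    if mass_quart > ratio * mass_half:
        label = "octoploid"
    elif mass_half > ratio * mass_quart:
        label = "tetraploid"
    else:
        label = "ambiguous"
    return PloidyCall(individual=individual, label=label, n_sites=int(f.size),
                      mass_half=mass_half, mass_quarters=mass_quart, modes=modes)


def classify_panel(table: pd.DataFrame, min_depth: int = 10,
                   min_sites: int = 200, window: float = 0.08,
                   ratio: float = 1.0) -> pd.DataFrame:
    """Classify every individual in an allelic-depth table.

    Returns a DataFrame with columns
    ``individual, label, n_sites, mass_half, mass_quarters``.
    """
    fracs = ref_allele_fractions(table, min_depth=min_depth)
    rows = []
    for ind, f in fracs.items():
        call = classify_ploidy(f, individual=ind, min_sites=min_sites,
                               window=window, ratio=ratio)
        rows.append((call.individual, call.label, call.n_sites,
                     call.mass_half, call.mass_quarters))
    return pd.DataFrame(rows, columns=["individual", "label", "n_sites",
                                       "mass_half", "mass_quarters"])
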