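"""Core in-memory containers shared across the pipeline.

Genotypes are biallelic dosages (0 = homozygous reference, 1 = heterozygous,
2 = homozygous alternate) with an explicit missing mask.  Kernels are dense
symmetric individual-by-individual covariance matrices.  Tabular data
(trial records, population metadata, allelic depths) travel as pandas
DataFrames with documented column contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix", "KernelMatrix", "PcScores"]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic markers, dosage coded with a missing mask.

    Parameters
    ----------
    dosage : float ndarray (n_individuals, n_markers)
        Values in {0, 1, 2}; entries under ``missing`` are ignored (their
        stored value is arbitrary).  After imputation, fractional values
        are allowed.
    missing : bool ndarray, same shape
        True marks a missing call.
    individual_ids, marker_ids : sequences of unique identifiers.
    chrom, pos : per-marker chromosome label and 1-based position.
    populations : optional per-individual population label.
    """

    dosage: np.ndarray
    missing: np.ndarray = None
    individual_ids: np.ndarray = None
    marker_ids: np.ndarray = None
    chrom: np.ndarray = None
    pos: np.ndarray = None
    populations: np.ndarray = None

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x markers)")
        n, m = self.dosage.shape
        if self.missing is None:
            self.missing = np.isnan(self.dosage)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.dosage.shape:
            raise ValueError("missing mask shape mismatch")
        if self.individual_ids is None:
            self.individual_ids = np.array([f"ind{i}" for i in range(n)])
        else:
            self.individual_ids = np.asarray(self.individual_ids)
        if self.marker_ids is None:
            self.marker_ids = np.array([f"m{j}" for j in range(m)])
        else:
            self.marker_ids = np.asarray(self.marker_ids)
        if len(set(self.individual_ids)) != n or len(set(self.marker_ids)) != m:
            raise ValueError("individual and marker ids must be unique")
        if self.chrom is None:
            self.chrom = np.array(["1"] * m)
        else:
            self.chrom = np.asarray(self.chrom)
        if self.pos is None:
            self.pos = np.arange(1, m + 1)
        else:
            self.pos = np.asarray(self.pos)
            if np.any(self.pos < 0):
                raise ValueError("positions must be non-negative")
        if self.populations is not None:
            self.populations = np.asarray(self.populations)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def filled(self) -> np.ndarray:
        """Dosage with missing entries as NaN."""
        out = self.dosage.copy()
        out[self.missing] = np.nan
        return out

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosage=self.dosage[:, keep],
            missing=self.missing[:, keep],
            individual_ids=self.individual_ids,
            marker_ids=self.marker_ids[keep],
            chrom=self.chrom[keep],
            pos=self.pos[keep],
            populations=self.populations,
        )

    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosage=self.dosage[keep],
            missing=self.missing[keep],
            individual_ids=self.individual_ids[keep],
            marker_ids=self.marker_ids,
            chrom=self.chrom,
            pos=self.pos,
            populations=None if self.populations is None else self.populations[keep],
        )


@dataclass
class KernelMatrix:
    """Symmetric PSD individual x individual covariance (GRM, IBS or product)."""

    values: np.ndarray
    ids: np.ndarray = None
    kind: str = "GRM"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("kernel must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")
        if self.ids is None:
            self.ids = np.array([f"ind{i}" for i in range(n)])
        else:
            self.ids = np.asarray(self.ids)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def check_psd(self, tol: float = 1e-8) -> None:
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -tol * max(1.0, abs(w).max()):
            raise ValueError(f"kernel not PSD: min eigenvalue {w.min():.3g}")


@dataclass
class PcScores:
    """Principal-component scores of a centred dosage matrix."""

    scores: np.ndarray           # n x d
    eigenvalues: np.ndarray      # length d
    var_explained: np.ndarray    # fractions of total variance, length d
    ids: np.ndarray = field(default=None)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.var_explained = np.asarray(self.var_explained, dtype=float)
        if self.ids is None:
            self.ids = np.array([f"ind{i}" for i in range(self.scores.shape[0])])

    @property
    def d(self) -> int:
        return self.scores.shape[1]
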