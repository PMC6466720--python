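"""Genomic relationship matrices at the individual and tank level.

The individual matrix G follows VanRaden's first method,

    Z = M - 2P,   G = Z Z' / (2 * sum_j p_j (1 - p_j)),

with M the individuals x SNPs dosage matrix (0/1/2) and P the allele
frequencies.  The tank-level matrix averages genotype deviations over the
members of each tank,

    T_tj = (1/n_t) * sum_{i in tank t} (M_ij - 2 p_j),   G_T = T T',

and is then rescaled by a single scalar so that the mean of its diagonal
equals exactly 1.0, which puts the tank-level genetic variance on the
scale of one average tank.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "RelationshipMatrix",
    "allele_frequencies",
    "qc_filter",
    "vanraden_g",
    "tank_g",
    "write_relationship",
    "read_relationship",
    "write_genotypes",
    "read_genotypes",
]


@dataclasses.dataclass
class GenotypeMatrix:
    """Dosage matrix (individuals x SNPs, values 0/1/2, NaN = missing)."""

    ids: list[str]
    dosages: np.ndarray
    snp_ids: list[str] = dataclasses.field(default_factory=list)
    #: Base-population allele frequencies when known (e.g. from simulation);
    #: observed frequencies are used otherwise.
    base_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[0] != len(self.ids):
            raise ValueError("dosage matrix shape inconsistent with ids")
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(self.dosages.shape[1])]
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclasses.dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with its scaling metadata."""

    ids: list[str]
    values: np.ndarray
    level: str = "individual"  # "individual" | "tank"
    scale_factor: float = 1.0  # divisor applied to the raw cross-product
    n_per_tank: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape inconsistent with ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def allele_frequencies(M: np.ndarray) -> np.ndarray:
    """Observed allele frequency per locus, over non-missing calls."""
    M = np.asarray(M, dtype=float)
    n_called = np.sum(~np.isnan(M), axis=0)
    if np.any(n_called == 0):
        bad = np.flatnonzero(n_called == 0).tolist()
        raise ValueError(f"loci with no non-missing call: {bad}")
    return np.nansum(M, axis=0) / (2.0 * n_called)


def qc_filter(
    geno: GenotypeMatrix, maf_min: float = 0.0, call_rate_min: float = 0.0
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop loci failing minor-allele-frequency or call-rate thresholds.

    Returns the filtered matrix and a per-locus report with the observed
    MAF, call rate and pass/fail status.
    """
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= call_rate_min <= 1.0):
        raise ValueError("thresholds must lie in [0, 1]")
    M = geno.dosages
    call_rate = np.mean(~np.isnan(M), axis=0)
    p = allele_frequencies(M)
    maf = np.minimum(p, 1.0 - p)
    keep = (maf >= maf_min) & (call_rate >= call_rate_min)
    report = pd.DataFrame(
        {"snp": geno.snp_ids, "maf": maf, "call_rate": call_rate, "kept": keep}
    )
    if not keep.any():
        raise ValueError("QC removed every locus")
    filtered = GenotypeMatrix(
        ids=list(geno.ids),
        dosages=M[:, keep],
        snp_ids=[s for s, k in zip(geno.snp_ids, keep) if k],
        base_freqs=None if geno.base_freqs is None else geno.base_freqs[keep],
    )
    return filtered, report


def _centered_deviations(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """M - 2P with missing dosages mean-imputed to 2p (zero deviation)."""
    Z = M - 2.0 * p[np.newaxis, :]
    return np.where(np.isnan(Z), 0.0, Z)


def vanraden_g(
    geno: GenotypeMatrix, p: np.ndarray | None = None
) -> RelationshipMatrix:
    """Individual genomic relationship matrix, VanRaden method 1."""
    if geno.n_individuals < 2:
        raise ValueError("at least two individuals required")
    if p is None:
        p = allele_frequencies(geno.dosages)
    p = np.asarray(p, dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all loci monomorphic: VanRaden denominator is zero")
    Z = _centered_deviations(geno.dosages, p)
    G = Z @ Z.T / denom
    G = (G + G.T) / 2.0
    return RelationshipMatrix(ids=list(geno.ids), values=G, scale_factor=denom)


def tank_g(
    geno: GenotypeMatrix,
    tank_assignment: Mapping[str, str] | pd.Series,
    p: np.ndarray | None = None,
    tank_order: Sequence[str] | None = None,
) -> RelationshipMatrix:
    """Tank-level genomic relationship matrix G_T = TT', scaled to mean diag 1.

    Row t of T is the mean genotype deviation ``(M - 2P)`` over the tank's
    genotyped members; after forming TT' a single scalar rescales the
    matrix so the average diagonal element is exactly 1.0 (the scalar is
    recorded in ``scale_factor``).
    """
    if isinstance(tank_assignment, pd.Series):
        tank_assignment = tank_assignment.to_dict()
    if p is None:
        p = allele_frequencies(geno.dosages)
    p = np.asarray(p, dtype=float)

    tanks = list(tank_order) if tank_order is not None else sorted(
        set(tank_assignment.values()), key=str
    )
    id_index = {i: k for k, i in enumerate(geno.ids)}
    Z = _centered_deviations(geno.dosages, p)
    T = np.zeros((len(tanks), geno.n_snps))
    n_per_tank: dict[str, int] = {}
    for t_idx, tank in enumerate(tanks):
        members = [i for i, t in tank_assignment.items() if t == tank]
        rows = [id_index[i] for i in members if i in id_index]
        if not rows:
            raise ValueError(f"tank {tank!r} has no genotyped member")
        T[t_idx] = Z[rows].mean(axis=0)
        n_per_tank[str(tank)] = len(rows)

    GT_raw = T @ T.T
    mean_diag = float(np.mean(np.diag(GT_raw)))
    if mean_diag <= 0:
        raise ValueError("raw tank relationship matrix has non-positive mean diagonal")
    GT = GT_raw / mean_diag
    GT = (GT + GT.T) / 2.0
    return RelationshipMatrix(
        ids=[str(t) for t in tanks],
        values=GT,
        level="tank",
        scale_factor=mean_diag,
        n_per_tank=n_per_tank,
    )


# --- plain-text IO -----------------------------------------------------------

def write_relationship(rel: RelationshipMatrix, path) -> None:
    df = pd.DataFrame(rel.values, index=rel.ids, columns=rel.ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_relationship(path, level: str = "individual") -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return RelationshipMatrix(
        ids=[str(i) for i in df.index], values=df.to_numpy(float), level=level
    )


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, index=geno.ids, columns=geno.snp_ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_genotypes(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="id")
    return GenotypeMatrix(
        ids=[str(i) for i in df.index],
        dosages=df.to_numpy(float),
        snp_ids=[str(c) for c in df.columns],
    )
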