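"""Recombination-informative summary statistics of a haplotype window.

The estimator regresses rho on four statistics computed after excluding
folded singletons: the variance of pairwise sequence differences (Hudson's
Sk2), mean r2 over all SNP pairs, haplotype heterozygosity, and the number
of distinct haplotypes H.  The compact folded spectrum (xi1', xi2', xix')
is the conditioning context for training-set simulation.

All statistics tolerate missing cells ('?') and multi-allelic sites:
pairwise differences count any allele difference at jointly non-missing
sites, r2 reduces a site to most-frequent-allele-vs-rest on complete
cases, and haplotype identity treats '?' as an ordinary fifth symbol.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype import MISSING, HaplotypeMatrix

__all__ = [
    "FoldedSpectrum",
    "SummaryStats",
    "EmptyWindowError",
    "fold_spectrum",
    "strip_folded_singletons",
    "sk2",
    "mean_r2",
    "hap_heterozygosity",
    "count_haplotypes",
    "summarize",
]


class EmptyWindowError(ValueError):
    """The window has no usable (non-singleton segregating) sites."""


@dataclass(frozen=True)
class FoldedSpectrum:
    """Compact folded mutation frequency spectrum of a window.

    xi1p = xi_1 + xi_{n-1} (folded singletons), xi2p = xi_2 + xi_{n-2},
    xixp pools the classes 3..n-3.  Requires n >= 6.
    """

    xi1p: int
    xi2p: int
    xixp: int
    n: int

    @property
    def S(self) -> int:
        return self.xi1p + self.xi2p + self.xixp


@dataclass(frozen=True)
class SummaryStats:
    sk2: float
    mean_r2: float
    hap_het: float
    H: int

    def as_vector(self) -> np.ndarray:
        return np.array([self.sk2, self.mean_r2, self.hap_het, float(self.H)])


def fold_spectrum(m: HaplotypeMatrix) -> FoldedSpectrum:
    """Classify every column by its folded minor-class count.

    Columns with any missing cells fold on the non-missing sample size.
    """
    if m.n < 6:
        raise ValueError("the compact folded spectrum requires n >= 6")
    c = m.folded_counts()
    return FoldedSpectrum(
        xi1p=int(np.sum(c == 1)),
        xi2p=int(np.sum(c == 2)),
        xixp=int(np.sum(c >= 3)),
        n=m.n,
    )


def strip_folded_singletons(m: HaplotypeMatrix) -> HaplotypeMatrix:
    """Remove columns whose folded minor-class count is 1."""
    c = m.folded_counts()
    return m.select_columns(np.flatnonzero(c != 1))


def _is_plain_binary(m: HaplotypeMatrix) -> bool:
    return not np.any(m.alleles >= 2)  # only '0'/'1' codes, no missing


def _pairwise_differences(m: HaplotypeMatrix) -> np.ndarray:
    """d_ij over jointly non-missing sites, as a condensed upper triangle."""
    if _is_plain_binary(m):
        X = m.alleles.astype(np.float64)
        diff = X @ (1 - X).T
        diff = diff + diff.T
    else:
        valid = (~m.missing_mask).astype(np.float64)
        both = valid @ valid.T
        same = np.zeros_like(both)
        for a in np.unique(m.alleles):
            if a == MISSING:
                continue
            ind = ((m.alleles == a)).astype(np.float64)
            same += ind @ ind.T
        diff = both - same
    iu = np.triu_indices(m.n, k=1)
    return diff[iu]


def sk2(m: HaplotypeMatrix) -> float:
    """Variance of pairwise sequence differences over all haplotype pairs
    (divisor = number of pairs)."""
    if m.n < 2:
        raise ValueError("sk2 requires n >= 2")
    d = _pairwise_differences(m)
    return float(np.mean((d - d.mean()) ** 2))


def _binary_reduce(m: HaplotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per column: 1 for the non-most-frequent alleles, 0 otherwise,
    plus the validity mask."""
    valid = ~m.missing_mask
    X = np.zeros(m.alleles.shape, dtype=np.float64)
    for j in range(m.S):
        col = m.alleles[:, j]
        obs = col[valid[:, j]]
        vals, counts = np.unique(obs, return_counts=True)
        major = vals[np.argmax(counts)]
        X[:, j] = (col != major) & valid[:, j]
    return X, valid.astype(np.float64)


def mean_r2(m: HaplotypeMatrix) -> float:
    """Unweighted mean of r2 (squared allele-frequency correlation) over
    all unordered site pairs with a nonzero denominator, each pair computed
    on its complete cases.  Returns NaN when fewer than 2 usable sites."""
    if m.S < 2:
        return float("nan")
    if _is_plain_binary(m):
        # r2 is invariant to allele relabeling, so no reduction is needed
        X = m.alleles.astype(np.float64)
        p = X.mean(axis=0)
        pAB = X.T @ X / m.n
        num = (pAB - np.outer(p, p)) ** 2
        v = p * (1 - p)
        den = np.outer(v, v)
        iu = np.triu_indices(m.S, k=1)
        usable = den[iu] > 1e-300
        if not np.any(usable):
            return float("nan")
        return float(np.mean(num[iu][usable] / den[iu][usable]))
    X, M = _binary_reduce(m)
    XM = X * M
    nv = M.T @ M
    n11 = XM.T @ XM
    n1_ = XM.T @ M
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = n1_ / nv
        pB = pA.T
        pAB = n11 / nv
        num = (pAB - pA * pB) ** 2
        den = pA * (1 - pA) * pB * (1 - pB)
        r2 = num / den
    iu = np.triu_indices(m.S, k=1)
    r2u, denu, nvu = r2[iu], den[iu], nv[iu]
    usable = (nvu > 0) & (denu > 1e-300)
    if not np.any(usable):
        return float("nan")
    return float(np.mean(r2u[usable]))


def _haplotype_counts(m: HaplotypeMatrix) -> np.ndarray:
    if m.S == 0:
        return np.array([m.n])
    _, counts = np.unique(m.alleles, axis=0, return_counts=True)
    return counts


def hap_heterozygosity(m: HaplotypeMatrix) -> float:
    """1 - sum(p_k^2) over distinct haplotype frequencies ('?' is an
    ordinary fifth symbol)."""
    p = _haplotype_counts(m) / m.n
    return float(1.0 - np.sum(p**2))


def count_haplotypes(m: HaplotypeMatrix) -> int:
    """Number of distinct haplotype strings."""
    return int(len(_haplotype_counts(m)))


def summarize(m: HaplotypeMatrix) -> SummaryStats:
    """Strip folded singletons, then compute the four statistics."""
    stripped = strip_folded_singletons(m)
    if stripped.S == 0:
        raise EmptyWindowError("no non-singleton segregating sites in window")
    return SummaryStats(
        sk2=sk2(stripped),
        mean_r2=mean_r2(stripped),
        hap_het=hap_heterozygosity(stripped),
        H=count_haplotypes(stripped),
    )
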