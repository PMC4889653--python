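"""The haplotype matrix: n phased sequences by S segregating sites.

This is the universal exchange object between the simulator, the summary
statistics and the genome scanner.  Alleles are stored as small integer
codes; ``"?"`` marks missing cells.  Positions are strictly increasing and
either relative (floats in [0, 1)) or physical base-pair coordinates.

Hudson ms-style text blocks ("//", "segsites:", "positions:", 0/1 rows,
with a "?" extension for missing cells) are supported for interop.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "HaplotypeMatrix",
    "read_ms",
    "write_ms",
]

#: allele code for a missing ("?") cell
MISSING: int = 255

_ALPHABET = "01ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_CODE["?"] = MISSING
_CHAR = {i: c for c, i in _CODE.items()}


def encode_alleles(rows: Sequence[str]) -> np.ndarray:
    """Encode an iterable of equal-length allele strings to a code matrix."""
    arr = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=np.uint8)
    for i, r in enumerate(rows):
        arr[i] = [_CODE[c] for c in r]
    return arr


@dataclass
class HaplotypeMatrix:
    """A sample of ``n`` phased haplotypes typed at ``S`` segregating sites.

    Parameters
    ----------
    alleles
        ``(n, S)`` uint8 matrix of allele codes ('0','1' for the
        infinite-site model, 'A','C','G','T' for finite sites, '?' missing).
    positions
        Strictly increasing site positions, relative in ``[0, 1)`` or
        integer base pairs.
    window
        Optional ``(chrom, start, end)`` genomic interval, 0-based
        half-open.
    """

    alleles: np.ndarray
    positions: np.ndarray
    window: tuple[str, int, int] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        if self.positions.shape != (self.alleles.shape[1],):
            raise ValueError("positions length must equal the site count")
        if self.S > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    # -- dimensions ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def S(self) -> int:
        return self.alleles.shape[1]

    # -- masks and per-column summaries --------------------------------
    @property
    def missing_mask(self) -> np.ndarray:
        return self.alleles == MISSING

    def folded_counts(self) -> np.ndarray:
        """Folded minor-class count per column.

        For a biallelic column this is ``min(k, m - k)`` with ``m`` the
        non-missing sample size; for a multi-allelic column it is ``m``
        minus the count of the most frequent allele, the same convention.
        """
        if not np.any(self.alleles >= 2):  # plain 0/1, no missing
            ones = self.alleles.sum(axis=0, dtype=np.int64)
            return np.minimum(ones, self.n - ones)
        counts = np.zeros(self.S, dtype=np.int64)
        for j in range(self.S):
            col = self.alleles[:, j]
            col = col[col != MISSING]
            if col.size == 0:
                counts[j] = 0
                continue
            _, c = np.unique(col, return_counts=True)
            counts[j] = col.size - c.max()
        return counts

    def segregating_mask(self) -> np.ndarray:
        """True for columns with >= 2 distinct non-missing alleles."""
        if not np.any(self.alleles >= 2):
            ones = self.alleles.sum(axis=0, dtype=np.int64)
            return (ones > 0) & (ones < self.n)
        out = np.zeros(self.S, dtype=bool)
        for j in range(self.S):
            col = self.alleles[:, j]
            col = col[col != MISSING]
            out[j] = np.unique(col).size >= 2
        return out

    def select_columns(self, idx: np.ndarray) -> "HaplotypeMatrix":
        return replace(self, alleles=self.alleles[:, idx], positions=self.positions[idx])

    def drop_nonsegregating(self) -> "HaplotypeMatrix":
        return self.select_columns(np.flatnonzero(self.segregating_mask()))

    # -- text views ----------------------------------------------------
    def row_strings(self) -> list[str]:
        return ["".join(_CHAR[c] for c in row) for row in self.alleles]

    @classmethod
    def from_strings(
        cls,
        rows: Sequence[str],
        positions: Iterable[float] | None = None,
        window: tuple[str, int, int] | None = None,
    ) -> "HaplotypeMatrix":
        alleles = encode_alleles(list(rows))
        if positions is None:
            positions = np.arange(alleles.shape[1], dtype=float)
        return cls(alleles, np.asarray(list(positions)), window=window)

    def __eq__(self, other: object) -> bool:  # byte-for-byte comparison
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            self.alleles.shape == other.alleles.shape
            and np.array_equal(self.alleles, other.alleles)
            and np.allclose(
                np.asarray(self.positions, float), np.asarray(other.positions, float), atol=1e-6
            )
            and self.window == other.window
        )


# ---------------------------------------------------------------------
# Hudson ms-style text interop
# ---------------------------------------------------------------------

def write_ms(matrices: Iterable[HaplotypeMatrix], fh: io.TextIOBase | str) -> None:
    """Write matrices as ms-style blocks (0/1 rows; '?' for missing)."""
    own = isinstance(fh, str)
    out = open(fh, "w") if own else fh
    try:
        for m in matrices:
            out.write("//\n")
            out.write(f"segsites: {m.S}\n")
            pos = " ".join(
                f"{p:.6f}" if np.issubdtype(np.asarray(m.positions).dtype, np.floating) else str(int(p))
                for p in m.positions
            )
            out.write(f"positions: {pos}\n")
            for row in m.row_strings():
                out.write(row + "\n")
            out.write("\n")
    finally:
        if own:
            out.close()


def read_ms(fh: io.TextIOBase | str) -> Iterator[HaplotypeMatrix]:
    """Iterate over ms-style blocks in a file or stream."""
    own = isinstance(fh, str)
    inp = open(fh) if own else fh
    try:
        lines = iter(inp.read().splitlines())
        block: list[str] | None = None
        positions: np.ndarray | None = None
        for line in lines:
            line = line.strip()
            if line == "//":
                if block:
                    yield HaplotypeMatrix.from_strings(block, positions)
                block, positions = [], None
            elif line.startswith("segsites:"):
                continue
            elif line.startswith("positions:"):
                positions = np.array([float(x) for x in line.split()[1:]])
            elif line and block is not None:
                block.append(line)
        if block:
            yield HaplotypeMatrix.from_strings(block, positions)
    finally:
        if own:
            inp.close()
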