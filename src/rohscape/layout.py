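"""Genome layout: ordered chromosomes and the fixed bin grid.

All coordinates in this package are 0-based, half-open ``[start, end)``.
The bin grid partitions each chromosome into consecutive windows of
``bin_size`` bp; the last bin of a chromosome may be shorter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 10_000


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names/lengths plus the analysis bin size.

    Parameters
    ----------
    chromosomes
        Tuple of ``(name, length_bp)`` pairs in genome order.
    bin_size
        Width of the analysis windows in bp (default 10 kbp).
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int = DEFAULT_BIN_SIZE

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(c), int(n)) for c, n in self.chromosomes))
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    # -- basic accessors ---------------------------------------------------

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.chromosomes)

    # -- bin grid ----------------------------------------------------------

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.length(chrom) / self.bin_size)

    @property
    def n_bins_total(self) -> int:
        return sum(self.n_bins(c) for c in self.names)

    def bin_starts(self, chrom: str) -> np.ndarray:
        return np.arange(self.n_bins(chrom), dtype=np.int64) * self.bin_size

    def bin_ends(self, chrom: str) -> np.ndarray:
        ends = self.bin_starts(chrom) + self.bin_size
        return np.minimum(ends, self.length(chrom))

    def bin_widths(self, chrom: str) -> np.ndarray:
        return self.bin_ends(chrom) - self.bin_starts(chrom)

    def bin_index(self, pos: int | np.ndarray) -> int | np.ndarray:
        return pos // self.bin_size

    # -- io ----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.chromosomes, columns=["chrom", "length"]).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, bin_size: int = DEFAULT_BIN_SIZE) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t")
        return cls(tuple(zip(df["chrom"].astype(str), df["length"].astype(int))), bin_size=bin_size)
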