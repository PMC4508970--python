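"""In-memory containers for a diploid genotype cohort and ROH interval sets.

Genotypes are coded 0 (hom ref), 1 (het), 2 (hom alt), -1 (missing).
ROH sets are plain pandas DataFrames with the columns in :data:`ROH_COLUMNS`
(0-based half-open intervals), optionally carrying a ``size_class`` column
with labels from :data:`ROH_SIZE_CLASSES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .layout import GenomeLayout

#: Functional classes an alternate allele may carry (one per site).
FUNC_CLASSES = ("synonymous", "non_deleterious", "deleterious", "nonsense", "lof")

#: ROH size-class labels: short, medium, long.
ROH_SIZE_CLASSES = ("S", "M", "L")

#: Required columns of an ROH DataFrame.
ROH_COLUMNS = ("sample", "chrom", "start", "end", "length")

MISSING = -1


def empty_roh() -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "sample": pd.Series(dtype=object),
            "chrom": pd.Series(dtype=object),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "length": pd.Series(dtype=np.int64),
        }
    )
    return df


def validate_roh(roh: pd.DataFrame, layout: GenomeLayout | None = None) -> pd.DataFrame:
    """Check ROH invariants: within-sample disjointness, positive lengths.

    Returns the frame sorted by (sample, chrom, start).
    """
    missing_cols = set(ROH_COLUMNS) - set(roh.columns)
    if missing_cols:
        raise ValueError(f"ROH frame missing columns: {sorted(missing_cols)}")
    if len(roh) == 0:
        return roh
    if (roh["end"] <= roh["start"]).any():
        raise ValueError("ROH with non-positive length")
    if not (roh["length"] == roh["end"] - roh["start"]).all():
        raise ValueError("length column inconsistent with start/end")
    roh = roh.sort_values(["sample", "chrom", "start"], kind="mergesort").reset_index(drop=True)
    for (_, _), grp in roh.groupby(["sample", "chrom"], sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("overlapping ROH within one individual")
    if layout is not None:
        lens = layout.lengths
        for chrom, grp in roh.groupby("chrom", sort=False):
            if chrom not in lens:
                raise ValueError(f"ROH on unknown chromosome {chrom!r}")
            if (grp["end"] > lens[chrom]).any():
                raise ValueError(f"ROH beyond end of chromosome {chrom!r}")
    return roh


@dataclass
class GenotypeCohort:
    """Sites x individuals genotype matrix with annotations and depth tracks.

    Attributes
    ----------
    layout
        Genome layout shared by all tracks.
    samples
        Ordered sample names (matrix columns).
    populations
        Mapping sample -> population label.
    sites
        DataFrame with columns ``chrom, pos, ref, alt, func_class``, sorted by
        (chrom in layout order, pos). ``pos`` is 0-based.
    genotypes
        int8 array of shape (n_sites, n_samples); -1 marks missing calls.
    bin_depth
        Per chromosome, float array (n_bins, n_samples) of covered bases (bp)
        per analysis bin — the DP/bin quantity the ROH caller corrects with.
    site_depth
        Optional int array (n_sites, n_samples) of per-site read depth,
        used when writing VCF DP fields.
    """

    layout: GenomeLayout
    samples: list[str]
    populations: dict[str, str]
    sites: pd.DataFrame
    genotypes: np.ndarray
    bin_depth: dict[str, np.ndarray] = field(default_factory=dict)
    site_depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        n_sites, n_samples = self.genotypes.shape
        if n_samples != len(self.samples):
            raise ValueError("genotype matrix width != number of samples")
        if n_sites != len(self.sites):
            raise ValueError("genotype matrix height != number of sites")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")
        unknown = set(self.sites["func_class"]) - set(FUNC_CLASSES)
        if unknown:
            raise ValueError(f"unknown functional classes: {sorted(unknown)}")
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise ValueError(f"samples without population assignment: {missing_pop}")

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def pop_samples(self, pop: str) -> list[str]:
        return [s for s in self.samples if self.populations[s] == pop]

    @property
    def pop_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            p = self.populations[s]
            if p not in seen:
                seen.append(p)
        return seen

    def site_mask(self, chrom: str) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()
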