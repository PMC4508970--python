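"""Partition of genotypes by functional class, alt-allele count and ROH class.

For each individual i the tensor g[i, j, c, k] counts annotated sites of
functional class c at which the individual carries k in {0, 1, 2} alternate
alleles and whose position falls in ROH class j: S, M, L (inside a short /
medium / long ROH), with R = S + M + L (inside any ROH) and N = outside all
ROH. The proportions f[i, j, c] = g[i, j, c, 2] / g_total[i, c, 2] give the
share of the individual's genome-wide alternate homozygotes of class c lying
in class-j ROH; they are undefined (NaN) when the individual has no
alternate homozygote of that class.

Missing genotypes contribute nowhere. Only alternate alleles carry
functional annotations, so reference homozygotes (k = 0) are tallied but
never enter f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import FUNC_CLASSES, GenotypeCohort

#: tensor axis order for ROH classes
ROH_CLASS_ORDER = ("S", "M", "L", "R", "N")
#: f is defined for these classes (N excluded: f_N = 1 - f_R)
F_CLASS_ORDER = ("S", "M", "L", "R")


@dataclass
class PartitionCounts:
    """g tensor: (n_samples, 5 ROH classes, n_func_classes, 3 allele counts)."""

    samples: list[str]
    func_classes: tuple[str, ...]
    g: np.ndarray  # int64

    def __post_init__(self) -> None:
        exp = (len(self.samples), len(ROH_CLASS_ORDER), len(self.func_classes), 3)
        if self.g.shape != exp:
            raise ValueError(f"g tensor shape {self.g.shape} != {exp}")
        if (self.g < 0).any():
            raise ValueError("negative counts in g tensor")

    @property
    def g_total(self) -> np.ndarray:
        """Marginal over location: R + N, shape (n_samples, n_func, 3)."""
        ix_r = ROH_CLASS_ORDER.index("R")
        ix_n = ROH_CLASS_ORDER.index("N")
        return self.g[:, ix_r] + self.g[:, ix_n]

    def get(self, sample: str, roh_class: str, func_class: str, k: int) -> int:
        return int(
            self.g[
                self.samples.index(sample),
                ROH_CLASS_ORDER.index(roh_class),
                self.func_classes.index(func_class),
                k,
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        """Long format: sample, roh_class, func_class, k, count."""
        rows = []
        for i, s in enumerate(self.samples):
            for j, rc in enumerate(ROH_CLASS_ORDER):
                for c, fc in enumerate(self.func_classes):
                    for k in range(3):
                        rows.append((s, rc, fc, k, int(self.g[i, j, c, k])))
        return pd.DataFrame(rows, columns=["sample", "roh_class", "func_class", "k", "count"])


def partition_genotypes(
    cohort: GenotypeCohort,
    labeled_roh: pd.DataFrame,
    func_classes: tuple[str, ...] = FUNC_CLASSES,
) -> PartitionCounts:
    """Tally the g tensor for every individual.

    Each (individual, site) pair with a non-missing genotype contributes to
    exactly one of S, M, L, N — the size class of the containing ROH (ROH of
    one individual are disjoint, so containment is unique under the
    half-open rule) or N outside any ROH — and additively to R.
    """
    if len(labeled_roh) and "size_class" not in labeled_roh.columns:
        raise ValueError("ROH frame must carry a size_class column (run classify_roh)")
    unknown = set(cohort.sites["func_class"]) - set(func_classes)
    if unknown:
        raise ValueError(f"sites with classes outside func_classes: {sorted(unknown)}")
    for chrom in set(cohort.sites["chrom"]):
        if chrom not in cohort.layout.lengths:
            raise ValueError(f"site on chromosome {chrom!r} absent from layout")

    n_s = cohort.n_samples
    g = np.zeros((n_s, len(ROH_CLASS_ORDER), len(func_classes), 3), dtype=np.int64)
    cls_ix = {c: i for i, c in enumerate(func_classes)}
    site_cls = cohort.sites["func_class"].map(cls_ix).to_numpy()
    pos_all = cohort.sites["pos"].to_numpy()
    chrom_all = cohort.sites["chrom"].to_numpy()
    jmap = {"S": 0, "M": 1, "L": 2}
    ix_r = ROH_CLASS_ORDER.index("R")
    ix_n = ROH_CLASS_ORDER.index("N")

    for i, s in enumerate(cohort.samples):
        gt = cohort.genotypes[:, i]
        # locate each site's containing ROH class (or N)
        jcode = np.full(cohort.n_sites, ix_n, dtype=np.int64)
        if len(labeled_roh):
            sub = labeled_roh[labeled_roh["sample"] == s]
            for chrom, grp in sub.groupby("chrom", sort=False):
                m = chrom_all == chrom
                if not m.any():
                    continue
                grp = grp.sort_values("start")
                starts = grp["start"].to_numpy()
                ends = grp["end"].to_numpy()
                labels = np.array([jmap[str(c)] for c in grp["size_class"]])
                pos = pos_all[m]
                k = np.searchsorted(starts, pos, side="right") - 1
                inside = (k >= 0) & (pos < ends[np.clip(k, 0, None)])
                loc = jcode[m]
                loc[inside] = labels[k[inside]]
                jcode[m] = loc
        valid = gt >= 0
        np.add.at(g, (i, jcode[valid], site_cls[valid], gt[valid]), 1)
    g[:, ix_r] = g[:, 0] + g[:, 1] + g[:, 2]
    return PartitionCounts(samples=list(cohort.samples), func_classes=tuple(func_classes), g=g)


def proportions(counts: PartitionCounts) -> pd.DataFrame:
    """f[i, j, c] for j in S, M, L, R as a long DataFrame.

    NaN when the individual carries no alternate homozygote of class c.
    """
    g2 = counts.g[..., 2].astype(float)  # (n, 5, c)
    tot2 = counts.g_total[..., 2].astype(float)  # (n, c)
    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        for j, rc in enumerate(ROH_CLASS_ORDER):
            if rc == "N":
                continue
            f = np.where(tot2 > 0, g2[:, j] / tot2, np.nan)
            for i, s in enumerate(counts.samples):
                for c, fc in enumerate(counts.func_classes):
                    rows.append((s, rc, fc, f[i, c]))
    return pd.DataFrame(rows, columns=["sample", "roh_class", "func_class", "f"])


def f_matrix(prop: pd.DataFrame, roh_class: str, func_class: str, samples: list[str]) -> np.ndarray:
    """Extract f values for one (ROH class, functional class) in sample order."""
    sub = prop[(prop["roh_class"] == roh_class) & (prop["func_class"] == func_class)]
    lookup = dict(zip(sub["sample"], sub["f"]))
    return np.array([lookup.get(s, np.nan) for s in samples], dtype=float)
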