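"""ROH size classes, genome-coverage profiles, cross-individual sharing and
the length-preserving randomization null.

Size classes: short (S) below ``short_max``, medium (M) from ``short_max`` to
``long_min`` inclusive, long (L) above ``long_min``. Defaults 100 kbp / 3 Mbp
with the alternate threshold pairs 50 kbp / 2 Mbp and 150 kbp / 4 Mbp also
supported. G_{i,j} is the fraction of the genome covered by class-j ROH for
individual i; sharing counts, per 10-kbp bin, how many individuals have at
least one ROH overlapping the bin. The null redistributes each individual's
segments uniformly over the genome, preserving segment count and the exact
multiset of lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import validate_roh
from .layout import GenomeLayout

_NULL_RETRIES = 1000


@dataclass(frozen=True)
class SizeClassThresholds:
    """Boundaries of the three ROH size classes (bp).

    S = [min_roh, short_max); M = [short_max, long_min]; L = (long_min, inf).
    """

    short_max: int = 100_000
    long_min: int = 3_000_000

    def __post_init__(self) -> None:
        if not 0 < self.short_max < self.long_min:
            raise ValueError("need 0 < short_max < long_min")

    def classify(self, length) -> np.ndarray:
        length = np.asarray(length)
        return np.where(length < self.short_max, "S", np.where(length <= self.long_min, "M", "L"))


#: alternate threshold pairs explored in sensitivity analyses
ALT_THRESHOLDS = (SizeClassThresholds(50_000, 2_000_000), SizeClassThresholds(150_000, 4_000_000))


def classify_roh(roh: pd.DataFrame, thresholds: SizeClassThresholds | None = None) -> pd.DataFrame:
    """Attach a ``size_class`` column (S/M/L) keyed on segment length."""
    thresholds = thresholds or SizeClassThresholds()
    out = roh.copy()
    out["size_class"] = thresholds.classify(out["length"].to_numpy()) if len(out) else pd.Series(dtype=object)
    return out


def coverage_profile(labeled_roh: pd.DataFrame, layout: GenomeLayout, samples: list[str] | None = None) -> pd.DataFrame:
    """Per-individual genome fractions G_S, G_M, G_L, G_R.

    ``samples`` lists individuals to report even when they carry no ROH.
    Additivity G_S + G_M + G_L = G_R holds exactly.
    """
    if len(labeled_roh):
        validate_roh(labeled_roh, layout)
    total = float(layout.total_length)
    if samples is None:
        samples = sorted(labeled_roh["sample"].unique()) if len(labeled_roh) else []
    rows = []
    for s in samples:
        sub = labeled_roh[labeled_roh["sample"] == s] if len(labeled_roh) else labeled_roh
        g = {c: 0.0 for c in ("S", "M", "L")}
        if len(sub):
            agg = sub.groupby("size_class")["length"].sum()
            for c in agg.index:
                g[str(c)] = float(agg[c]) / total
        rows.append({"sample": s, "G_S": g["S"], "G_M": g["M"], "G_L": g["L"], "G_R": g["S"] + g["M"] + g["L"]})
    return pd.DataFrame(rows, columns=["sample", "G_S", "G_M", "G_L", "G_R"])


def sharing_track(
    roh: pd.DataFrame, layout: GenomeLayout, mode: str = "individuals"
) -> dict[str, np.ndarray]:
    """Count, per 10-kbp bin, individuals whose ROH overlap the bin.

    ``mode='pairs'`` reports the number of overlapping individual pairs,
    i.e. C(count, 2). Overlap is half-open interval intersection.
    """
    if mode not in ("individuals", "pairs"):
        raise ValueError("mode must be 'individuals' or 'pairs'")
    samples = list(roh["sample"].unique()) if len(roh) else []
    if len(samples) < 2:
        warnings.warn("sharing requires >= 2 individuals with ROH; track is all zero")
    counts = {c: np.zeros(layout.n_bins(c), dtype=np.int64) for c in layout.names}
    bs = layout.bin_size
    for s in samples:
        sub = roh[roh["sample"] == s]
        for chrom, grp in sub.groupby("chrom", sort=False):
            nb = layout.n_bins(chrom)
            hit = np.zeros(nb + 1, dtype=np.int64)
            b0 = (grp["start"].to_numpy() // bs).astype(np.int64)
            b1 = ((grp["end"].to_numpy() - 1) // bs).astype(np.int64)  # last bin touched
            np.add.at(hit, b0, 1)
            np.add.at(hit, b1 + 1, -1)
            covered = np.cumsum(hit[:-1]) > 0
            counts[chrom] += covered
    if mode == "pairs":
        counts = {c: v * (v - 1) // 2 for c, v in counts.items()}
    return counts


def randomize_roh(roh: pd.DataFrame, layout: GenomeLayout, rng: np.random.Generator) -> pd.DataFrame:
    """Redistribute every individual's ROH uniformly over the genome.

    Per individual, segment count and the exact multiset of lengths are
    preserved. Chromosome is chosen proportional to its length, position
    uniform, resampling on within-individual overlap; placements are not
    re-aligned to the bin grid. Raises when a segment cannot be packed.
    """
    if not len(roh):
        return roh.copy()
    names = layout.names
    lens = np.array([layout.length(c) for c in names], dtype=float)
    probs = lens / lens.sum()
    recs = []
    has_class = "size_class" in roh.columns
    for s, sub in roh.groupby("sample", sort=False):
        order = np.argsort(-sub["length"].to_numpy(), kind="stable")  # longest first
        placed: list[tuple[str, int, int]] = []
        for ridx in order:
            row = sub.iloc[ridx]
            length = int(row["length"])
            ok = False
            for _ in range(_NULL_RETRIES):
                ci = int(rng.choice(len(names), p=probs))
                clen = int(lens[ci])
                if length > clen:
                    continue
                start = int(rng.integers(0, clen - length + 1))
                end = start + length
                if all(not (names[ci] == c and start < e and st < end) for c, st, e in placed):
                    placed.append((names[ci], start, end))
                    rec = {
                        "sample": s,
                        "chrom": names[ci],
                        "start": start,
                        "end": end,
                        "length": length,
                    }
                    if has_class:
                        rec["size_class"] = row["size_class"]
                    recs.append(rec)
                    ok = True
                    break
            if not ok:
                raise ValueError(f"could not place a {length}-bp segment for individual {s!r}")
    out = pd.DataFrame(recs)
    return validate_roh(out, layout) if not has_class else out.sort_values(
        ["sample", "chrom", "start"], kind="mergesort"
    ).reset_index(drop=True)


def sharing_null(
    roh: pd.DataFrame,
    layout: GenomeLayout,
    n_reps: int,
    rng: np.random.Generator,
    mode: str = "individuals",
) -> pd.DataFrame:
    """Null distribution of the sharing track under random ROH placement.

    Returns one row per replicate with the maximum and mean per-bin sharing
    count of the randomized landscape.
    """
    rows = []
    for rep in range(n_reps):
        shuffled = randomize_roh(roh, layout, rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            track = sharing_track(shuffled, layout, mode=mode)
        flat = np.concatenate([track[c] for c in layout.names])
        rows.append({"replicate": rep, "max_sharing": int(flat.max()), "mean_sharing": float(flat.mean())})
    return pd.DataFrame(rows)
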