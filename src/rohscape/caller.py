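"""ROH detection from binned heterozygous-SNP counts with depth correction.

Per individual, heterozygous sites are counted in consecutive 10-kbp bins and
corrected for incomplete coverage: corrected = raw * bin_size / DP, where DP
is the covered bases (bp) in the bin. Bins whose relative coverage falls
outside 0.5–2.0x of the individual's mean relative coverage are flagged
unusable. A bin belongs to an ROH when its corrected count is at most
``threshold_factor`` (default 0.25) times the individual's genome-wide mean
corrected count per usable bin; maximal runs of qualifying bins at least
``min_length`` bp long (default 10 kbp, the minimum ROH size considered)
become ROH segments. Nucleotide diversity pi (het positions per kbp) is
reported genome-wide and restricted to bins outside ROH (pi-out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import GenotypeCohort, empty_roh, validate_roh
from .layout import GenomeLayout

#: relative-coverage window within which a bin is considered correctable
COVERAGE_WINDOW = (0.5, 2.0)


@dataclass
class BinnedHetTrack:
    """Per-chromosome binned heterozygosity arrays for one individual.

    For each chromosome: ``raw`` (het-site counts), ``depth`` (covered bp),
    ``corrected`` (depth-corrected counts, NaN where unusable) and ``usable``
    (bool) arrays over the bin grid.
    """

    sample: str
    layout: GenomeLayout
    raw: dict[str, np.ndarray]
    depth: dict[str, np.ndarray]
    corrected: dict[str, np.ndarray]
    usable: dict[str, np.ndarray]

    def genome_mean_corrected(self) -> float:
        """Mean corrected het count per usable bin across the genome."""
        tot = 0.0
        n = 0
        for chrom in self.layout.names:
            u = self.usable[chrom]
            tot += float(np.nansum(self.corrected[chrom][u]))
            n += int(u.sum())
        return tot / n if n else float("nan")


def bin_heterozygosity(
    cohort: GenotypeCohort,
    sample: str,
    qual_threshold: float | None = None,
    site_qual: np.ndarray | None = None,
) -> BinnedHetTrack:
    """Count heterozygous sites per bin for one individual and apply the
    coverage correction.

    ``qual_threshold``/``site_qual`` optionally restrict to sites whose
    quality exceeds the threshold (off by default for synthetic input).
    """
    if cohort.n_sites == 0:
        raise ValueError("cohort has no sites")
    j = cohort.sample_index(sample)
    gt = cohort.genotypes[:, j]
    keep = np.ones(cohort.n_sites, dtype=bool)
    if qual_threshold is not None:
        if site_qual is None:
            raise ValueError("qual_threshold given without site_qual")
        keep = site_qual > qual_threshold
    layout = cohort.layout
    raw: dict[str, np.ndarray] = {}
    depth: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        nb = layout.n_bins(chrom)
        m = cohort.site_mask(chrom) & keep & (gt == 1)
        pos = cohort.sites.loc[m, "pos"].to_numpy()
        raw[chrom] = np.bincount(pos // layout.bin_size, minlength=nb).astype(np.int64)
        if chrom in cohort.bin_depth:
            depth[chrom] = cohort.bin_depth[chrom][:, j].astype(float)
        else:
            # no depth information: assume fully covered bins
            depth[chrom] = layout.bin_widths(chrom).astype(float)

    # individual's mean relative coverage over the genome
    tot_dp = sum(float(d.sum()) for d in depth.values())
    tot_bp = float(layout.total_length)
    mean_rel = tot_dp / tot_bp if tot_bp else float("nan")

    corrected: dict[str, np.ndarray] = {}
    usable: dict[str, np.ndarray] = {}
    lo, hi = COVERAGE_WINDOW
    for chrom in layout.names:
        widths = layout.bin_widths(chrom).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = depth[chrom] / widths
            u = (depth[chrom] > 0) & (rel >= lo * mean_rel) & (rel <= hi * mean_rel)
            corr = np.where(u, raw[chrom] * layout.bin_size / depth[chrom], np.nan)
        corrected[chrom] = corr
        usable[chrom] = u
    return BinnedHetTrack(sample=sample, layout=layout, raw=raw, depth=depth, corrected=corrected, usable=usable)


def call_roh(
    track: BinnedHetTrack,
    threshold_factor: float = 0.25,
    min_length: int = 10_000,
    bridge: int = 0,
) -> pd.DataFrame:
    """Call ROH segments from a binned track.

    A usable bin qualifies when corrected count <= threshold_factor * the
    genome-wide mean corrected count per usable bin. Maximal runs of
    consecutive qualifying bins become segments (bin-grid aligned,
    truncated at chromosome ends); runs shorter than ``min_length`` are
    discarded. Unusable bins interrupt runs unless ``bridge`` > 0 allows
    spanning up to that many consecutive unusable (never high-het) bins.
    """
    layout = track.layout
    n_usable = sum(int(track.usable[c].sum()) for c in layout.names)
    if n_usable == 0:
        warnings.warn(f"all bins unusable for {track.sample}; returning empty ROH set")
        return empty_roh()
    mean_corr = track.genome_mean_corrected()
    thr = threshold_factor * mean_corr
    recs = []
    for chrom in layout.names:
        u = track.usable[chrom]
        corr = track.corrected[chrom]
        qual = u & (corr <= thr)
        nb = len(qual)
        ends = layout.bin_ends(chrom)
        i = 0
        while i < nb:
            if not qual[i]:
                i += 1
                continue
            j = i
            last_q = i
            gap = 0
            while j + 1 < nb:
                nxt = j + 1
                if qual[nxt]:
                    j = nxt
                    last_q = nxt
                    gap = 0
                elif not u[nxt] and gap < bridge:
                    j = nxt
                    gap += 1
                else:
                    break
            start = i * layout.bin_size
            end = int(ends[last_q])
            if end - start >= min_length:
                recs.append((track.sample, chrom, start, end, end - start, last_q - i + 1))
            i = last_q + 1
    if not recs:
        return empty_roh()
    df = pd.DataFrame(recs, columns=["sample", "chrom", "start", "end", "length", "n_bins"])
    return validate_roh(df, layout)


def call_roh_cohort(
    cohort: GenotypeCohort,
    threshold_factor: float = 0.25,
    min_length: int = 10_000,
    bridge: int = 0,
) -> pd.DataFrame:
    """Call ROH for every individual in a cohort; returns one stacked frame."""
    frames = []
    for s in cohort.samples:
        track = bin_heterozygosity(cohort, s)
        frames.append(call_roh(track, threshold_factor=threshold_factor, min_length=min_length, bridge=bridge))
    out = pd.concat(frames, ignore_index=True) if frames else empty_roh()
    return out


@dataclass
class DiversityStats:
    """Nucleotide diversity summary for one individual (het positions/kbp)."""

    sample: str
    pi: float
    pi_out: float
    usable_bp: int
    usable_bp_out: int


def nucleotide_diversity(track: BinnedHetTrack, roh: pd.DataFrame) -> DiversityStats:
    """pi over usable bins genome-wide and over usable bins outside all ROH
    of the individual. Reported as heterozygous positions per kbp; NaN when
    no usable bases."""
    layout = track.layout
    roh_s = roh[roh["sample"] == track.sample] if len(roh) else roh
    tot = tot_bp = 0.0
    tot_out = tot_bp_out = 0.0
    for chrom in layout.names:
        u = track.usable[chrom]
        corr = track.corrected[chrom]
        widths = layout.bin_widths(chrom).astype(float)
        starts = layout.bin_starts(chrom)
        ends = layout.bin_ends(chrom)
        in_roh = np.zeros(len(u), dtype=bool)
        if len(roh_s):
            for _, seg in roh_s[roh_s["chrom"] == chrom].iterrows():
                in_roh |= (starts < seg["end"]) & (ends > seg["start"])
        tot += float(np.nansum(corr[u]))
        tot_bp += float(widths[u].sum())
        sel = u & ~in_roh
        tot_out += float(np.nansum(corr[sel]))
        tot_bp_out += float(widths[sel].sum())
    pi = 1000.0 * tot / tot_bp if tot_bp else float("nan")
    pi_out = 1000.0 * tot_out / tot_bp_out if tot_bp_out else float("nan")
    return DiversityStats(
        sample=track.sample, pi=pi, pi_out=pi_out, usable_bp=int(tot_bp), usable_bp_out=int(tot_bp_out)
    )
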