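"""Weir–Cockerham Fst per 10-kbp bin, 500-kbp aggregation, and correlation
of differentiation with ROH sharing.

Per biallelic site the two-level (populations / individuals) genotypic
variance components are, for r populations with sample sizes n_i, alt-allele
frequencies p_i and observed heterozygote proportions h_i:

    n_bar = mean n_i,  n_c = (r*n_bar - sum n_i^2 / (r*n_bar)) / (r - 1)
    p_bar = sum n_i p_i / (r n_bar),  h_bar = sum n_i h_i / (r n_bar)
    s2 = sum n_i (p_i - p_bar)^2 / ((r - 1) n_bar)

    a = n_bar/n_c * (s2 - (p_bar(1-p_bar) - (r-1)/r * s2 - h_bar/4)/(n_bar-1))
    b = n_bar/(n_bar-1) * (p_bar(1-p_bar) - (r-1)/r * s2 - (2 n_bar - 1)/(4 n_bar) * h_bar)
    c = h_bar / 2

and theta = a / (a + b + c). Within a bin, theta is the ratio of sums
sum(a) / sum(a + b + c) over its polymorphic sites (the standard multi-locus
combination; this differs from averaging per-site ratios). Sites
monomorphic across both populations contribute nothing. Fixed differences
give theta = 1 exactly; slightly negative estimates are a known property of
the estimator, not an error.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .cohort import GenotypeCohort
from .layout import GenomeLayout
from .stats import pearson_with_test


def wc_components(counts1: np.ndarray, counts2: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site variance components (a, b, c) for two populations.

    ``counts1``/``counts2``: arrays of shape (n_sites, 3) with genotype
    counts (hom ref, het, hom alt) per population; missing genotypes are
    simply absent from the counts. Sites where either population has no
    genotyped individual, or that are monomorphic across both populations,
    return (0, 0, 0).
    """
    counts1 = np.atleast_2d(np.asarray(counts1, dtype=float))
    counts2 = np.atleast_2d(np.asarray(counts2, dtype=float))
    r = 2.0
    n1 = counts1.sum(axis=1)
    n2 = counts2.sum(axis=1)
    ok = (n1 >= 1) & (n2 >= 1)
    n1s = np.where(ok, n1, 1.0)
    n2s = np.where(ok, n2, 1.0)
    p1 = (counts1[:, 1] + 2 * counts1[:, 2]) / (2 * n1s)
    p2 = (counts2[:, 1] + 2 * counts2[:, 2]) / (2 * n2s)
    h1 = counts1[:, 1] / n1s
    h2 = counts2[:, 1] / n2s

    n_bar = (n1s + n2s) / r
    n_c = (r * n_bar - (n1s**2 + n2s**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1s * p1 + n2s * p2) / (r * n_bar)
    h_bar = (n1s * h1 + n2s * h2) / (r * n_bar)
    s2 = (n1s * (p1 - p_bar) ** 2 + n2s * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)

    poly = ok & (p_bar > 0) & (p_bar < 1) & (n_bar > 1) & (n_c > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4
        a = n_bar / n_c * (s2 - inner / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    a = np.where(poly, a, 0.0)
    b = np.where(poly, b, 0.0)
    c = np.where(poly, c, 0.0)
    return a, b, c


def wc_theta_site(counts1, counts2) -> float:
    """Single-site theta = a / (a + b + c); NaN when monomorphic."""
    a, b, c = wc_components(np.asarray(counts1)[None, :], np.asarray(counts2)[None, :])
    denom = float(a[0] + b[0] + c[0])
    return float(a[0]) / denom if denom != 0 else float("nan")


def _genotype_counts(cohort: GenotypeCohort, samples: list[str]) -> np.ndarray:
    """(n_sites, 3) genotype counts over the given samples, missing excluded."""
    idx = [cohort.sample_index(s) for s in samples]
    gt = cohort.genotypes[:, idx]
    out = np.zeros((cohort.n_sites, 3), dtype=np.int64)
    for k in range(3):
        out[:, k] = (gt == k).sum(axis=1)
    return out


def fst_bins(cohort: GenotypeCohort, layout: GenomeLayout | None = None) -> dict[tuple[str, str], dict[str, np.ndarray]]:
    """Ratio-of-sums theta per 10-kbp bin for every population pair.

    Returns ``{(popA, popB): {chrom: theta array}}`` with NaN where a bin has
    no polymorphic site. Pairs involving a population with fewer than two
    samples are skipped with a warning.
    """
    layout = layout or cohort.layout
    pops = cohort.pop_names
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    counts = {}
    for p in pops:
        members = cohort.pop_samples(p)
        if len(members) < 2:
            warnings.warn(f"population {p!r} has < 2 samples; its pairs are skipped")
            continue
        counts[p] = _genotype_counts(cohort, members)
    chrom_all = cohort.sites["chrom"].to_numpy()
    pos_all = cohort.sites["pos"].to_numpy()
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for pa, pb in combinations([p for p in pops if p in counts], 2):
        a, b, c = wc_components(counts[pa], counts[pb])
        denom = a + b + c
        tracks: dict[str, np.ndarray] = {}
        for chrom in layout.names:
            nb = layout.n_bins(chrom)
            m = chrom_all == chrom
            bins = pos_all[m] // layout.bin_size
            num_sum = np.bincount(bins, weights=a[m], minlength=nb)
            den_sum = np.bincount(bins, weights=denom[m], minlength=nb)
            with np.errstate(divide="ignore", invalid="ignore"):
                theta = np.where(den_sum != 0, num_sum / den_sum, np.nan)
            tracks[chrom] = theta
        out[(pa, pb)] = tracks
    if not out:
        raise ValueError("no population pair with >= 2 samples each")
    return out


def aggregate_track(
    track: dict[str, np.ndarray], layout: GenomeLayout, window: int = 500_000
) -> dict[str, np.ndarray]:
    """Missing-aware mean of fine-bin values over coarse windows (default
    500 kbp, i.e. 50 consecutive 10-kbp bins; chromosome ends may be
    shorter)."""
    if window % layout.bin_size:
        raise ValueError("window must be a multiple of the bin size")
    k = window // layout.bin_size
    out: dict[str, np.ndarray] = {}
    for chrom in layout.names:
        v = np.asarray(track[chrom], dtype=float)
        n_coarse = -(-len(v) // k)
        agg = np.full(n_coarse, np.nan)
        for i in range(n_coarse):
            chunk = v[i * k : (i + 1) * k]
            if np.isfinite(chunk).any():
                agg[i] = np.nanmean(chunk)
        out[chrom] = agg
    return out


def correlate_tracks(track_a: dict[str, np.ndarray], track_b: dict[str, np.ndarray], layout: GenomeLayout) -> tuple[float, float]:
    """Pearson correlation between two tracks on the same coarse grid,
    over bins where both are non-missing."""
    xs, ys = [], []
    for chrom in layout.names:
        va = np.asarray(track_a[chrom], dtype=float)
        vb = np.asarray(track_b[chrom], dtype=float)
        if len(va) != len(vb):
            raise ValueError(f"track grids differ on {chrom!r}")
        xs.append(va)
        ys.append(vb)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 jointly non-missing bins")
    return pearson_with_test(x[keep], y[keep])


def correlate_sharing_selection(
    fst_track: dict[str, np.ndarray],
    sharing: dict[str, np.ndarray],
    layout: GenomeLayout,
    window: int = 500_000,
) -> tuple[float, float]:
    """Aggregate a 10-kbp Fst track and a 10-kbp sharing track to the coarse
    window and correlate them."""
    agg_fst = aggregate_track(fst_track, layout, window=window)
    agg_share = aggregate_track({c: v.astype(float) for c, v in sharing.items()}, layout, window=window)
    return correlate_tracks(agg_fst, agg_share, layout)
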