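"""Synthetic multi-population diploid cohorts with planted autozygous tracts.

The generator emulates a multi-breed resequencing cohort: each individual
carries identity-by-descent (IBD) tracts planted in three length classes
(short / medium / long). Outside tracts, genotypes follow Hardy–Weinberg
proportions for the individual's population allele frequency p; inside a
tract both haplotypes are copies of one draw, so the alternate homozygote
probability is p rather than p**2 and true heterozygotes are absent.
Functional classes differ only through their allele-frequency law
(deleterious and nonsense alleles rarer than tolerated or synonymous ones);
that frequency contrast alone produces the enrichment of rare-allele
homozygotes inside autozygous tracts that the downstream statistics measure.

No recombination, linkage disequilibrium or coalescent structure is modelled
beyond the planted tracts; see docs/methods.md for what this does and does
not exercise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import FUNC_CLASSES, GenotypeCohort
from .layout import GenomeLayout

_TRACT_RETRIES = 200


@dataclass(frozen=True)
class TractPlan:
    """Plan for one size class: Poisson-mean tract count per individual and a
    uniform length range (bp)."""

    mean_count: float
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        if self.mean_count < 0:
            raise ValueError("mean_count must be >= 0")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")


@dataclass(frozen=True)
class DepthModel:
    """Per-bin covered-bases model.

    Covered fraction per bin = min(1, LogNormal(-sigma^2/2, sigma)); with
    probability ``lowcov_rate`` a bin is additionally knocked down to a
    0.05–0.45 fraction, emulating poorly covered regions the caller must
    flag unusable. ``mean_depth`` scales the per-site DP written to VCF.
    """

    mean_depth: float = 10.0
    bin_noise_sigma: float = 0.15
    lowcov_rate: float = 5e-4


@dataclass(frozen=True)
class SweepSpec:
    """A selective-sweep-like region: a fixed interval where a fraction of
    individuals share an identical planted tract and, optionally, population
    allele frequencies are strongly diverged."""

    chrom: str
    start: int
    end: int
    carrier_fraction: float = 0.8
    diverge: bool = True


def _default_densities() -> dict[str, float]:
    # sites per bp; scaled so out-of-tract heterozygosity is ~6-7 het/10 kbp
    return {
        "synonymous": 1.2e-3,
        "non_deleterious": 8.0e-4,
        "deleterious": 2.5e-4,
        "nonsense": 2.0e-5,
        "lof": 2.0e-5,
    }


def _default_freq_beta() -> dict[str, tuple[float, float]]:
    # Beta(a, b) per class; means 0.3 / 0.2 / 0.05 / 0.05 / 0.05
    return {
        "synonymous": (1.5, 3.5),
        "non_deleterious": (1.2, 4.8),
        "deleterious": (0.8, 15.2),
        "nonsense": (0.8, 15.2),
        "lof": (0.8, 15.2),
    }


def _default_tract_plan() -> dict[str, TractPlan]:
    return {
        "S": TractPlan(8.0, 15_000, 90_000),
        "M": TractPlan(6.0, 120_000, 900_000),
        "L": TractPlan(0.7, 3_100_000, 3_600_000),
    }


@dataclass(frozen=True)
class SimParams:
    """Cohort-simulation parameters; defaults emulate a four-breed dairy-bull
    resequencing cohort at desk scale (mean ROH genome fraction ~0.19 with
    wide individual spread)."""

    n_pops: int = 4
    n_per_pop: int = 6
    site_density: dict[str, float] = field(default_factory=_default_densities)
    allele_freq_beta: dict[str, tuple[float, float]] = field(default_factory=_default_freq_beta)
    tract_plan: dict[str, TractPlan] = field(default_factory=_default_tract_plan)
    depth_model: DepthModel = field(default_factory=DepthModel)
    het_error_rate: float = 1e-3
    missing_rate: float = 2e-3
    sweep: SweepSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pops < 1 or self.n_per_pop < 1:
            raise ValueError("need at least one population and one individual")
        if not 0 <= self.het_error_rate < 1:
            raise ValueError("het_error_rate must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if any(d < 0 for d in self.site_density.values()):
            raise ValueError("site densities must be >= 0")
        unknown = set(self.site_density) - set(FUNC_CLASSES)
        if unknown:
            raise ValueError(f"unknown functional classes in site_density: {sorted(unknown)}")


def demo_layout(n_chrom: int = 2, chrom_length: int = 15_000_000, bin_size: int = 10_000) -> GenomeLayout:
    """Small multi-chromosome layout used by examples and defaults."""
    return GenomeLayout(tuple((f"chr{i + 1}", chrom_length) for i in range(n_chrom)), bin_size=bin_size)


def genotype_site(p, in_tract, rng: np.random.Generator):
    """Draw diploid genotype code(s) for allele frequency ``p``.

    Outside a tract the genotype is Hardy–Weinberg, i.e. Binomial(2, p).
    Inside an IBD tract both haplotypes are one draw: 2 with probability p,
    else 0 — never heterozygous. Accepts scalars or broadcastable arrays.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("allele frequency p must be in [0, 1]")
    in_arr = np.asarray(in_tract, dtype=bool)
    p_b, in_b = np.broadcast_arrays(p_arr, in_arr)
    hwe = rng.binomial(2, p_b)
    ibd = 2 * (rng.random(p_b.shape) < p_b).astype(np.int64)
    out = np.where(in_b, ibd, hwe)
    if np.isscalar(p) and np.isscalar(in_tract):
        return int(out)
    return out


@dataclass
class SimResult:
    """Bundle returned by :func:`simulate_cohort`."""

    cohort: GenotypeCohort
    truth_tracts: pd.DataFrame  # sample, chrom, start, end, length, size_class
    params: SimParams


def _place_tracts(
    layout: GenomeLayout,
    plan: dict[str, TractPlan],
    rng: np.random.Generator,
    sample: str,
    preplaced: list[tuple[str, int, int, str]],
) -> list[tuple[str, int, int, str]]:
    """Place tracts uniformly per chromosome (chromosome picked proportional
    to its length), resampling on within-individual overlap."""
    placed = list(preplaced)
    names = layout.names
    lens = np.array([layout.length(c) for c in names], dtype=float)
    probs = lens / lens.sum()
    # longer classes first eases packing
    for cls in ("L", "M", "S"):
        if cls not in plan:
            continue
        tp = plan[cls]
        count = rng.poisson(tp.mean_count)
        for _ in range(count):
            length = int(rng.integers(tp.min_len, tp.max_len + 1))
            if length > lens.max():
                raise ValueError(
                    f"tract plan infeasible for {sample}: tract of {length} bp "
                    "exceeds every chromosome"
                )
            ok = False
            for _ in range(_TRACT_RETRIES):
                ci = int(rng.choice(len(names), p=probs))
                chrom = names[ci]
                clen = int(lens[ci])
                if length > clen:
                    continue
                start = int(rng.integers(0, clen - length + 1))
                end = start + length
                if all(not (chrom == c and start < e and s < end) for c, s, e, _ in placed):
                    placed.append((chrom, start, end, cls))
                    ok = True
                    break
            if not ok:
                raise ValueError(f"tract plan infeasible for {sample}: could not place a {cls} tract")
    return placed


def simulate_cohort(layout: GenomeLayout, params: SimParams) -> SimResult:
    """Generate a cohort: sites, per-population allele frequencies, planted
    tracts, genotypes, depth tracks and truth intervals. Deterministic given
    ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    samples = [f"P{p + 1}_I{i + 1}" for p in range(params.n_pops) for i in range(params.n_per_pop)]
    pops = {s: s.split("_")[0] for s in samples}
    pop_names = [f"P{p + 1}" for p in range(params.n_pops)]
    pop_of = np.array([pop_names.index(pops[s]) for s in samples])

    # ---- sites and per-population allele frequencies ----------------------
    recs = []
    for chrom in layout.names:
        clen = layout.length(chrom)
        taken: set[int] = set()
        for cls in FUNC_CLASSES:
            dens = params.site_density.get(cls, 0.0)
            n = int(round(dens * clen))
            if n == 0:
                continue
            pos = rng.choice(clen, size=min(n, clen), replace=False)
            for x in pos:
                x = int(x)
                if x in taken:
                    continue  # one class per site
                taken.add(x)
                recs.append((chrom, x, cls))
    sites = pd.DataFrame(recs, columns=["chrom", "pos", "func_class"])
    order = {c: i for i, c in enumerate(layout.names)}
    sites["chrom_order"] = sites["chrom"].map(order)
    sites = sites.sort_values(["chrom_order", "pos"], kind="mergesort").drop(columns="chrom_order")
    sites = sites.reset_index(drop=True)
    bases = np.array(["A", "C", "G", "T"])
    ref = rng.choice(bases, size=len(sites))
    shift = rng.integers(1, 4, size=len(sites))
    alt = bases[(np.searchsorted(bases, ref) + shift) % 4]
    sites.insert(2, "ref", ref)
    sites.insert(3, "alt", alt)

    n_sites = len(sites)
    freqs = np.empty((n_sites, params.n_pops))
    for cls in FUNC_CLASSES:
        mask = (sites["func_class"] == cls).to_numpy()
        if not mask.any():
            continue
        a, b = params.allele_freq_beta[cls]
        freqs[mask] = rng.beta(a, b, size=(int(mask.sum()), params.n_pops))
    if params.sweep is not None and params.sweep.diverge:
        sw = params.sweep
        in_sw = ((sites["chrom"] == sw.chrom) & (sites["pos"] >= sw.start) & (sites["pos"] < sw.end)).to_numpy()
        # strong frequency contrast: population 1 near fixation for alt
        freqs[in_sw, 0] = rng.uniform(0.85, 0.99, size=int(in_sw.sum()))
        freqs[in_sw, 1:] = rng.uniform(0.01, 0.10, size=(int(in_sw.sum()), params.n_pops - 1))

    # ---- planted tracts ----------------------------------------------------
    sweep_carriers: set[str] = set()
    if params.sweep is not None:
        sw = params.sweep
        n_car = int(round(sw.carrier_fraction * len(samples)))
        idx = rng.choice(len(samples), size=n_car, replace=False)
        sweep_carriers = {samples[i] for i in sorted(idx)}
    truth_recs = []
    tracts_by_sample: dict[str, list[tuple[str, int, int, str]]] = {}
    for s in samples:
        pre: list[tuple[str, int, int, str]] = []
        if s in sweep_carriers:
            sw = params.sweep
            cls = _length_class_of(sw.end - sw.start, params.tract_plan)
            pre = [(sw.chrom, sw.start, sw.end, cls)]
        placed = _place_tracts(layout, params.tract_plan, rng, s, pre)
        tracts_by_sample[s] = placed
        for chrom, st, en, cls in placed:
            truth_recs.append((s, chrom, st, en, en - st, cls))
    truth = pd.DataFrame(truth_recs, columns=["sample", "chrom", "start", "end", "length", "size_class"])
    truth = truth.sort_values(["sample", "chrom", "start"], kind="mergesort").reset_index(drop=True)

    # ---- genotypes ---------------------------------------------------------
    pos_all = sites["pos"].to_numpy()
    chrom_all = sites["chrom"].to_numpy()
    in_tract = np.zeros((n_sites, len(samples)), dtype=bool)
    for j, s in enumerate(samples):
        for chrom, st, en, _ in tracts_by_sample[s]:
            m = (chrom_all == chrom) & (pos_all >= st) & (pos_all < en)
            in_tract[m, j] = True
    p_mat = freqs[:, pop_of]  # (n_sites, n_samples)
    gt = genotype_site(p_mat, in_tract, rng)
    gt = gt.astype(np.int8)
    if params.het_error_rate > 0:
        hom = gt != 1
        flip = hom & (rng.random(gt.shape) < params.het_error_rate)
        gt[flip] = 1
    if params.missing_rate > 0:
        miss = rng.random(gt.shape) < params.missing_rate
        gt[miss] = -1

    # ---- depth tracks ------------------------------------------------------
    dm = params.depth_model
    bin_depth: dict[str, np.ndarray] = {}
    site_frac = np.empty((n_sites, len(samples)))
    for chrom in layout.names:
        nb = layout.n_bins(chrom)
        widths = layout.bin_widths(chrom).astype(float)
        frac = np.minimum(
            1.0, rng.lognormal(-dm.bin_noise_sigma**2 / 2.0, dm.bin_noise_sigma, size=(nb, len(samples)))
        )
        if dm.lowcov_rate > 0:
            low = rng.random((nb, len(samples))) < dm.lowcov_rate
            frac = np.where(low, frac * rng.uniform(0.05, 0.45, size=(nb, len(samples))), frac)
        bin_depth[chrom] = frac * widths[:, None]
        m = chrom_all == chrom
        site_frac[m] = frac[pos_all[m] // layout.bin_size]
    site_depth = rng.poisson(dm.mean_depth * site_frac).astype(np.int32)

    cohort = GenotypeCohort(
        layout=layout,
        samples=samples,
        populations=pops,
        sites=sites,
        genotypes=gt,
        bin_depth=bin_depth,
        site_depth=site_depth,
    )
    return SimResult(cohort=cohort, truth_tracts=truth, params=params)


def _length_class_of(length: int, plan: dict[str, TractPlan]) -> str:
    for cls, tp in plan.items():
        if tp.min_len <= length <= tp.max_len:
            return cls
    return "M"


def downsample_to_array(cohort: GenotypeCohort, target_density: float, rng: np.random.Generator) -> GenotypeCohort:
    """Uniformly thin the site set to ``target_density`` sites/bp, emulating
    the drop from sequencing to SNP-array resolution. Genotypes at retained
    sites are unchanged; depth tracks are kept."""
    current = cohort.n_sites / cohort.layout.total_length
    if target_density >= current:
        warnings.warn("target density >= current density; returning cohort unchanged")
        return cohort
    n_keep = int(round(cohort.n_sites * target_density / current))
    keep = np.sort(rng.choice(cohort.n_sites, size=n_keep, replace=False))
    return GenotypeCohort(
        layout=cohort.layout,
        samples=list(cohort.samples),
        populations=dict(cohort.populations),
        sites=cohort.sites.iloc[keep].reset_index(drop=True),
        genotypes=cohort.genotypes[keep],
        bin_depth={c: a.copy() for c, a in cohort.bin_depth.items()},
        site_depth=None if cohort.site_depth is None else cohort.site_depth[keep],
    )


def with_seed(params: SimParams, seed: int) -> SimParams:
    """Return a copy of ``params`` with a different seed."""
    return replace(params, seed=seed)


#: genome size the default tract-plan counts are referenced to
TRACT_RATE_REF_BP = 30_000_000


def scaled_tract_plan(layout: GenomeLayout, plan: dict[str, TractPlan] | None = None) -> dict[str, TractPlan]:
    """Rescale per-individual tract counts to a genome of a different size.

    Tract counts are per-genome rates; the defaults target a 30-Mbp genome,
    so a smaller demo genome should carry proportionally fewer tracts to
    keep the ROH genome fraction comparable. Length distributions are left
    untouched (size-class boundaries are absolute).
    """
    plan = plan or _default_tract_plan()
    scale = layout.total_length / TRACT_RATE_REF_BP
    out = {}
    for cls, tp in plan.items():
        if tp.min_len > max(layout.lengths.values()):
            continue  # class cannot fit on any chromosome
        out[cls] = replace(tp, mean_count=tp.mean_count * scale)
    return out


def enrichment_experiment_params(seed: int, n_pops: int = 4, n_per_pop: int = 5) -> SimParams:
    """Study conditions for the deleterious-enrichment contrast.

    The slope difference between rare (deleterious, mean frequency 0.05) and
    common (non-deleterious, mean 0.2) alternate-homozygote proportions is
    largest at low ROH coverage, where the saturating relation
    f = G p / (G p + (1 - G) p^2) is steepest for rare alleles. The cohort
    therefore carries short and medium tracts only (coverage spanning
    roughly 0.02-0.35) and a denser deleterious site set so each
    individual's f_d is estimated from enough homozygotes.
    """
    dens = _default_densities()
    dens["deleterious"] = 2.0e-3
    plan = {
        "S": TractPlan(8.0, 15_000, 90_000),
        "M": TractPlan(3.0, 120_000, 1_500_000),
    }
    return SimParams(n_pops=n_pops, n_per_pop=n_per_pop, site_density=dens, tract_plan=plan, seed=seed)


def sweep_experiment_params(seed: int, layout: GenomeLayout | None = None) -> SimParams:
    """Study conditions for the shared-sweep positive control: a 2-Mbp
    region on the first chromosome carried as an identical tract by 80% of
    individuals, with strong allele-frequency divergence of population P1
    inside it."""
    layout = layout or demo_layout()
    chrom = layout.names[0]
    mid = layout.length(chrom) // 2
    sweep = SweepSpec(chrom=chrom, start=mid - 1_000_000, end=mid + 1_000_000, carrier_fraction=0.8)
    return SimParams(sweep=sweep, seed=seed)
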