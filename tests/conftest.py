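"""Shared fixtures: a session-scoped simulated cohort plus toy-cohort builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import rohscape as rs


@pytest.fixture(scope="session")
def default_sim() -> rs.SimResult:
    """Default-condition cohort: 4 populations x 6 individuals, 2 x 15 Mbp."""
    return rs.simulate_cohort(rs.demo_layout(), rs.SimParams(seed=7))


@pytest.fixture(scope="session")
def called_roh(default_sim) -> pd.DataFrame:
    return rs.classify_roh(rs.call_roh_cohort(default_sim.cohort))


@pytest.fixture(scope="session")
def profiles(default_sim, called_roh) -> pd.DataFrame:
    return rs.coverage_profile(called_roh, default_sim.cohort.layout, samples=default_sim.cohort.samples)


def make_cohort(
    layout: rs.GenomeLayout,
    positions: list[tuple[str, int]],
    genotypes: np.ndarray,
    func_class: str | list[str] = "synonymous",
    samples: list[str] | None = None,
    bin_depth: dict[str, np.ndarray] | None = None,
) -> rs.GenotypeCohort:
    """Hand-built cohort for toy examples; full coverage unless given."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    if genotypes.ndim == 1:
        genotypes = genotypes[:, None]
    n_sites, n_samples = genotypes.shape
    samples = samples or [f"ind{j}" for j in range(n_samples)]
    classes = [func_class] * n_sites if isinstance(func_class, str) else list(func_class)
    sites = pd.DataFrame(
        {
            "chrom": [c for c, _ in positions],
            "pos": [p for _, p in positions],
            "ref": "A",
            "alt": "T",
            "func_class": classes,
        }
    )
    if bin_depth is None:
        bin_depth = {
            c: np.repeat(layout.bin_widths(c).astype(float)[:, None], n_samples, axis=1) for c in layout.names
        }
    return rs.GenotypeCohort(
        layout=layout,
        samples=samples,
        populations={s: "pop1" for s in samples},
        sites=sites,
        genotypes=genotypes,
        bin_depth=bin_depth,
    )


def make_track(
    layout: rs.GenomeLayout,
    corrected: dict[str, np.ndarray],
    usable: dict[str, np.ndarray] | None = None,
    sample: str = "ind0",
) -> rs.BinnedHetTrack:
    """Hand-built binned track (raw/depth filled consistently)."""
    usable = usable or {c: np.ones(len(v), dtype=bool) for c, v in corrected.items()}
    corr = {
        c: np.where(usable[c], np.asarray(v, dtype=float), np.nan) for c, v in corrected.items()
    }
    return rs.BinnedHetTrack(
        sample=sample,
        layout=layout,
        raw={c: np.nan_to_num(v).astype(np.int64) for c, v in corr.items()},
        depth={c: layout.bin_widths(c).astype(float) for c in corrected},
        corrected=corr,
        usable=usable,
    )


def recall_with_boundary(truth: pd.DataFrame, called: pd.DataFrame, bin_size: int, min_bins: int = 2) -> float:
    """Fraction of truth tracts >= min_bins recovered with <= 1-bin boundary error."""
    t = truth[truth["length"] >= min_bins * bin_size]
    if not len(t):
        return float("nan")
    hits = 0
    for row in t.itertuples(index=False):
        sub = called[(called["sample"] == row.sample) & (called["chrom"] == row.chrom)]
        if len(sub):
            ok = ((sub["start"] - row.start).abs() <= bin_size) & ((sub["end"] - row.end).abs() <= bin_size)
            hits += bool(ok.any())
    return hits / len(t)


def random_binned_track(rng: np.random.Generator, max_bins: int = 100) -> rs.BinnedHetTrack:
    """Random small track: 1-3 chromosomes, <= max_bins bins total, mixed
    usability, a spread of low/high corrected counts."""
    n_chrom = int(rng.integers(1, 4))
    sizes = rng.integers(3, max(4, max_bins // n_chrom), size=n_chrom)
    layout = rs.GenomeLayout(tuple((f"c{i}", int(s) * 10_000) for i, s in enumerate(sizes)))
    corrected, usable = {}, {}
    for i, s in enumerate(sizes):
        vals = rng.choice([0.0, 0.2, 1.0, 3.0, 8.0], size=int(s), p=[0.3, 0.15, 0.15, 0.2, 0.2])
        u = rng.random(int(s)) > 0.1
        corrected[f"c{i}"] = vals
        usable[f"c{i}"] = u
    return make_track(layout, corrected, usable)
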