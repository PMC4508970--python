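"""Weir–Cockerham components and binned Fst: textbook oracle, estimator
properties, aggregation and track correlation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rohscape as rs

from conftest import make_cohort


def wc_oracle(c1, c2):
    """Scalar textbook two-population variance components (independent of the
    vectorized implementation)."""
    r = 2
    n = [sum(c1), sum(c2)]
    p = [(c[1] + 2 * c[2]) / (2 * nn) for c, nn in zip((c1, c2), n)]
    h = [c[1] / nn for c, nn in zip((c1, c2), n)]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(nn * pp for nn, pp in zip(n, p)) / (r * nbar)
    hbar = sum(nn * hh for nn, hh in zip(n, h)) / (r * nbar)
    s2 = sum(nn * (pp - pbar) ** 2 for nn, pp in zip(n, p)) / ((r - 1) * nbar)
    if pbar in (0.0, 1.0) or nbar <= 1 or nc <= 0:
        return 0.0, 0.0, 0.0
    a = nbar / nc * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


def test_fixed_difference_theta_one():
    theta = rs.wc_theta_site([0, 0, 10], [10, 0, 0])
    assert abs(theta - 1.0) < 1e-12


def test_identical_counts_theta_nonpositive():
    theta = rs.wc_theta_site([5, 4, 1], [5, 4, 1])
    assert theta <= 0


def test_monomorphic_returns_nan():
    assert np.isnan(rs.wc_theta_site([10, 0, 0], [8, 0, 0]))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
def test_components_match_oracle_and_label_swap(a0, a1, a2, b0, b1, b2):
    c1 = [a0 + 1, a1, a2]
    c2 = [b0 + 1, b1, b2]
    a, b, c = rs.wc_components(np.array([c1]), np.array([c2]))
    ae, be, ce = wc_oracle(c1, c2)
    assert a[0] == pytest.approx(ae, abs=1e-12)
    assert b[0] == pytest.approx(be, abs=1e-12)
    assert c[0] == pytest.approx(ce, abs=1e-12)
    # swapping which allele is called "alt" leaves theta unchanged
    t1 = rs.wc_theta_site(c1, c2)
    t2 = rs.wc_theta_site(c1[::-1], c2[::-1])
    if np.isfinite(t1) or np.isfinite(t2):
        assert t1 == pytest.approx(t2, abs=1e-12)


def _two_pop_cohort(rng, n_sites=60, diverged=False):
    layout = rs.GenomeLayout((("chr1", 200_000),))
    positions = [("chr1", int(p)) for p in np.sort(rng.choice(200_000, n_sites, replace=False))]
    n_per = 6
    if diverged:
        p1 = rng.uniform(0.7, 1.0, n_sites)
        p2 = rng.uniform(0.0, 0.3, n_sites)
    else:
        p1 = p2 = rng.uniform(0.1, 0.9, n_sites)
    gt = np.empty((n_sites, 2 * n_per), dtype=np.int8)
    gt[:, :n_per] = rng.binomial(2, p1[:, None], (n_sites, n_per))
    gt[:, n_per:] = rng.binomial(2, p2[:, None], (n_sites, n_per))
    samples = [f"A{i}" for i in range(n_per)] + [f"B{i}" for i in range(n_per)]
    cohort = make_cohort(layout, positions, gt, samples=samples)
    cohort.populations = {s: s[0] for s in samples}
    return cohort


def test_fst_bins_ratio_of_sums_oracle():
    rng = np.random.default_rng(5)
    cohort = _two_pop_cohort(rng)
    tracks = rs.fst_bins(cohort)
    track = tracks[("A", "B")]["chr1"]
    # recompute per bin with the scalar oracle (ratio of sums)
    pos = cohort.sites["pos"].to_numpy()
    idxA = [cohort.sample_index(s) for s in cohort.pop_samples("A")]
    idxB = [cohort.sample_index(s) for s in cohort.pop_samples("B")]
    for b in range(cohort.layout.n_bins("chr1")):
        m = pos // 10_000 == b
        num = den = 0.0
        for i in np.where(m)[0]:
            c1 = [(cohort.genotypes[i, idxA] == k).sum() for k in range(3)]
            c2 = [(cohort.genotypes[i, idxB] == k).sum() for k in range(3)]
            a, bb, cc = wc_oracle(c1, c2)
            num += a
            den += a + bb + cc
        if den == 0:
            assert np.isnan(track[b])
        else:
            assert track[b] == pytest.approx(num / den, abs=1e-12)


def test_fst_monomorphic_and_fixed_difference_bins():
    layout = rs.GenomeLayout((("chr1", 30_000),))
    positions = [("chr1", 1_000), ("chr1", 11_000)]
    gt = np.array([[0, 0, 0, 0], [2, 2, 0, 0]], dtype=np.int8)  # site2: fixed diff
    cohort = make_cohort(layout, positions, gt, samples=["A1", "A2", "B1", "B2"])
    cohort.populations = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
    track = rs.fst_bins(cohort)[("A", "B")]["chr1"]
    assert np.isnan(track[0])  # monomorphic bin
    assert track[1] == pytest.approx(1.0, abs=1e-12)
    assert np.isnan(track[2])  # no sites at all


def test_fst_divergence_increases_theta():
    rng = np.random.default_rng(6)
    same = rs.fst_bins(_two_pop_cohort(rng, diverged=False))[("A", "B")]["chr1"]
    rng = np.random.default_rng(6)
    div = rs.fst_bins(_two_pop_cohort(rng, diverged=True))[("A", "B")]["chr1"]
    assert np.nanmean(div) > np.nanmean(same) + 0.3


def test_single_sample_population_skipped():
    layout = rs.GenomeLayout((("chr1", 30_000),))
    cohort = make_cohort(layout, [("chr1", 1_000)], np.array([[0, 2, 1]], dtype=np.int8), samples=["A1", "B1", "B2"])
    cohort.populations = {"A1": "A", "B1": "B", "B2": "B"}
    with pytest.warns(UserWarning), pytest.raises(ValueError):
        rs.fst_bins(cohort)


def test_aggregate_track_missing_aware():
    layout = rs.GenomeLayout((("chr1", 70_000),), bin_size=10_000)
    vals = {"chr1": np.array([1.0, np.nan, 3.0, np.nan, np.nan, 6.0, 9.0])}
    agg = rs.aggregate_track(vals, layout, window=30_000)
    assert agg["chr1"][0] == pytest.approx(2.0)  # mean of 1, 3
    assert agg["chr1"][1] == pytest.approx(6.0)
    assert agg["chr1"][2] == pytest.approx(9.0)  # partial window at the end


def test_correlate_tracks_identity_and_minimum():
    layout = rs.GenomeLayout((("chr1", 50_000),), bin_size=10_000)
    v = {"chr1": np.array([1.0, 2, 3, 4, 5])}
    r, p = rs.correlate_tracks(v, v, layout)
    assert r == pytest.approx(1.0)
    sparse = {"chr1": np.array([1.0, np.nan, np.nan, np.nan, np.nan])}
    with pytest.raises(ValueError, match="non-missing"):
        rs.correlate_tracks(sparse, v, layout)


def test_sweep_positive_control():
    """Co-located shared tracts and frequency divergence yield a positive
    sharing/Fst correlation involving the diverged population."""
    layout = rs.demo_layout()
    hits = 0
    for seed in (101, 102, 103):
        sim = rs.simulate_cohort(layout, rs.sweep_experiment_params(seed))
        roh = rs.classify_roh(rs.call_roh_cohort(sim.cohort))
        share = rs.sharing_track(roh, layout)
        track = rs.fst_bins(sim.cohort)[("P1", "P2")]
        r, p = rs.correlate_sharing_selection(track, share, layout)
        hits += (r > 0) and (p < 0.05)
    assert hits >= 2
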