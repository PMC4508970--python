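"""End-to-end orchestration from a single YAML config.

Stages: (optional) simulate -> ROH calling -> landscape/sharing ->
functional partition -> enrichment regressions -> Fst -> sharing/Fst
correlation. Every output directory gets a ``run_info.yaml`` stamping the
seed and a hash of the resolved config, so a rerun with the same config is
byte-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .caller import bin_heterozygosity, call_roh, nucleotide_diversity
from .cohort import GenotypeCohort
from .fst import correlate_sharing_selection, fst_bins
from .landscape import SizeClassThresholds, classify_roh, coverage_profile, sharing_null, sharing_track
from .layout import GenomeLayout
from .partition import f_matrix, partition_genotypes, proportions
from .simulate import SimParams, demo_layout, scaled_tract_plan, simulate_cohort
from .stats import fit_interaction_model, split_low_high


@dataclass
class RunConfig:
    """Resolved run configuration (see ``RunConfig.from_yaml``)."""

    outdir: str
    vcf: str | None = None
    annotations: str | None = None
    popmap: str | None = None
    layout: str | None = None
    bin_depth: str | None = None
    simulate: bool = True
    n_chrom: int = 2
    chrom_length: int = 5_000_000
    n_pops: int = 3
    n_per_pop: int = 8
    bin_size: int = 10_000
    threshold_factor: float = 0.25
    min_length: int = 10_000
    short_max: int = 100_000
    long_min: int = 3_000_000
    low_high_cutoff: float = 0.20
    null_reps: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis written elsewhere stamps identically)."""
        params = {
            k: v
            for k, v in asdict(self).items()
            if k not in ("outdir", "vcf", "annotations", "popmap", "layout", "bin_depth")
        }
        return hashlib.sha256(json.dumps(params, sort_keys=True).encode()).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[GenotypeCohort, pd.DataFrame | None]:
    if config.simulate:
        layout = demo_layout(config.n_chrom, config.chrom_length, config.bin_size)
        params = SimParams(
            n_pops=config.n_pops,
            n_per_pop=config.n_per_pop,
            tract_plan=scaled_tract_plan(layout),
            seed=config.seed,
        )
        sim = simulate_cohort(layout, params)
        return sim.cohort, sim.truth_tracts
    for key in ("vcf", "layout"):
        val = getattr(config, key)
        if val is None:
            raise ValueError(f"config without simulate=true must set {key!r}")
        if not Path(val).exists():
            raise FileNotFoundError(f"stage input missing: {key} = {val}")
    layout = GenomeLayout.from_tsv(config.layout, bin_size=config.bin_size)
    ann = rio.read_annotations(config.annotations) if config.annotations else None
    pops = rio.read_popmap(config.popmap) if config.popmap else None
    cohort = rio.read_vcf(config.vcf, layout, annotations=ann, populations=pops)
    if config.bin_depth:
        cohort.bin_depth = rio.read_bin_depth(config.bin_depth, layout, cohort.samples)
    return cohort, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; writes TSV/bedGraph outputs under ``outdir`` and
    returns a summary report dictionary (also written as report.json)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    def _stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - error path
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    cohort, truth = _stage("load")(lambda: _load_inputs(config))
    layout = cohort.layout
    if config.simulate:
        rio.write_vcf(cohort, out / "cohort.vcf")
        rio.write_annotations(cohort, out / "annotations.tsv")
        rio.write_popmap(cohort, out / "popmap.tsv")
        layout.to_tsv(out / "layout.tsv")
        if truth is not None:
            rio.write_truth_bed(truth, out / "truth_tracts.bed")

    # --- ROH calling -------------------------------------------------------
    def _call():
        rows, div = [], []
        for s in cohort.samples:
            track = bin_heterozygosity(cohort, s)
            roh_s = call_roh(track, config.threshold_factor, config.min_length)
            rows.append(roh_s)
            d = nucleotide_diversity(track, roh_s)
            div.append({"sample": s, "pi": d.pi, "pi_out": d.pi_out})
        return pd.concat(rows, ignore_index=True), pd.DataFrame(div)

    roh, diversity = _stage("call-roh")(_call)
    thresholds = SizeClassThresholds(config.short_max, config.long_min)
    roh = classify_roh(roh, thresholds)
    rio.write_roh_tsv(roh, out / "roh.tsv")
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
    report["n_roh"] = int(len(roh))
    report["mean_pi"] = float(diversity["pi"].mean())
    report["mean_pi_out"] = float(diversity["pi_out"].mean())

    # --- landscape ---------------------------------------------------------
    def _landscape():
        prof = coverage_profile(roh, layout, samples=cohort.samples)
        share = sharing_track(roh, layout)
        rng = np.random.default_rng(config.seed + 1)
        null = sharing_null(roh, layout, config.null_reps, rng) if config.null_reps else pd.DataFrame()
        return prof, share, null

    profiles, share, null = _stage("landscape")(_landscape)
    profiles.to_csv(out / "coverage_profiles.tsv", sep="\t", index=False)
    rio.write_bedgraph({c: v.astype(float) for c, v in share.items()}, layout, out / "sharing.bedgraph", "roh_sharing")
    if len(null):
        null.to_csv(out / "sharing_null.tsv", sep="\t", index=False)
    obs_max = int(max(v.max() for v in share.values()))
    report["mean_G_R"] = float(profiles["G_R"].mean())
    report["observed_max_sharing"] = obs_max
    if len(null):
        report["null_max_sharing_q99"] = float(null["max_sharing"].quantile(0.99))

    # --- partition + regressions ------------------------------------------
    def _partition():
        counts = partition_genotypes(cohort, roh)
        prop = proportions(counts)
        return counts, prop

    counts, prop = _stage("partition")(_partition)
    counts.to_frame().to_csv(out / "partition_counts.tsv", sep="\t", index=False)
    prop.to_csv(out / "partition_proportions.tsv", sep="\t", index=False)

    def _regress():
        g_r = profiles.set_index("sample").loc[cohort.samples, "G_R"].to_numpy()
        f_n = f_matrix(prop, "R", "non_deleterious", cohort.samples)
        f_d = f_matrix(prop, "R", "deleterious", cohort.samples)
        return fit_interaction_model(f_n, g_r, f_d, g_r)

    try:
        fit = _stage("regress")(_regress)
        fit.to_frame("deleterious_vs_non_deleterious_anyROH").to_csv(out / "regression.tsv", sep="\t", index=False)
        report["beta3"] = float(fit.beta[3])
        report["beta3_p"] = float(fit.p[3])
    except RuntimeError as exc:
        warnings.warn(str(exc))
        report["beta3"] = None
    groups = split_low_high(profiles, config.low_high_cutoff)
    groups.to_csv(out / "roh_groups.tsv", sep="\t", index=False)

    # --- Fst + correlation -------------------------------------------------
    def _fst():
        tracks = fst_bins(cohort)
        results = {}
        for pair, tr in tracks.items():
            r, p = correlate_sharing_selection(tr, share, layout)
            results[pair] = (r, p)
            rio.write_bedgraph(tr, layout, out / f"fst_{pair[0]}_{pair[1]}.bedgraph", f"fst_{pair[0]}_{pair[1]}")
        return results

    fst_corr = _stage("fst")(_fst)
    report["fst_sharing_correlation"] = {
        f"{a}-{b}": {"r": r, "p": p} for (a, b), (r, p) in fst_corr.items()
    }

    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "run_info.yaml").write_text(yaml.safe_dump({"config_hash": config.config_hash(), "seed": config.seed, **asdict(config)}))
    return report
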