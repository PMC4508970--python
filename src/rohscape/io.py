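"""Readers and writers for the package's on-disk formats.

VCF carries genotypes (GT) and per-site depth (DP) per sample; internal
0-based positions become 1-based POS on emission. Sidecar tables are plain
TSV: site annotations (chrom, pos, ref, alt, class), population map
(sample, pop), genome layout (chrom, length), truth tracts as BED
(0-based half-open), and a per-bin depth table that round-trips the
caller's DP/bin correction input. Tracks are written as bedGraph.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeCohort
from .layout import GenomeLayout

_GT_STR = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(cohort: GenotypeCohort, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rohscape\n")
        for chrom, length in cohort.layout.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(cohort.samples) + "\n")
        dp = cohort.site_depth
        for i, row in enumerate(cohort.sites.itertuples(index=False)):
            fields = [row.chrom, str(row.pos + 1), ".", row.ref, row.alt, ".", "PASS", ".", "GT:DP"]
            for j in range(cohort.n_samples):
                d = int(dp[i, j]) if dp is not None else 0
                fields.append(f"{_GT_STR[int(cohort.genotypes[i, j])]}:{d}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(
    vcf_path,
    layout: GenomeLayout,
    annotations: pd.DataFrame | None = None,
    populations: dict[str, str] | None = None,
    bin_depth: dict[str, np.ndarray] | None = None,
) -> GenotypeCohort:
    """Load a cohort from VCF plus its sidecar tables.

    ``annotations`` supplies per-site functional classes (unannotated sites
    default to 'synonymous'); ``bin_depth`` supplies the caller's covered-bp
    tracks (full coverage assumed when absent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    chroms, poss, refs, alts = [], [], [], []
    gts, dps = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic only
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        g = var.gt_types.astype(np.int8)  # 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        g[g == 3] = -1
        gts.append(g)
        try:
            d = var.format("DP")
            dps.append(d[:, 0].astype(np.int32) if d is not None else np.zeros(len(samples), np.int32))
        except Exception:
            dps.append(np.zeros(len(samples), np.int32))
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})
    if annotations is not None:
        ann = annotations.set_index(["chrom", "pos"])["func_class"]
        key = list(zip(sites["chrom"], sites["pos"]))
        sites["func_class"] = [ann.get(k, "synonymous") for k in key]
    else:
        sites["func_class"] = "synonymous"
    if populations is None:
        populations = {s: "pop1" for s in samples}
    return GenotypeCohort(
        layout=layout,
        samples=samples,
        populations=populations,
        sites=sites,
        genotypes=np.array(gts, dtype=np.int8) if gts else np.zeros((0, len(samples)), np.int8),
        bin_depth=bin_depth or {},
        site_depth=np.array(dps, dtype=np.int32) if dps else None,
    )


# ---------------------------------------------------------------------------
# sidecar tables


def write_annotations(cohort: GenotypeCohort, path) -> None:
    cohort.sites[["chrom", "pos", "ref", "alt", "func_class"]].to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_popmap(cohort: GenotypeCohort, path) -> None:
    pd.DataFrame({"sample": cohort.samples, "pop": [cohort.populations[s] for s in cohort.samples]}).to_csv(
        path, sep="\t", index=False
    )


def read_popmap(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["pop"].astype(str)))


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    """Truth tracts as BED: chrom, start, end, sample|size_class."""
    with Path(path).open("w") as fh:
        for row in truth.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.sample}|{row.size_class}\n")


def read_truth_bed(path) -> pd.DataFrame:
    recs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        chrom, start, end, name = line.split("\t")
        sample, cls = name.split("|")
        recs.append((sample, chrom, int(start), int(end), int(end) - int(start), cls))
    return pd.DataFrame(recs, columns=["sample", "chrom", "start", "end", "length", "size_class"])


def write_roh_tsv(roh: pd.DataFrame, path) -> None:
    roh.to_csv(path, sep="\t", index=False)


def read_roh_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bin_depth(cohort: GenotypeCohort, path) -> None:
    """Long-format per-bin covered-bp table: chrom, bin_start, sample, dp."""
    rows = []
    for chrom in cohort.layout.names:
        if chrom not in cohort.bin_depth:
            continue
        starts = cohort.layout.bin_starts(chrom)
        arr = cohort.bin_depth[chrom]
        for j, s in enumerate(cohort.samples):
            for b in range(arr.shape[0]):
                rows.append((chrom, int(starts[b]), s, float(arr[b, j])))
    pd.DataFrame(rows, columns=["chrom", "bin_start", "sample", "dp"]).to_csv(path, sep="\t", index=False)


def read_bin_depth(path, layout: GenomeLayout, samples: list[str]) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    s_ix = {s: j for j, s in enumerate(samples)}
    for chrom in layout.names:
        arr = np.zeros((layout.n_bins(chrom), len(samples)))
        sub = df[df["chrom"] == chrom]
        arr[sub["bin_start"].to_numpy() // layout.bin_size, sub["sample"].map(s_ix).to_numpy()] = sub[
            "dp"
        ].to_numpy()
        out[chrom] = arr
    return out


def write_bedgraph(track: dict[str, np.ndarray], layout: GenomeLayout, path, name: str = "track") -> None:
    with Path(path).open("w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom in layout.names:
            starts = layout.bin_starts(chrom)
            ends = layout.bin_ends(chrom)
            vals = track[chrom]
            for s, e, v in zip(starts, ends, vals):
                if np.isfinite(float(v)):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
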