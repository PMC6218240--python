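"""Readers and writers for the external formats the pipeline touches.

VCF genotypes are read with :mod:`cyvcf2`; everything else is plain TSV/BED
through pandas.  All writers round-trip bit-exactly through the matching
reader (scores are serialized with full ``repr`` precision).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    MISSING,
    CandidateSet,
    GeneticMap,
    HaplotypePanel,
    IntervalSet,
    PanelError,
    ScoreTrack,
)

logger = logging.getLogger("sweepenrich")


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def read_pop_map(path) -> dict:
    """Read a two-column TSV (sample, population) into a dict.

    A header line ``sample<TAB>population`` is accepted and skipped.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise PanelError(f"population map {path} needs two tab-separated columns")
    if str(df.iloc[0, 0]).lower() == "sample":
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_haplotypes(vcf_path, pop_map_path, het_policy: str = "missing",
                    rng=None) -> HaplotypePanel:
    """Load a haploid panel from a VCF of inbred lines.

    Heterozygous genotypes are handled per ``het_policy``: ``"missing"``
    (default; the panels are inbred lines, a het call is treated as a failed
    call) or ``"random"`` (pick one allele at random, for generality).
    Multiallelic and non-SNP records are skipped with a logged count.
    """
    from cyvcf2 import VCF

    if het_policy not in ("missing", "random"):
        raise PanelError(f"unknown het_policy {het_policy!r}")
    if het_policy == "random" and rng is None:
        rng = np.random.default_rng()

    pop_labels = read_pop_map(pop_map_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    unlabeled = [s for s in samples if s not in pop_labels]
    if unlabeled:
        raise PanelError(f"VCF samples absent from population map: {unlabeled}")

    chroms: list = []
    positions: list = []
    rows: list = []
    n_skipped = 0
    n_het = 0
    last: dict = {}
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        if var.CHROM in last and var.POS <= last[var.CHROM]:
            raise PanelError(
                f"VCF not sorted: {var.CHROM}:{var.POS} after {last[var.CHROM]}"
            )
        last[var.CHROM] = var.POS
        row = np.empty(len(samples), dtype=np.int8)
        for j, g in enumerate(var.genotypes):
            a, b = g[0], g[1] if len(g) > 2 else g[0]
            if a < 0 or b < 0:
                row[j] = MISSING
            elif a == b:
                row[j] = a
            else:
                n_het += 1
                row[j] = MISSING if het_policy == "missing" else rng.choice((a, b))
        chroms.append(var.CHROM)
        positions.append(var.POS)
        rows.append(row)
    if n_skipped:
        logger.info("read_haplotypes: skipped %d multiallelic/non-SNP records", n_skipped)
    if n_het:
        logger.info("read_haplotypes: %d heterozygous calls handled as %s",
                    n_het, het_policy)
    alleles = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    return HaplotypePanel(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        alleles=alleles,
        sample_ids=samples,
        pop_labels={s: pop_labels[s] for s in samples},
    )


def write_haplotypes_vcf(panel: HaplotypePanel, path) -> None:
    """Write the panel as an uncompressed VCF (alleles as homozygous diploid GTs)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepenrich\n")
        for c in panel.chromosomes:
            length = int(panel.pos[panel.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        gt = {0: "0/0", 1: "1/1", MISSING: "./."}
        for i in range(panel.n_sites):
            calls = "\t".join(gt[int(a)] for a in panel.alleles[i])
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def write_pop_map(pop_labels: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\n")
        for s, p in pop_labels.items():
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# complete-data subset
# ---------------------------------------------------------------------------

def complete_data_subset(panel: HaplotypePanel, pops) -> HaplotypePanel:
    """Restrict to sites fully called and polymorphic across the two panels.

    Keeps only sites with zero missing calls among the members of both named
    populations, then drops sites monomorphic across their union (a minimum
    minor-allele frequency of 0, i.e. polymorphic-only).  Idempotent.
    """
    pop_a, pop_b = pops
    cols = np.concatenate([panel.pop_columns(pop_a), panel.pop_columns(pop_b)])
    sub = panel.alleles[:, cols]
    complete = ~(sub == MISSING).any(axis=1)
    counts1 = (sub == 1).sum(axis=1)
    polymorphic = (counts1 > 0) & (counts1 < sub.shape[1])
    keep = complete & polymorphic
    n_missing = int((~complete).sum())
    n_mono = int((complete & ~polymorphic).sum())
    if n_missing or n_mono:
        logger.info(
            "complete_data_subset: dropped %d sites with missing calls and "
            "%d monomorphic sites; %d retained", n_missing, n_mono, int(keep.sum())
        )
    return panel.take_sites(keep)


# ---------------------------------------------------------------------------
# genetic map / BED / candidates / score tracks
# ---------------------------------------------------------------------------

def read_genetic_map(path) -> GeneticMap:
    """Read a TSV of (chrom, bp, cM) anchors; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 3:
        raise PanelError(f"genetic map {path} needs chrom, bp, cM columns")
    first = str(df.iloc[0, 1])
    try:
        float(first)
    except ValueError:
        df = df.iloc[1:]
    anchors: dict = {}
    for c, grp in df.groupby(df.columns[0], sort=False):
        anchors[c] = (
            grp.iloc[:, 1].astype(float).to_numpy(),
            grp.iloc[:, 2].astype(float).to_numpy(),
        )
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tbp\tcM\n")
        for c, (bp, cm) in gmap.anchors.items():
            for b, m in zip(bp, cm):
                fh.write(f"{c}\t{b:.0f}\t{float(m)!r}\n")


def read_intervals(path) -> IntervalSet:
    """Read a BED file (0-based half-open) of gene intervals."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={0: str})
    return IntervalSet(df)


def write_intervals(intervals: IntervalSet, path) -> None:
    intervals.df.to_csv(path, sep="\t", header=False, index=False)


def read_candidates(path) -> CandidateSet:
    """Read a candidate association TSV with columns chrom, pos, trait[, source_population]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "trait"}
    if not required <= set(df.columns):
        raise PanelError(f"candidate table {path} needs columns {sorted(required)}")
    return CandidateSet(df)


def write_candidates(candidates: CandidateSet, path) -> None:
    candidates.df.to_csv(path, sep="\t", index=False)


def read_score_track(path, statistic: str | None = None) -> ScoreTrack:
    """Read a score-track TSV (chrom, pos, statistic, value)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    if len(df) == 0:
        logger.warning("read_score_track: %s is empty", path)
        return ScoreTrack(pd.DataFrame(columns=["chrom", "pos", "value"]),
                          statistic or "unknown")
    name = statistic or (str(df["statistic"].iloc[0]) if "statistic" in df else "unknown")
    cols = [c for c in ("chrom", "pos", "value", "raw") if c in df.columns]
    return ScoreTrack(df[cols], name)


def write_score_track(track: ScoreTrack, path) -> None:
    df = track.df.copy()
    df.insert(2, "statistic", track.statistic)
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("\t".join(repr(v) if isinstance(v, float) else str(v)
                              for v in row) + "\n")


def attach_external_scores(path, statistic_name: str) -> ScoreTrack:
    """Load an externally computed statistic (e.g. XP-CLR) as a ScoreTrack.

    The resulting track is usable by binning and enrichment identically to
    internally computed tracks.
    """
    return read_score_track(path, statistic=statistic_name)


# ---------------------------------------------------------------------------
# YAML config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
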