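"""Binning per-SNP scores into nonoverlapping 10 kb windows.

Each SNP at 1-based position ``p`` belongs to the window starting at
``((p - 1) // size) * size`` (0-based half-open).  A window's binned score
is its most extreme member value: the maximum absolute value with sign
preserved, so both tails of a signed statistic such as XP-EHH survive
binning; for nonnegative statistics this reduces to the plain maximum.
Ties between ``+a`` and ``-a`` keep the positive value.

Windows are then annotated with the covariates the matched null needs:
gene count (any overlap), local recombination rate (cM difference across
the window per Mb), and the mean minor-allele frequency of the window's
scored SNPs in each population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CandidateSet, GeneticMap, HaplotypePanel, IntervalSet, PanelError, ScoreTrack
from .io import logger
from .selstats import allele_frequencies

WINDOW_SIZE_DEFAULT = 10_000


def window_start(pos, window_size: int = WINDOW_SIZE_DEFAULT):
    """0-based window start for 1-based SNP position(s)."""
    return ((np.asarray(pos, dtype=np.int64) - 1) // window_size) * window_size


def bin_max(track: ScoreTrack, window_size: int = WINDOW_SIZE_DEFAULT) -> pd.DataFrame:
    """Bin a score track into windows by most extreme member score.

    Returns a window table (one row per *scored* window) with columns
    ``chrom, start, end, score, n_snps_scored``, ordered by position within
    chromosome.
    """
    if window_size <= 0:
        raise PanelError("window_size must be positive")
    if len(track) == 0:
        raise PanelError("cannot bin an empty score track")
    df = track.df.copy()
    df["start"] = window_start(df["pos"].to_numpy(), window_size)
    # sort so the first row per window is the winner: largest |score|,
    # positive preferred on ties, then deterministic by position
    df["_abs"] = df["value"].abs()
    df["_neg"] = df["value"] < 0
    df = df.sort_values(["chrom", "start", "_abs", "_neg", "pos"],
                        ascending=[True, True, False, True, True], kind="stable")
    grouped = df.groupby(["chrom", "start"], sort=False)
    out = grouped.head(1).loc[:, ["chrom", "start", "value"]].rename(columns={"value": "score"})
    out["n_snps_scored"] = grouped.size().to_numpy()
    out["end"] = out["start"] + window_size
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    return out[["chrom", "start", "end", "score", "n_snps_scored"]]


def interpolate_cm(gmap: GeneticMap, chrom, pos):
    """Genetic position in cM by linear interpolation of the map anchors."""
    return gmap.interpolate(chrom, pos)


def annotate_windows(windows: pd.DataFrame, gmap: GeneticMap, genes: IntervalSet,
                     panel: HaplotypePanel, pop_a: str, pop_b: str,
                     track: ScoreTrack | None = None) -> pd.DataFrame:
    """Attach matched-null covariates to a window table.

    * ``gene_count`` — gene intervals overlapping the window at all (a gene
      spanning two windows counts in both);
    * ``recomb_rate`` — (cM at end - cM at start) / window length in Mb;
    * ``mean_freq_a`` / ``mean_freq_b`` — mean minor-allele frequency of the
      window's scored SNPs in each population (``track`` defaults to all
      panel sites).
    """
    out = windows.reset_index(drop=True).copy()

    gene_counts = np.zeros(len(out), dtype=np.int64)
    for c, grp in out.groupby("chrom", sort=False):
        gdf = genes.df[genes.df["chrom"] == c]
        if len(gdf) == 0:
            continue
        gs = gdf["start"].to_numpy()[None, :]
        ge = gdf["end"].to_numpy()[None, :]
        ws = grp["start"].to_numpy()[:, None]
        we = grp["end"].to_numpy()[:, None]
        gene_counts[grp.index] = ((gs < we) & (ge > ws)).sum(axis=1)
    out["gene_count"] = gene_counts

    rate = np.empty(len(out))
    for c, grp in out.groupby("chrom", sort=False):
        cm_start = gmap.interpolate(c, grp["start"].to_numpy())
        cm_end = gmap.interpolate(c, grp["end"].to_numpy())
        mb = (grp["end"] - grp["start"]).to_numpy() / 1e6
        rate[grp.index] = (cm_end - cm_start) / mb
    out["recomb_rate"] = rate

    freq_a = allele_frequencies(panel, pop_a)
    freq_b = allele_frequencies(panel, pop_b)
    site_df = pd.DataFrame({
        "chrom": panel.chrom,
        "start": window_start(panel.pos),
        "maf_a": np.minimum(freq_a, 1.0 - freq_a),
        "maf_b": np.minimum(freq_b, 1.0 - freq_b),
    })
    if track is not None:
        key = pd.MultiIndex.from_arrays([track.df["chrom"], track.df["pos"]])
        panel_key = pd.MultiIndex.from_arrays([pd.Series(panel.chrom), pd.Series(panel.pos)])
        site_df = site_df[panel_key.isin(key)]
    means = site_df.groupby(["chrom", "start"])[["maf_a", "maf_b"]].mean()
    idx = pd.MultiIndex.from_frame(out[["chrom", "start"]])
    out["mean_freq_a"] = means["maf_a"].reindex(idx).to_numpy()
    out["mean_freq_b"] = means["maf_b"].reindex(idx).to_numpy()
    return out


@dataclass
class ObservedScores:
    """Window scores assigned to candidate associations."""

    df: pd.DataFrame  # columns: chrom, pos, trait, trait_class, window_start, score
    n_retained: int
    n_dropped: int

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy()


def assign_candidate_scores(candidates: CandidateSet,
                            windows: pd.DataFrame,
                            window_size: int = WINDOW_SIZE_DEFAULT) -> ObservedScores:
    """Give each SNP-trait association its window's binned score.

    Associations falling in unscored windows are dropped and counted; the
    retained count is reported alongside the observed sample (a SNP
    associated with several traits contributes one entry per trait).
    """
    cdf = candidates.df.copy()
    cdf["window_start"] = window_start(cdf["pos"].to_numpy(), window_size)
    merged = cdf.merge(
        windows[["chrom", "start", "score"]],
        left_on=["chrom", "window_start"], right_on=["chrom", "start"],
        how="left",
    ).drop(columns="start")
    dropped = int(merged["score"].isna().sum())
    kept = merged.dropna(subset=["score"]).reset_index(drop=True)
    if dropped:
        logger.info("assign_candidate_scores: %d of %d associations in unscored "
                    "windows dropped", dropped, len(merged))
    return ObservedScores(df=kept, n_retained=len(kept), n_dropped=dropped)
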