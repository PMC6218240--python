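"""Enrichment of selection signals in trait-associated windows.

The observed sample is the set of binned selection-statistic scores of the
windows containing a-priori candidate SNP-trait associations.  It is
compared against two null distributions:

* **circular permutation** — candidate window positions are rigidly rotated
  around each chromosome's ordered list of scored windows, preserving the
  candidates' relative spacing and multiplicity while randomizing their
  placement relative to the score landscape;
* **matched-window resampling** — for every candidate window, scored
  non-candidate windows with a similar gene count (default +/-1), local
  recombination rate (+/-20% relative) and per-population allele
  frequencies (+/-0.15 absolute) are sampled without replacement; when
  fewer than ``n_per`` windows match, the allele-frequency criteria are
  dropped and the pool rebuilt from the gene and recombination constraints
  alone.

Observed-vs-null distribution shifts are tested with the two-sample
Kolmogorov-Smirnov test (two-sided, asymptotic p); the branchiness-vs-length
contrast asks whether scores of branchiness-trait associations are
stochastically smaller than those of length-trait associations (one-sided
rank-sum test, normal approximation with tie correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import CandidateSet, GeneticMap, HaplotypePanel, IntervalSet, PanelError, ScoreTrack
from .io import logger
from .windows import (
    WINDOW_SIZE_DEFAULT,
    ObservedScores,
    annotate_windows,
    assign_candidate_scores,
    bin_max,
)


@dataclass
class MatchTolerances:
    """Covariate-matching tolerances for the matched-window null."""

    genes: int = 1            # +/- genes
    recomb_rel: float = 0.20  # +/- fraction of the candidate window's rate
    freq_abs: float = 0.15    # +/- absolute minor-allele frequency, per population


@dataclass
class NullDistribution:
    """One null sample of window scores for an observed candidate set."""

    method: str                     # "circular" | "matched"
    pooled: np.ndarray
    iterations: np.ndarray | None = None   # circular: (n_iter, n_assoc)
    offsets: np.ndarray | None = None      # circular: (n_iter, n_chrom)
    samples: dict = field(default_factory=dict)  # matched: window -> scores
    n_iter: int = 0
    n_per: int = 0
    seed: int | None = None


@dataclass
class EnrichmentResult:
    statistic: str
    null_method: str
    observed: ObservedScores
    null: NullDistribution
    ks_d: float
    ks_p: float
    perm_p: float | None = None
    contrast_w: float | None = None
    contrast_p: float | None = None


def _as_observed(candidates, windows, window_size):
    if isinstance(candidates, ObservedScores):
        return candidates
    return assign_candidate_scores(candidates, windows, window_size)


# ---------------------------------------------------------------------------
# circular permutation null
# ---------------------------------------------------------------------------

def circular_null(candidates, windows: pd.DataFrame, n_iter: int = 10_000,
                  seed=None, window_size: int = WINDOW_SIZE_DEFAULT,
                  offsets=None) -> NullDistribution:
    """Null by rigid rotation of candidate positions along each chromosome.

    Per iteration and per chromosome one uniform offset is drawn over that
    chromosome's ordered list of scored windows; every candidate
    association's window index is shifted by the offset modulo the list
    length, so the candidates' cyclic spacing is preserved exactly.
    ``offsets`` (iterations x chromosomes) overrides the random draw, e.g.
    to enumerate every rotation of a small chromosome.
    """
    if isinstance(candidates, CandidateSet):
        missing = set(candidates.df["chrom"]) - set(windows["chrom"])
        if missing:
            raise PanelError(
                f"chromosome(s) with candidates but no scored windows: {sorted(missing)}"
            )
    observed = _as_observed(candidates, windows, window_size)
    rng = np.random.default_rng(seed)
    win = windows.sort_values(["chrom", "start"]).reset_index(drop=True)

    chrom_list = list(dict.fromkeys(observed.df["chrom"]))
    n_assoc = len(observed.df)
    if offsets is not None:
        offsets = np.asarray(offsets, dtype=np.int64)
        if offsets.ndim == 1:
            offsets = offsets[:, None]
        n_iter = offsets.shape[0]
    iterations = np.empty((n_iter, n_assoc))
    given = offsets
    offsets = np.empty((n_iter, len(chrom_list)), dtype=np.int64)
    obs_chrom = observed.df["chrom"].to_numpy()
    for k, c in enumerate(chrom_list):
        wc = win[win["chrom"] == c]
        starts = wc["start"].to_numpy()
        scores = wc["score"].to_numpy()
        m = starts.size
        rows = np.nonzero(obs_chrom == c)[0]
        cand_ws = observed.df.loc[rows, "window_start"].to_numpy()
        idx = np.searchsorted(starts, cand_ws)
        off = rng.integers(0, m, size=n_iter) if given is None else given[:, k] % m
        offsets[:, k] = off
        iterations[:, rows] = scores[(idx[None, :] + off[:, None]) % m]
    return NullDistribution(method="circular", pooled=iterations.ravel(),
                            iterations=iterations, offsets=offsets,
                            n_iter=n_iter, seed=seed)


# ---------------------------------------------------------------------------
# matched-window null
# ---------------------------------------------------------------------------

def matched_null(candidates, windows: pd.DataFrame, n_per: int = 50,
                 tolerances: MatchTolerances | None = None, seed=None,
                 window_size: int = WINDOW_SIZE_DEFAULT) -> NullDistribution:
    """Null by resampling covariate-matched, non-candidate scored windows.

    For each candidate window the eligible pool must match on gene count,
    recombination rate and both allele-frequency covariates; if fewer than
    ``n_per`` windows qualify, the allele-frequency criteria are omitted
    and the pool rebuilt.  A pool still smaller than ``n_per`` is used
    whole, with a logged warning naming the window.  Sampled scores are
    replicated per association count of the candidate window.
    """
    tolerances = tolerances or MatchTolerances()
    observed = _as_observed(candidates, windows, window_size)
    rng = np.random.default_rng(seed)
    required = ("gene_count", "recomb_rate", "mean_freq_a", "mean_freq_b")
    if any(c not in windows.columns for c in required):
        raise PanelError("windows must be annotated (annotate_windows) for matched_null")

    cand_keys = set(zip(observed.df["chrom"], observed.df["window_start"]))
    win = windows.reset_index(drop=True)
    is_candidate = pd.MultiIndex.from_frame(win[["chrom", "start"]]).isin(cand_keys)
    base_pool = win[~is_candidate]

    counts = observed.df.groupby(["chrom", "window_start"]).size()
    samples: dict = {}
    pooled_parts = []
    for (c, ws), n_assoc in counts.items():
        cand = win[(win["chrom"] == c) & (win["start"] == ws)].iloc[0]
        genes_ok = (base_pool["gene_count"] - cand["gene_count"]).abs() <= tolerances.genes
        rate_lo = cand["recomb_rate"] * (1 - tolerances.recomb_rel)
        rate_hi = cand["recomb_rate"] * (1 + tolerances.recomb_rel)
        rate_ok = base_pool["recomb_rate"].between(min(rate_lo, rate_hi),
                                                   max(rate_lo, rate_hi))
        freq_ok = ((base_pool["mean_freq_a"] - cand["mean_freq_a"]).abs()
                   <= tolerances.freq_abs) & \
                  ((base_pool["mean_freq_b"] - cand["mean_freq_b"]).abs()
                   <= tolerances.freq_abs)
        pool = base_pool[genes_ok & rate_ok & freq_ok]
        if len(pool) < n_per:  # drop the allele-frequency criteria
            pool = base_pool[genes_ok & rate_ok]
        if len(pool) < n_per:
            logger.warning("matched_null: window %s:%d has only %d matched windows "
                           "(< %d) even after relaxation", c, ws, len(pool), n_per)
            drawn = pool["score"].to_numpy()
        else:
            drawn = rng.choice(pool["score"].to_numpy(), size=n_per, replace=False)
        samples[(c, int(ws))] = drawn
        pooled_parts.append(np.tile(drawn, n_assoc))
    pooled = np.concatenate(pooled_parts) if pooled_parts else np.empty(0)
    return NullDistribution(method="matched", pooled=pooled, samples=samples,
                            n_per=n_per, seed=seed)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def ks_two_sample(observed, null_sample) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov D and two-sided asymptotic p."""
    observed = np.asarray(observed, dtype=float)
    null_sample = np.asarray(null_sample, dtype=float)
    if observed.size < 3:
        raise PanelError(f"need >= 3 observed scores for a KS test, have {observed.size}")
    if null_sample.size == 0:
        raise PanelError("empty null sample")
    res = stats.ks_2samp(observed, null_sample, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def _ks_d(sample, sorted_ref) -> float:
    """KS D between a sample and a pre-sorted reference sample.

    The supremum of |ECDF difference| is attained at a jump point; checking
    both one-sided ECDF values of the reference at the sample's own jump
    points is exact and costs O(n log m).
    """
    s = np.sort(np.asarray(sample, dtype=float))
    n, m = s.size, sorted_ref.size
    cdf_right = np.searchsorted(sorted_ref, s, side="right") / m
    cdf_left = np.searchsorted(sorted_ref, s, side="left") / m
    i = np.arange(1, n + 1)
    d_hi = np.abs(i / n - cdf_right).max()
    d_lo = np.abs((i - 1) / n - cdf_left).max()
    return float(max(d_hi, d_lo))


def permutation_ks_p(observed_scores, null: NullDistribution) -> float:
    """Fraction of circular iterations at least as extreme as the observed KS D.

    Secondary, permutation-based p-value: each iteration's scores are
    compared to the pooled null exactly as the observed sample is.
    """
    if null.iterations is None:
        raise PanelError("permutation_ks_p requires a circular null with iterations")
    ref = np.sort(null.pooled)
    d_obs = _ks_d(observed_scores, ref)
    d_iter = np.array([_ks_d(row, ref) for row in null.iterations])
    return float((d_iter >= d_obs).mean())


def branchiness_contrast(observed: ObservedScores) -> tuple[float, float]:
    """One-sided rank-sum test: branchiness scores smaller than length scores.

    Returns the rank-sum statistic W of the branchiness group and the
    one-sided p (normal approximation with tie correction at analysis
    sample sizes; exact enumeration for tiny tie-free groups).
    """
    df = observed.df
    b = df.loc[df["trait_class"] == "branchiness", "score"].to_numpy()
    l = df.loc[df["trait_class"] == "length", "score"].to_numpy()
    if b.size < 3 or l.size < 3:
        raise PanelError(
            f"need >= 3 scores per trait class, have branchiness={b.size}, length={l.size}"
        )
    res = stats.mannwhitneyu(b, l, alternative="less", method="auto")
    w = float(res.statistic) + b.size * (b.size + 1) / 2.0  # U -> rank-sum W
    return w, float(res.pvalue)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_enrichment(tracks, candidates: CandidateSet, gmap: GeneticMap,
                   genes: IntervalSet, panel: HaplotypePanel,
                   pop_a: str, pop_b: str, n_iter: int = 10_000, n_per: int = 50,
                   tolerances: MatchTolerances | None = None, seed=None,
                   window_size: int = WINDOW_SIZE_DEFAULT,
                   methods=("circular", "matched"),
                   compute_permutation_p: bool = True) -> list[EnrichmentResult]:
    """Full enrichment analysis: every score track x every null method.

    ``tracks`` is a mapping from statistic name to :class:`ScoreTrack` (or a
    plain list of tracks).  Returns one :class:`EnrichmentResult` per
    track x method; the branchiness-vs-length contrast is attached whenever
    both trait classes are represented.
    """
    if isinstance(tracks, dict):
        tracks = list(tracks.values())
    if isinstance(seed, np.random.Generator):
        ss = np.random.SeedSequence(int(seed.integers(2**31)))
    else:
        ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(tracks) * len(methods))
    results: list[EnrichmentResult] = []
    k = 0
    for track in tracks:
        win = bin_max(track, window_size)
        win = annotate_windows(win, gmap, genes, panel, pop_a, pop_b, track=track)
        observed = assign_candidate_scores(candidates, win, window_size)
        try:
            contrast_w, contrast_p = branchiness_contrast(observed)
        except PanelError:
            contrast_w = contrast_p = None
        for method in methods:
            child_rng = np.random.default_rng(children[k]); k += 1
            if method == "circular":
                null = circular_null(observed, win, n_iter=n_iter, seed=child_rng)
            elif method == "matched":
                null = matched_null(observed, win, n_per=n_per,
                                    tolerances=tolerances, seed=child_rng)
            else:
                raise PanelError(f"unknown null method {method!r}")
            d, p = ks_two_sample(observed.scores, null.pooled)
            perm_p = None
            if method == "circular" and compute_permutation_p:
                perm_p = permutation_ks_p(observed.scores, null)
            results.append(EnrichmentResult(
                statistic=track.statistic, null_method=method, observed=observed,
                null=null, ks_d=d, ks_p=p, perm_p=perm_p,
                contrast_w=contrast_w, contrast_p=contrast_p,
            ))
    return results


def results_table(results) -> pd.DataFrame:
    """Flat report: statistic, null method, retained count, KS D and p."""
    return pd.DataFrame([{
        "statistic": r.statistic,
        "null_method": r.null_method,
        "n_retained": r.observed.n_retained,
        "ks_d": r.ks_d,
        "ks_p": r.ks_p,
        "perm_p": r.perm_p,
        "contrast_w": r.contrast_w,
        "contrast_p": r.contrast_p,
    } for r in results])
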