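"""Per-SNP cross-population selection statistics.

Two signals of recent selection are computed between an ancestral panel
(``pop_a``, BSSSC0-like) and a derived panel (``pop_b``, ex-PVP-like):

* **FST** — the haploid two-population variance-components estimator with
  the small-r / uneven-sample-size correction (r = 2 populations).
  Negative estimates are retained, not truncated.
* **XP-EHH** — the log ratio of site-specific integrated extended haplotype
  homozygosity (iES) between the two panels, normalized genome-wide to
  mean 0 / sd 1.  Positive scores mean longer, more prevalent haplotypes in
  ``pop_a``; negative scores point to extended haplotypes (recent sweeps)
  in ``pop_b``.

EHH here is site-level (unconditioned on the core allele): ``EHH(x)`` is
the probability that two haplotypes drawn at random from the population are
identical at every site from the core (exclusive) through ``x``.  iES is
the trapezoidal integral of EHH against physical distance in both
directions, with each inter-SNP interval's contribution weighted by
``min(1, scale / gap)`` so sparse regions are down-weighted, truncated at
the first point where EHH drops below the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, HaplotypePanel, PanelError, ScoreTrack
from .io import attach_external_scores, logger  # noqa: F401  (track interface)


@dataclass
class XpehhConfig:
    """Tuning constants of the XP-EHH scan.

    ``scale`` is the gap down-weighting scale in bp (intervals longer than
    this contribute as if they were ``scale`` long); ``ehh_cutoff`` stops
    the EHH integration; ``min_haplotypes`` is the smallest panel usable.
    """

    ehh_cutoff: float = 0.05
    scale: float = 20_000.0
    min_haplotypes: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.ehh_cutoff < 1.0:
            raise ValueError("ehh_cutoff must be in (0, 1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


@dataclass
class EHHCurve:
    """EHH as a function of physical distance from a core site."""

    core_site: int
    direction: str  # "upstream" | "downstream"
    distance_bp: np.ndarray  # non-negative, increasing, first entry 0
    ehh: np.ndarray  # ehh[0] == 1


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(panel: HaplotypePanel, pop: str) -> np.ndarray:
    """Per-site frequency of allele 1 within one population."""
    cols = panel.pop_columns(pop)
    sub = panel.alleles[:, cols]
    called = (sub != MISSING).sum(axis=1)
    if np.any(called == 0):
        i = int(np.argmin(called))
        raise PanelError(
            f"all calls missing in {pop} at {panel.chrom[i]}:{panel.pos[i]}; "
            "filter with complete_data_subset first"
        )
    return (sub == 1).sum(axis=1) / called


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def fst_weir_haploid(panel: HaplotypePanel, pop_a: str, pop_b: str) -> ScoreTrack:
    """Per-site haploid variance-components FST between two panels.

    Uses the two-population (r = 2) estimator with the correction for a
    small number of populations and uneven sample sizes; sites monomorphic
    across both panels (T2 = 0) are excluded with a logged count.
    """
    p_a = allele_frequencies(panel, pop_a)
    p_b = allele_frequencies(panel, pop_b)
    sub_a = panel.alleles[:, panel.pop_columns(pop_a)]
    sub_b = panel.alleles[:, panel.pop_columns(pop_b)]
    n_a = (sub_a != MISSING).sum(axis=1).astype(float)
    n_b = (sub_b != MISSING).sum(axis=1).astype(float)

    r = 2.0
    nbar = (n_a + n_b) / r
    nc = (r * nbar - (n_a**2 + n_b**2) / (r * nbar)) / (r - 1.0)
    pbar = (n_a * p_a + n_b * p_b) / (r * nbar)
    s2 = (n_a * (p_a - pbar) ** 2 + n_b * (p_b - pbar) ** 2) / ((r - 1.0) * nbar)
    t1 = s2 - (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r) / (nbar - 1.0)
    t2 = ((nc - 1.0) / (nbar - 1.0)) * pbar * (1.0 - pbar) \
        + (1.0 + (r - 1.0) * (nbar - nc) / (nbar - 1.0)) * s2 / r

    scored = t2 != 0.0
    n_dropped = int((~scored).sum())
    if n_dropped:
        logger.info("fst_weir_haploid: excluded %d monomorphic sites", n_dropped)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = t1 / t2
    df = pd.DataFrame({
        "chrom": panel.chrom[scored],
        "pos": panel.pos[scored],
        "value": theta[scored],
    })
    return ScoreTrack(df, statistic="FST")


# ---------------------------------------------------------------------------
# EHH curves (reference path, exact integer pair counting)
# ---------------------------------------------------------------------------

def ehh_curve(panel: HaplotypePanel, pop: str, core_site: int, direction: str,
              ehh_cutoff: float = 0.05) -> EHHCurve:
    """EHH curve from a core site, walking one direction along its chromosome.

    The curve starts at (0, 1) by definition, extends site by site, and
    terminates at the chromosome end or at the first point where EHH falls
    below ``ehh_cutoff`` (that sub-cutoff point is kept in the curve; it is
    excluded from integration downstream).
    """
    if direction not in ("upstream", "downstream"):
        raise PanelError(f"unknown direction {direction!r}")
    cols = panel.pop_columns(pop)
    n = cols.size
    if n < 2:
        raise PanelError(f"need >= 2 haplotypes in {pop}, have {n}")
    chrom = panel.chrom[core_site]
    on_chrom = np.nonzero(panel.chrom == chrom)[0]
    step = 1 if direction == "downstream" else -1
    scan = on_chrom[on_chrom > core_site] if step == 1 else on_chrom[on_chrom < core_site][::-1]

    sub = panel.alleles[:, cols]
    if np.any(sub[scan] == MISSING) or np.any(sub[core_site] == MISSING):
        raise PanelError("missing data in scanned range; filter first")

    denom = n * (n - 1) // 2
    core_pos = panel.pos[core_site]
    distances = [0.0]
    values = [1.0]
    # group haplotypes by their extended sequence; EHH = sum C(c,2)/C(n,2)
    codes = np.zeros(n, dtype=np.int64)
    for s in scan:
        codes = codes * 2 + sub[s]
        # re-rank to keep codes small
        _, codes = np.unique(codes, return_inverse=True)
        counts = np.bincount(codes)
        ident_pairs = int((counts * (counts - 1) // 2).sum())
        ehh = ident_pairs / denom
        distances.append(float(abs(panel.pos[s] - core_pos)))
        values.append(ehh)
        if ehh < ehh_cutoff:
            break
    return EHHCurve(core_site=int(core_site), direction=direction,
                    distance_bp=np.array(distances), ehh=np.array(values))


def integrate_ehh(curve_up: EHHCurve | None, curve_down: EHHCurve | None,
                  config: XpehhConfig | None = None) -> float:
    """Gap-weighted trapezoidal integral of EHH over both directions (iES, bp).

    Each interval contributes ``min(gap, scale) * (e0 + e1) / 2``;
    integration stops before the first point with EHH below the cutoff.
    A core with no integrable interval in either direction yields 0.0,
    flagging the site as unscored.
    """
    config = config or XpehhConfig()
    total = 0.0
    for curve in (curve_up, curve_down):
        if curve is None or curve.ehh.size < 2:
            continue
        for k in range(curve.ehh.size - 1):
            if curve.ehh[k + 1] < config.ehh_cutoff:
                break
            gap = curve.distance_bp[k + 1] - curve.distance_bp[k]
            total += min(gap, config.scale) * (curve.ehh[k] + curve.ehh[k + 1]) / 2.0
    return total


# ---------------------------------------------------------------------------
# fast whole-chromosome iES scan (pairwise next-mismatch formulation)
# ---------------------------------------------------------------------------

def _ies_chromosome(geno: np.ndarray, pos: np.ndarray,
                    config: XpehhConfig) -> np.ndarray:
    """iES at every site of one chromosome for one population.

    ``geno`` is the complete (sites x haplotypes) 0/1 matrix of the
    population.  Identity between two haplotypes over an interval is
    tracked through each pair's nearest mismatch on either side of the
    core, which makes EHH at distance x an order statistic of the pairwise
    next-mismatch positions; the whole-chromosome scan then costs one sort
    per site instead of one matrix pass per (site, distance).  Exactly
    equivalent to integrating :func:`ehh_curve` per core.
    """
    n_sites, n = geno.shape
    if n < config.min_haplotypes or n < 2:
        raise PanelError(f"need >= {max(config.min_haplotypes, 2)} haplotypes, have {n}")
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    mism = geno[:, iu] != geno[:, ju]  # (sites, pairs)

    idx = np.arange(n_sites, dtype=np.int32)[:, None]
    nxt_src = np.where(mism, idx, np.int32(n_sites))
    suffmin = np.minimum.accumulate(nxt_src[::-1], axis=0)[::-1]
    nxt = np.empty_like(nxt_src)
    nxt[:-1] = suffmin[1:]
    nxt[-1] = n_sites
    prv_src = np.where(mism, idx, np.int32(-1))
    prefmax = np.maximum.accumulate(prv_src, axis=0)
    prv = np.empty_like(prv_src)
    prv[1:] = prefmax[:-1]
    prv[0] = -1
    nxt_sorted = np.sort(nxt, axis=1)
    prv_sorted = np.sort(prv, axis=1)

    cutoff, scale = config.ehh_cutoff, config.scale
    # largest pair count still at/above cutoff: cnt_le <= cmax  <=>  EHH >= cutoff
    cmax = int(np.floor(n_pairs * (1.0 - cutoff) + 1e-12))
    # smallest identical-pair count at/above cutoff (upstream direction)
    mmin = int(np.ceil(n_pairs * cutoff - 1e-12))

    ies = np.zeros(n_sites)
    posf = pos.astype(np.float64)
    for c in range(n_sites):
        total = 0.0
        # downstream: pair identical through x  <=>  nxt[c] > x
        row = nxt_sorted[c]
        xlim = n_sites - 1 if cmax >= n_pairs else min(int(row[cmax]) - 1, n_sites - 1)
        if xlim > c:
            xs = np.arange(c + 1, xlim + 1)
            cnt = np.searchsorted(row, xs, side="right")
            ehh = np.empty(xs.size + 1)
            ehh[0] = 1.0
            ehh[1:] = (n_pairs - cnt) / n_pairs
            gaps = np.diff(posf[c:xlim + 1])
            total += float(np.minimum(gaps, scale) @ ((ehh[:-1] + ehh[1:]) / 2.0))
        # upstream: pair identical through x  <=>  prv[c] < x
        row = prv_sorted[c]
        xmin = 0 if mmin <= 0 else max(int(row[mmin - 1]) + 1, 0)
        if xmin < c:
            xs = np.arange(xmin, c)
            cnt = np.searchsorted(row, xs, side="left")
            ehh = np.empty(xs.size + 1)
            ehh[:-1] = cnt / n_pairs
            ehh[-1] = 1.0
            gaps = np.diff(posf[xmin:c + 1])
            total += float(np.minimum(gaps, scale) @ ((ehh[:-1] + ehh[1:]) / 2.0))
        ies[c] = total
    return ies


def xpehh_scan(panel: HaplotypePanel, pop_a: str, pop_b: str,
               config: XpehhConfig | None = None,
               normalize: bool = True) -> ScoreTrack:
    """Genome-wide XP-EHH between an ancestral and a derived panel.

    Raw score per site is ``ln iES_A - ln iES_B``; sites where either panel
    is unscored (iES = 0) are omitted.  With ``normalize=True`` (default)
    scores are standardized by the genome-wide mean and sd of the raw
    scores, stored on the track's ``normalization`` metadata; the raw
    scores are kept in the ``raw`` column.
    """
    config = config or XpehhConfig()
    cols_a = panel.pop_columns(pop_a)
    cols_b = panel.pop_columns(pop_b)
    if np.any(panel.alleles[:, np.concatenate([cols_a, cols_b])] == MISSING):
        raise PanelError("xpehh_scan requires complete data; use complete_data_subset")

    chroms, poss, raws = [], [], []
    n_unscored = 0
    for c in panel.chromosomes:
        on = panel.chrom == c
        geno_a = panel.alleles[on][:, cols_a]
        geno_b = panel.alleles[on][:, cols_b]
        pos_c = panel.pos[on]
        ies_a = _ies_chromosome(geno_a, pos_c, config)
        ies_b = _ies_chromosome(geno_b, pos_c, config)
        ok = (ies_a > 0) & (ies_b > 0)
        n_unscored += int((~ok).sum())
        raw = np.log(ies_a[ok]) - np.log(ies_b[ok])
        chroms.append(np.asarray(panel.chrom[on])[ok])
        poss.append(pos_c[ok])
        raws.append(raw)
    if n_unscored:
        logger.info("xpehh_scan: %d sites unscored (iES = 0)", n_unscored)
    raw = np.concatenate(raws) if raws else np.empty(0)
    df = pd.DataFrame({
        "chrom": np.concatenate(chroms) if chroms else np.empty(0, dtype=object),
        "pos": np.concatenate(poss) if poss else np.empty(0, dtype=np.int64),
        "raw": raw,
    })
    if not normalize:
        df["value"] = df["raw"]
        return ScoreTrack(df[["chrom", "pos", "value", "raw"]], statistic="XP-EHH")
    mean = float(raw.mean()) if raw.size else 0.0
    sd = float(raw.std(ddof=0)) if raw.size else 0.0
    if sd == 0.0:
        raise PanelError("degenerate score distribution (sd of raw XP-EHH is 0)")
    df["value"] = (df["raw"] - mean) / sd
    return ScoreTrack(df[["chrom", "pos", "value", "raw"]], statistic="XP-EHH",
                      normalization={"mean": mean, "sd": sd})
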