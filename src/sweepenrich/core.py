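"""Domain containers shared by the whole pipeline.

The substrate of every selection statistic is a haploid allele matrix over
inbred lines (one column per line, heterozygous calls resolved at read
time), together with a genetic map, gene annotation intervals, a table of
a-priori candidate SNP-trait associations, and per-SNP score tracks.

Coordinate conventions, stated once and used everywhere:

* VCF / SNP positions are 1-based base pairs.
* Windows and BED intervals are 0-based half-open; a SNP at VCF position
  ``p`` falls in the window starting at ``((p - 1) // size) * size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call in :class:`HaplotypePanel.alleles`.
MISSING: int = -1

#: Traits describing tassel length (higher in the modern ex-PVP lines,
#: except BZ).
LENGTH_TRAITS = ("TL", "TLp", "SL", "SLp", "BZ", "SP")

#: Traits describing the quantity and density of tassel branches (higher in
#: the ancestral BSSSC0 lines).
BRANCHINESS_TRAITS = ("BN", "BNp", "BD", "CP", "FD", "SK", "PR", "TW", "TWp")

#: The full 15-trait vocabulary.
ALL_TRAITS = LENGTH_TRAITS + BRANCHINESS_TRAITS

#: trait -> "length" | "branchiness"
TRAIT_CLASS: Mapping[str, str] = {
    **{t: "length" for t in LENGTH_TRAITS},
    **{t: "branchiness" for t in BRANCHINESS_TRAITS},
}


class PanelError(ValueError):
    """Raised when an input violates a panel invariant."""


@dataclass
class HaplotypePanel:
    """Sites x haplotypes allele matrix for one or more inbred panels.

    Parameters
    ----------
    chrom
        Chromosome id per site, shape ``(n_sites,)``.
    pos
        1-based physical position per site, strictly increasing within each
        chromosome.
    alleles
        ``int8`` matrix of shape ``(n_sites, n_samples)`` with values in
        ``{0, 1, MISSING}``.
    sample_ids
        Column labels, one per haplotype / inbred line.
    pop_labels
        Map from sample id to population name; every sample must be labeled.
    """

    chrom: np.ndarray
    pos: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str]
    pop_labels: dict[str, str]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise PanelError("alleles must be a 2-D sites x samples matrix")
        if self.alleles.shape != (self.pos.size, len(self.sample_ids)):
            raise PanelError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{self.pos.size} sites x {len(self.sample_ids)} samples"
            )
        bad = set(np.unique(self.alleles)) - {0, 1, MISSING}
        if bad:
            raise PanelError(f"allele values outside {{0,1,missing}}: {sorted(bad)}")
        missing_labels = [s for s in self.sample_ids if s not in self.pop_labels]
        if missing_labels:
            raise PanelError(f"samples without a population label: {missing_labels}")
        for c in self.chromosomes:
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise PanelError(f"positions not strictly increasing on chromosome {c}")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def chromosomes(self) -> list:
        """Chromosome ids in order of first appearance."""
        seen: dict = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    @property
    def populations(self) -> list[str]:
        seen: dict = {}
        for s in self.sample_ids:
            seen.setdefault(self.pop_labels[s], None)
        return list(seen)

    # -- selection ---------------------------------------------------------
    def pop_columns(self, pop: str) -> np.ndarray:
        """Column indices of the samples belonging to ``pop``."""
        idx = np.array(
            [i for i, s in enumerate(self.sample_ids) if self.pop_labels[s] == pop],
            dtype=np.intp,
        )
        if idx.size == 0:
            raise PanelError(f"population {pop!r} is empty or unknown")
        return idx

    def take_sites(self, mask_or_index: np.ndarray) -> "HaplotypePanel":
        """New panel restricted to the given site mask / index array."""
        return replace(
            self,
            chrom=self.chrom[mask_or_index],
            pos=self.pos[mask_or_index],
            alleles=self.alleles[mask_or_index],
        )

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos})


@dataclass
class GeneticMap:
    """Piecewise-linear physical-to-genetic map.

    ``anchors`` maps chromosome id to a ``(bp, cM)`` pair of 1-D arrays with
    ``bp`` strictly increasing and ``cM`` non-decreasing.  Interpolation is
    linear between anchors; beyond the terminal anchors the terminal
    interval's rate is extended, floored at 0 cM.
    """

    anchors: dict

    def __post_init__(self) -> None:
        clean: dict = {}
        for c, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=np.float64)
            cm = np.asarray(cm, dtype=np.float64)
            order = np.argsort(bp, kind="stable")
            bp, cm = bp[order], cm[order]
            # collapse duplicated bp anchors by mean cM
            if bp.size and np.any(np.diff(bp) == 0):
                df = pd.DataFrame({"bp": bp, "cm": cm}).groupby("bp", as_index=False).mean()
                bp, cm = df["bp"].to_numpy(), df["cm"].to_numpy()
            if bp.size < 2:
                raise PanelError(f"genetic map for chromosome {c} needs >= 2 anchors")
            drops = np.nonzero(np.diff(cm) < 0)[0]
            if drops.size:
                i = int(drops[0])
                raise PanelError(
                    f"cM decreasing on chromosome {c} at anchor bp={bp[i + 1]:.0f} "
                    f"({cm[i + 1]} cM after {cm[i]} cM)"
                )
            clean[c] = (bp, cm)
        self.anchors = clean

    def interpolate(self, chrom, pos) -> np.ndarray:
        """Genetic position (cM) at physical position(s) ``pos``."""
        if chrom not in self.anchors:
            raise PanelError(f"chromosome {chrom!r} absent from genetic map")
        bp, cm = self.anchors[chrom]
        pos = np.asarray(pos, dtype=np.float64)
        out = np.interp(pos, bp, cm)
        # linear extrapolation at the terminal rates, floored at 0 cM
        left_rate = (cm[1] - cm[0]) / (bp[1] - bp[0])
        right_rate = (cm[-1] - cm[-2]) / (bp[-1] - bp[-2])
        out = np.where(pos < bp[0], cm[0] + (pos - bp[0]) * left_rate, out)
        out = np.where(pos > bp[-1], cm[-1] + (pos - bp[-1]) * right_rate, out)
        return np.maximum(out, 0.0)


@dataclass
class IntervalSet:
    """0-based half-open genomic intervals (gene annotations)."""

    df: pd.DataFrame  # columns: chrom, start, end

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise PanelError(f"interval with start >= end: {tuple(bad)}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CandidateSet:
    """A-priori candidate SNP-trait associations.

    One record per association; the same SNP may appear under several traits
    and then contributes several entries to the observed score sample.
    """

    df: pd.DataFrame  # columns: chrom, pos, trait, source_population, trait_class

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        unknown = sorted(set(df["trait"]) - set(ALL_TRAITS))
        if unknown:
            raise PanelError(
                f"unknown trait(s) {unknown}; valid traits: {', '.join(ALL_TRAITS)}"
            )
        df["trait_class"] = df["trait"].map(TRAIT_CLASS)
        if "source_population" not in df.columns:
            df["source_population"] = ""
        df["pos"] = df["pos"].astype(np.int64)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class ScoreTrack:
    """Per-SNP values of one selection statistic.

    ``df`` has columns ``chrom, pos, value`` (plus optional extras such as
    ``raw`` for XP-EHH); at most one value per (chrom, pos).
    ``normalization`` records the genome-wide mean/sd used, when the
    statistic is reported on a normalized scale.
    """

    df: pd.DataFrame
    statistic: str
    normalization: dict | None = None

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True).copy()
        if len(df) and df.duplicated(["chrom", "pos"]).any():
            dup = df[df.duplicated(["chrom", "pos"])].iloc[0]
            raise PanelError(
                f"duplicate score for {self.statistic} at {dup['chrom']}:{dup['pos']}"
            )
        if len(df):
            df["pos"] = df["pos"].astype(np.int64)
            df["value"] = df["value"].astype(np.float64)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy()
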