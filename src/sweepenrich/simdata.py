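"""Synthetic two-population panels, genomes, and phenotypes.

The generator emulates the contrast the selection scan is built for: an
ancestral panel (default 41 lines, the BSSSC0-like group) and a smaller
derived panel (default 21 lines, the ex-PVP-like group) that share neutral
background variation.  Haplotypes are recombinant mosaics of a common set
of founder haplotypes; the derived panel drifts a fraction of its allele
copies toward derived-specific founder frequencies, and selective sweeps
are injected by replacing a carrier fraction ``f`` of derived haplotypes
with one fixed founder's segment inside the sweep region — which produces
exactly the two signals the statistics measure: extended haplotype
homozygosity and an allele-frequency shift, without forward-time
simulation.

Every generator is a pure function of (config, seed); the ancestral panel
is drawn from its own random stream, so its realization is identical in law
(and bit-identical at fixed seed) across sweep carrier fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GeneticMap, HaplotypePanel, IntervalSet, PanelError
from .windows import WINDOW_SIZE_DEFAULT, window_start


@dataclass
class SweepSpec:
    """One injected sweep in the derived population."""

    chrom: str
    center_bp: int
    width_bp: int = 200_000
    carrier_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.carrier_fraction <= 1.0:
            raise PanelError("carrier_fraction must be in [0, 1]")


@dataclass
class SweepSimConfig:
    """Study conditions for the two-population sweep simulation.

    Defaults mirror the sample-size regime of the selection contrast:
    41 ancestral vs 21 derived inbred lines on a 10 Mb chromosome with
    5,000 complete-data SNPs.  ``effective_meioses`` sets the accumulated
    recombination depth of the mosaic (generations of breeding history
    compressed into one draw), which controls the physical scale of
    haplotype sharing; ``drift`` is the fraction of derived allele copies
    redrawn toward derived-specific founder frequencies.
    """

    n_chrom: int = 1
    chrom_length_bp: int = 10_000_000
    n_sites: int = 5_000
    n_founders: int = 16
    n_a: int = 41
    n_b: int = 21
    sweeps: list = field(default_factory=list)
    drift: float = 0.10
    recomb_segments: tuple = (0.5, 1.5, 1.0)  # cM/Mb over equal thirds
    gene_density: float = 20.0                # genes per Mb
    gene_length_bp: float = 3_000.0           # mean gene length
    effective_meioses: float = 150.0
    pop_a: str = "ancestral"
    pop_b: str = "derived"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.chrom_length_bp <= 0:
            raise PanelError("chrom_length_bp must be positive")
        if self.n_sites < 2:
            raise PanelError("need at least 2 sites per chromosome")
        if self.n_founders < 2:
            raise PanelError("need at least 2 founder haplotypes")
        if any(r <= 0 for r in self.recomb_segments):
            raise PanelError("recombination rates must be positive")
        self.sweeps = [s if isinstance(s, SweepSpec) else SweepSpec(**s)
                       for s in self.sweeps]

    @property
    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chrom)]


# ---------------------------------------------------------------------------
# genome resources
# ---------------------------------------------------------------------------

def simulate_genome_resources(config: SweepSimConfig, seed=None):
    """Piecewise-linear genetic map and Poisson-placed gene intervals."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    length = config.chrom_length_bp
    rates = np.asarray(config.recomb_segments, dtype=float)
    bounds = np.linspace(0, length, rates.size + 1)
    seg_mb = np.diff(bounds) / 1e6
    cm = np.concatenate([[0.0], np.cumsum(rates * seg_mb)])

    anchors = {}
    records = []
    lam = config.gene_density * length / 1e6
    for c in config.chromosomes:
        anchors[c] = (bounds.copy(), cm.copy())
        n_genes = rng.poisson(lam)
        starts = np.sort(rng.integers(0, length, size=n_genes))
        lens = np.maximum(1, rng.exponential(config.gene_length_bp, size=n_genes)).astype(np.int64)
        ends = np.minimum(starts + lens, length)
        for s, e in zip(starts, ends):
            if e > s:
                records.append((c, int(s), int(e)))
    genes = IntervalSet(pd.DataFrame(records, columns=["chrom", "start", "end"])
                        if records else
                        pd.DataFrame(columns=["chrom", "start", "end"]))
    return GeneticMap(anchors), genes


# ---------------------------------------------------------------------------
# two-population sweep panel
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    swept_windows: list = field(default_factory=list)  # (chrom, window_start)
    causal_ids: list = field(default_factory=list)
    causal_effects: list = field(default_factory=list)
    variance_components: dict = field(default_factory=dict)


def _mosaic_panel(founders, pos, gmap, chrom, n_hap, depth, rng):
    """Draw n_hap recombinant founder mosaics over one chromosome."""
    n_founders, n_sites = founders.shape
    bp, cm = gmap.anchors[chrom]
    cm_total = cm[-1]
    lam = depth * cm_total / 100.0
    out = np.empty((n_sites, n_hap), dtype=np.int8)
    for h in range(n_hap):
        n_x = rng.poisson(lam)
        if n_x:
            cuts_cm = np.sort(rng.uniform(0.0, cm_total, size=n_x))
            cuts_bp = np.interp(cuts_cm, cm, bp)
            seg = np.searchsorted(cuts_bp, pos, side="right")
        else:
            seg = np.zeros(n_sites, dtype=np.intp)
        donors = rng.integers(0, n_founders, size=n_x + 1)
        out[:, h] = founders[donors[seg], np.arange(n_sites)]
    return out


def simulate_two_pop_sweep(config: SweepSimConfig, seed=None):
    """Simulate the ancestral/derived panel pair with injected sweeps.

    Returns ``(HaplotypePanel, SimTruth)``; the truth lists every 10 kb
    window overlapped by a sweep region.
    """
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    (ss_sites, ss_founders, ss_a, ss_b, ss_drift, ss_sweep, ss_genes) = root.spawn(7)
    rng_sites = np.random.default_rng(ss_sites)
    rng_founders = np.random.default_rng(ss_founders)
    rng_a = np.random.default_rng(ss_a)
    rng_b = np.random.default_rng(ss_b)
    rng_drift = np.random.default_rng(ss_drift)
    rng_sweep = np.random.default_rng(ss_sweep)

    gmap, _ = simulate_genome_resources(config, seed=np.random.default_rng(ss_genes))
    length = config.chrom_length_bp
    for s in config.sweeps:
        if not (1 <= s.center_bp <= length):
            raise PanelError(f"sweep center {s.center_bp} outside chromosome "
                             f"(length {length})")

    chroms_out, pos_out, blocks = [], [], []
    truth = SimTruth()
    for c in config.chromosomes:
        pos = np.unique(rng_sites.integers(1, length + 1, size=int(config.n_sites * 1.2)))
        while pos.size < config.n_sites:
            pos = np.unique(np.concatenate(
                [pos, rng_sites.integers(1, length + 1, size=config.n_sites)]))
        pos = np.sort(rng_sites.choice(pos, size=config.n_sites, replace=False))

        q = rng_founders.uniform(0.05, 0.95, size=config.n_sites)
        founders = (rng_founders.random((config.n_founders, config.n_sites))
                    < q).astype(np.int8)

        hap_a = _mosaic_panel(founders, pos, gmap, c, config.n_a,
                              config.effective_meioses, rng_a)
        hap_b = _mosaic_panel(founders, pos, gmap, c, config.n_b,
                              config.effective_meioses, rng_b)

        # drift: redraw a fraction of derived allele copies toward
        # derived-specific founder frequencies
        if config.drift > 0:
            w = rng_drift.dirichlet(np.ones(config.n_founders))
            q_b = w @ founders
            redraw = rng_drift.random((config.n_sites, config.n_b)) < config.drift
            fresh = (rng_drift.random((config.n_sites, config.n_b))
                     < q_b[:, None]).astype(np.int8)
            hap_b = np.where(redraw, fresh, hap_b)

        for s in config.sweeps:
            if s.chrom != c:
                continue
            lo, hi = s.center_bp - s.width_bp / 2, s.center_bp + s.width_bp / 2
            region = (pos >= lo) & (pos <= hi)
            donor = int(rng_sweep.integers(0, config.n_founders))
            n_carriers = int(round(s.carrier_fraction * config.n_b))
            carriers = rng_sweep.permutation(config.n_b)[:n_carriers]
            if region.any() and n_carriers:
                hap_b[np.ix_(region, carriers)] = founders[donor, region][:, None]
            w0 = int(window_start(max(int(lo), 1)))
            w1 = int(window_start(min(int(hi), length)))
            truth.swept_windows.extend(
                (c, w) for w in range(w0, w1 + 1, WINDOW_SIZE_DEFAULT))

        chroms_out.append(np.full(config.n_sites, c, dtype=object))
        pos_out.append(pos)
        blocks.append(np.hstack([hap_a, hap_b]))

    sample_ids = ([f"A{i + 1:03d}" for i in range(config.n_a)]
                  + [f"B{i + 1:03d}" for i in range(config.n_b)])
    pop_labels = {s: (config.pop_a if s.startswith("A") else config.pop_b)
                  for s in sample_ids}
    panel = HaplotypePanel(
        chrom=np.concatenate(chroms_out),
        pos=np.concatenate(pos_out),
        alleles=np.vstack(blocks),
        sample_ids=sample_ids,
        pop_labels=pop_labels,
    )
    return panel, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_rcbd_phenotypes(n_geno: int, n_env: int, n_block: int,
                             var_components, mu: float = 0.0,
                             seed=None) -> pd.DataFrame:
    """Balanced multi-environment RCBD phenotypes.

    ``var_components`` is ``(sigma_g2, sigma_env2, sigma_gxe2, sigma_block2,
    sigma_eps2)``; each effect is drawn normal with the stated variance and
    the model is y = mu + g + e + g:e + b(e) + eps.  One record per
    genotype x environment x block.
    """
    sg2, se2, sgxe2, sb2, seps2 = (float(v) for v in var_components)
    for name, v in (("sigma_g2", sg2), ("sigma_env2", se2), ("sigma_gxe2", sgxe2),
                    ("sigma_block2", sb2), ("sigma_eps2", seps2)):
        if v < 0:
            raise PanelError(f"negative variance component {name} = {v}")
    rng = np.random.default_rng(seed)
    g = rng.normal(0, math.sqrt(sg2), n_geno)
    e = rng.normal(0, math.sqrt(se2), n_env)
    gxe = rng.normal(0, math.sqrt(sgxe2), (n_geno, n_env))
    b = rng.normal(0, math.sqrt(sb2), (n_env, n_block))
    eps = rng.normal(0, math.sqrt(seps2), (n_geno, n_env, n_block))
    y = (mu + g[:, None, None] + e[None, :, None] + gxe[:, :, None]
         + b[None, :, :] + eps)
    gi, ei, bi = np.meshgrid(np.arange(n_geno), np.arange(n_env),
                             np.arange(n_block), indexing="ij")
    return pd.DataFrame({
        "genotype": gi.ravel(), "environment": ei.ravel(),
        "block": bi.ravel(), "value": y.ravel(),
    })


# ---------------------------------------------------------------------------
# mapping population
# ---------------------------------------------------------------------------

def simulate_mapping_population(n_lines: int, n_snps: int, causal_ids=(),
                                causal_effects=(), h2: float = 0.5,
                                switch_prob: float = 0.1, seed=None):
    """Biparental-style mapping population with local LD.

    Genotypes are 0/1 at 50/50 expected frequency with a first-order Markov
    copy process along the chromosome (``switch_prob`` per adjacent pair).
    The phenotype is the causal genetic value plus normal noise scaled so
    the realized broad-sense h2 matches the request; with no causal effects
    the phenotype is pure standard-normal noise.
    """
    causal_ids = np.asarray(causal_ids, dtype=int)
    causal_effects = np.asarray(causal_effects, dtype=float)
    if causal_ids.size != causal_effects.size:
        raise PanelError("causal_ids and causal_effects must have equal length")
    if causal_ids.size and causal_ids.max() >= n_snps:
        raise PanelError("causal id beyond n_snps")
    if not 0.0 < h2 < 1.0:
        raise PanelError("h2 must be in (0, 1)")
    rng = np.random.default_rng(seed)
    geno = np.empty((n_lines, n_snps), dtype=np.int8)
    geno[:, 0] = rng.integers(0, 2, size=n_lines)
    switch = rng.random((n_lines, n_snps)) < switch_prob
    fresh = rng.integers(0, 2, size=(n_lines, n_snps)).astype(np.int8)
    for j in range(1, n_snps):
        geno[:, j] = np.where(switch[:, j], fresh[:, j], geno[:, j - 1])

    if causal_ids.size:
        g = geno[:, causal_ids].astype(float) @ causal_effects
        var_g = float(np.var(g))
    else:
        g = np.zeros(n_lines)
        var_g = 0.0
    if var_g > 0:
        noise_sd = math.sqrt(var_g * (1.0 - h2) / h2)
    else:
        noise_sd = 1.0
    y = g + rng.normal(0.0, noise_sd, size=n_lines)
    truth = SimTruth(causal_ids=list(map(int, causal_ids)),
                     causal_effects=list(map(float, causal_effects)))
    return geno, y, truth
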