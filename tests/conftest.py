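"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import sweepenrich as se

POP_A, POP_B = "ancestral", "derived"


def make_panel(alleles, pos=None, chrom="1", pops=None):
    """Build a small panel from a (sites x haplotypes) matrix."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_sites, n_samples = alleles.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    chrom_arr = np.array([chrom] * n_sites, dtype=object) if np.isscalar(chrom) \
        else np.asarray(chrom, dtype=object)
    ids = [f"s{i}" for i in range(n_samples)]
    if pops is None:
        pops = {s: "pop" for s in ids}
    else:
        pops = dict(zip(ids, pops))
    return se.HaplotypePanel(chrom_arr, np.asarray(pos), alleles, ids, pops)


def study_config(sweeps=True, carrier_fraction=0.9):
    """The simulation at the study's sample-size regime (41 vs 21 lines,
    10 Mb, 5,000 SNPs, three sweeps)."""
    specs = []
    if sweeps:
        specs = [se.SweepSpec("1", c, 200_000, carrier_fraction)
                 for c in (2_000_000, 5_000_000, 8_000_000)]
    return se.SweepSimConfig(sweeps=specs)


def sweep_candidates(panel, truth, rng, n_assoc=40):
    """Candidate associations at SNPs inside swept windows, random traits."""
    swept = set(truth.swept_windows)
    ws = se.window_start(panel.pos)
    eligible = np.nonzero([
        (c, w) in swept for c, w in zip(panel.chrom, ws)
    ])[0]
    idx = rng.choice(eligible, size=n_assoc, replace=False)
    return se.CandidateSet(pd.DataFrame({
        "chrom": panel.chrom[idx],
        "pos": panel.pos[idx],
        "trait": rng.choice(se.ALL_TRAITS, size=n_assoc),
    }))


def random_candidates(panel, rng, n_assoc=40):
    idx = rng.choice(panel.n_sites, size=n_assoc, replace=False)
    return se.CandidateSet(pd.DataFrame({
        "chrom": panel.chrom[idx],
        "pos": panel.pos[idx],
        "trait": rng.choice(se.ALL_TRAITS, size=n_assoc),
    }))


@pytest.fixture(scope="session")
def study_run():
    """One full study-condition dataset: panel, truth, map, genes, tracks."""
    cfg = study_config()
    panel, truth = se.simulate_two_pop_sweep(cfg, seed=11)
    panel = se.complete_data_subset(panel, (POP_A, POP_B))
    gmap, genes = se.simulate_genome_resources(cfg, seed=11)
    fst = se.fst_weir_haploid(panel, POP_A, POP_B)
    xpehh = se.xpehh_scan(panel, POP_A, POP_B)
    return {
        "config": cfg, "panel": panel, "truth": truth,
        "gmap": gmap, "genes": genes, "fst": fst, "xpehh": xpehh,
    }


@pytest.fixture(scope="session")
def annotated_windows(study_run):
    """Annotated XP-EHH window table for the study run."""
    win = se.bin_max(study_run["xpehh"])
    return se.annotate_windows(win, study_run["gmap"], study_run["genes"],
                               study_run["panel"], POP_A, POP_B,
                               track=study_run["xpehh"])
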