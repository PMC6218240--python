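"""NAM-style mapping: stepwise selection, per-chromosome residuals, and
resampling model-inclusion probabilities (RMIP).

The procedure: (1) a permutation-derived entry threshold per trait (the
quantile of genome-wide minimum single-marker p-values under phenotype
permutation); (2) forward-backward stepwise selection, terms exiting at
twice the entry threshold; (3) residuals computed separately per
chromosome with that chromosome's model SNPs excluded; (4) resampling
GWAS — repeated forward regression (no exit) on random 80% subsamples of
the lines against the residuals, each SNP's RMIP being the fraction of
refits that included it; (5) a permutation-derived RMIP cutoff that caps
the expected number of false-positive SNPs.

All tests are ordinary least-squares partial F/t tests; ties in p-values
break toward the lowest SNP index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import PanelError
from .io import logger

_VAR_EPS = 1e-12


def _prepare(genotypes, phenotype):
    x = np.asarray(genotypes, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    if x.ndim != 2 or y.ndim != 1 or x.shape[0] != y.size:
        raise PanelError("genotypes must be (n_lines, n_snps) and phenotype (n_lines,)")
    return x, y


def _residualize(v, q):
    """Residual of columns of v against an orthonormal basis q."""
    return v - q @ (q.T @ v)


def _model_basis(x, model, n):
    cols = [np.ones((n, 1))]
    if model:
        cols.append(x[:, model])
    q, _ = np.linalg.qr(np.hstack(cols))
    return q


def _partial_pvalues(x_cand, y, q):
    """p-value of adding each candidate column to the model spanned by q.

    ``q`` is an orthonormal basis of the current design (intercept plus
    model SNPs).  Collinear candidates (no variance left after
    residualizing on the model) get p = 1.
    """
    n = y.size
    yr = _residualize(y[:, None], q).ravel()
    xr = _residualize(x_cand, q)
    ss_x = np.einsum("ij,ij->j", xr, xr)
    ss_y = float(yr @ yr)
    df = n - q.shape[1] - 1
    if df <= 0 or ss_y <= _VAR_EPS:
        return np.ones(x_cand.shape[1])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xr.T @ yr) / np.sqrt(ss_x * ss_y)
    r = np.where(ss_x <= _VAR_EPS, 0.0, np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore"):
        t2 = r * r * df / np.maximum(1.0 - r * r, _VAR_EPS)
    p = stats.f.sf(t2, 1, df)
    p[ss_x <= _VAR_EPS] = 1.0
    return p


def _add_pvalues(x, y, model, candidates):
    """p-values for adding each of ``candidates`` to ``model``."""
    q = _model_basis(x, model, y.size)
    return _partial_pvalues(x[:, candidates], y, q)


def _term_pvalues(x, y, model):
    """Drop-one p-value of every term currently in the model."""
    return np.array([
        _partial_pvalues(x[:, [j]], y,
                         _model_basis(x, [m for m in model if m != j], y.size))[0]
        for j in model
    ])


# ---------------------------------------------------------------------------
# entry threshold
# ---------------------------------------------------------------------------

def permutation_entry_threshold(genotypes, phenotype, n_perm: int,
                                quantile: float = 0.05, seed=None) -> float:
    """Entry threshold: quantile of permutation minimum p-values.

    For each phenotype permutation the genome-wide minimum single-marker
    regression p-value is recorded; the threshold is the requested
    quantile of those minima.
    """
    x, y = _prepare(genotypes, phenotype)
    if n_perm < 20:
        raise PanelError(f"n_perm must be >= 20, got {n_perm}")
    if np.var(y) <= _VAR_EPS:
        raise PanelError("constant phenotype")
    rng = np.random.default_rng(seed)
    n, m = x.shape
    xc = x - x.mean(axis=0)
    sx = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    ok = sx > _VAR_EPS
    xn = np.where(ok, xc / np.where(ok, sx, 1.0), 0.0)
    perms = np.array([rng.permutation(y) for _ in range(n_perm)]).T  # (n, n_perm)
    pc = perms - perms.mean(axis=0)
    pn = pc / np.sqrt(np.einsum("ij,ij->j", pc, pc))
    r_max = np.abs(xn.T @ pn).max(axis=0)
    r_max = np.clip(r_max, 0.0, 1.0)
    df = n - 2
    t2 = r_max**2 * df / np.maximum(1.0 - r_max**2, _VAR_EPS)
    minima = stats.f.sf(t2, 1, df)
    return float(np.quantile(minima, quantile))


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def stepwise_select(genotypes, phenotype, alpha_entry: float,
                    max_terms: int = 50) -> list[int]:
    """Forward-backward stepwise SNP selection.

    Forward: add the SNP with the smallest partial p if p < ``alpha_entry``.
    Backward: after each addition any model term with drop-one p above
    twice the entry threshold exits.  Iterates to a fixed point.
    """
    x, y = _prepare(genotypes, phenotype)
    if not 0.0 < alpha_entry < 1.0:
        raise PanelError("alpha_entry must be in (0, 1)")
    alpha_exit = 2.0 * alpha_entry
    model: list[int] = []
    changed = True
    while changed and len(model) < max_terms:
        changed = False
        candidates = [j for j in range(x.shape[1]) if j not in model]
        if candidates:
            p = _add_pvalues(x, y, model, candidates)
            best = int(np.argmin(p))  # argmin breaks ties at lowest index
            if p[best] < alpha_entry:
                model.append(candidates[best])
                changed = True
        # backward passes, one removal at a time
        while model:
            term_p = _term_pvalues(x, y, model)
            worst = int(np.argmax(term_p))
            if term_p[worst] > alpha_exit:
                model.pop(worst)
                changed = True
            else:
                break
    return model


def chromosome_residuals(genotypes, phenotype, model, chrom_of_snp, chrom):
    """Phenotype residuals with the focal chromosome's model SNPs excluded."""
    x, y = _prepare(genotypes, phenotype)
    chrom_of_snp = np.asarray(chrom_of_snp)
    keep = [j for j in model if chrom_of_snp[j] != chrom]
    q = _model_basis(x, keep, y.size)
    return _residualize(y[:, None], q).ravel()


# ---------------------------------------------------------------------------
# resampling GWAS
# ---------------------------------------------------------------------------

def forward_select(genotypes, phenotype, alpha: float,
                   max_terms: int = 50) -> list[int]:
    """Forward regression with entry p < alpha and no exit step."""
    x, y = _prepare(genotypes, phenotype)
    model: list[int] = []
    while len(model) < max_terms:
        candidates = [j for j in range(x.shape[1]) if j not in model]
        if not candidates:
            break
        p = _add_pvalues(x, y, model, candidates)
        best = int(np.argmin(p))
        if p[best] < alpha:
            model.append(candidates[best])
        else:
            break
    return model


@dataclass
class RmipResult:
    """Per-SNP resampling inclusion counts and probabilities."""

    counts: np.ndarray
    n_reps: int
    alpha: float
    subsample: float

    @property
    def rmip(self) -> np.ndarray:
        return self.counts / self.n_reps

    def significant(self, threshold: float) -> np.ndarray:
        return np.nonzero(self.rmip >= threshold)[0]


def resampling_rmip(genotypes, residuals, n_reps: int = 100,
                    subsample: float = 0.8, alpha: float = 1e-4,
                    seed=None) -> RmipResult:
    """RMIP by repeated forward regression on random line subsamples.

    Per repetition ``floor(subsample * n)`` lines are drawn without
    replacement and forward regression (entry p < ``alpha``, no exit) is
    run; each SNP's RMIP is its inclusion count over ``n_reps``.
    """
    x, y = _prepare(genotypes, residuals)
    if not 0.0 < subsample < 1.0:
        raise PanelError("subsample must be in (0, 1)")
    n = y.size
    k = int(subsample * n)
    if k < 10:
        raise PanelError(f"subsample leaves only {k} lines (< 10)")
    rng = np.random.default_rng(seed)
    counts = np.zeros(x.shape[1], dtype=np.int64)
    for _ in range(n_reps):
        idx = rng.permutation(n)[:k]
        model = forward_select(x[idx], y[idx], alpha)
        counts[model] += 1
    return RmipResult(counts=counts, n_reps=n_reps, alpha=alpha, subsample=subsample)


def rmip_threshold(genotypes, phenotype, chrom_of_snp=None, n_perm: int = 5,
                   target_fp: int = 5, alpha_entry: float = 1e-4,
                   n_reps: int = 100, subsample: float = 0.8,
                   alpha: float = 1e-4, seed=None,
                   per_perm_budget: float | None = None) -> float:
    """Permutation-derived RMIP significance cutoff.

    The full residual + resampling procedure is run on permuted phenotypes;
    the returned cutoff is the smallest value in {0.01, ..., 1.00} whose
    mean number of passing SNPs per permutation (genome-wide) stays within
    the false-positive budget (default ``target_fp / n_perm``).
    """
    x, y = _prepare(genotypes, phenotype)
    if n_perm < 1:
        raise PanelError("n_perm must be >= 1")
    if chrom_of_snp is None:
        chrom_of_snp = np.zeros(x.shape[1], dtype=int)
    chrom_of_snp = np.asarray(chrom_of_snp)
    budget = target_fp / n_perm if per_perm_budget is None else per_perm_budget
    rng = np.random.default_rng(seed)
    grid = np.round(np.arange(0.01, 1.01, 0.01), 2)
    pass_counts = np.zeros((n_perm, grid.size))
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        model = stepwise_select(x, y_perm, alpha_entry)
        for c in np.unique(chrom_of_snp):
            resid = chromosome_residuals(x, y_perm, model, chrom_of_snp, c)
            on = chrom_of_snp == c
            res = resampling_rmip(x[:, on], resid, n_reps=n_reps,
                                  subsample=subsample, alpha=alpha, seed=rng)
            pass_counts[i] += (res.rmip[:, None] >= grid[None, :]).sum(axis=0)
    mean_fp = pass_counts.mean(axis=0)
    ok = np.nonzero(mean_fp <= budget)[0]
    if ok.size == 0:
        logger.warning("rmip_threshold: no cutoff meets the budget; returning 1.0")
        return 1.0
    return float(grid[ok[0]])
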