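"""Phenotype algebra: derived traits, balanced-design variance components,
entry-mean heritability, repeatability, and balanced BLUE/BLUP summaries.

The phenotypic model is the balanced multi-environment RCBD

    y = mu + g + e + g:e + b(e) + eps

with all effects random.  Variance components come from the method-of-
moments solution of the expected mean squares (negative estimates truncate
to zero, flagged); heritability on an entry-mean basis is

    h2 = sigma_g2 / (sigma_g2 + sigma_gxe2 / e + sigma_eps2 / (b * e))

and repeatability (single-environment traits, e = 1) is

    r = sigma_g2 / (sigma_g2 + sigma_eps2 / b).

In the balanced design the genotype BLUE is the genotype mean and the
BLUP is the entry-mean-h2-shrunken centered mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PanelError
from .io import logger

#: Traits square-root transformed before analysis to stabilize residuals.
SQRT_TRANSFORM_TRAITS = ("BN", "BD", "PR", "SK", "TW")


def derived_traits(tl, sl, bn):
    """Derived tassel traits from the three manual measurements.

    BZ (branch zone) = TL - SL; BD (branch density) = BN / BZ;
    SP (spike proportion) = SL / TL.  BD is undefined (NaN, logged) where
    the branch zone is zero.
    """
    tl = np.asarray(tl, dtype=float)
    sl = np.asarray(sl, dtype=float)
    bn = np.asarray(bn, dtype=float)
    if np.any(sl > tl) or np.any(sl <= 0):
        raise PanelError("requires TL >= SL > 0")
    bz = tl - sl
    with np.errstate(divide="ignore", invalid="ignore"):
        bd = np.where(bz > 0, bn / np.where(bz > 0, bz, 1.0), np.nan)
        bd = np.where((bz == 0) & (bn == 0), 0.0, bd)
    n_undef = int(np.isnan(bd).sum())
    if n_undef:
        logger.info("derived_traits: BD undefined for %d records (BZ = 0, BN > 0)",
                    n_undef)
    sp = sl / tl
    return bz, bd, sp


def sqrt_transform(table: pd.DataFrame, traits=SQRT_TRANSFORM_TRAITS,
                   trait_col: str = "trait",
                   value_col: str = "value") -> pd.DataFrame:
    """Square-root transform the listed traits' values (never back-transformed)."""
    out = table.copy()
    mask = out[trait_col].isin(traits)
    if (out.loc[mask, value_col] < 0).any():
        raise PanelError("cannot sqrt-transform negative values")
    out.loc[mask, value_col] = np.sqrt(out.loc[mask, value_col])
    return out


@dataclass
class VarianceComponents:
    """Method-of-moments variance components of the balanced RCBD model."""

    sigma_g2: float
    sigma_gxe2: float
    sigma_eps2: float
    n_blocks: int
    n_envs: int
    truncated: bool = False  # any negative estimate was floored at 0


def anova_variance_components(table: pd.DataFrame) -> VarianceComponents:
    """Estimate (sigma_g2, sigma_gxe2, sigma_eps2) from a balanced table.

    Expects columns ``genotype, environment, block, value`` with every
    genotype observed once in every environment x block.  With a single
    environment the interaction is not estimable and is fixed at 0 (the
    repeatability design).
    """
    required = {"genotype", "environment", "block", "value"}
    if not required <= set(table.columns):
        raise PanelError(f"phenotype table needs columns {sorted(required)}")
    counts = table.groupby(["genotype", "environment", "block"]).size()
    g = table["genotype"].nunique()
    e = table["environment"].nunique()
    b = table["block"].nunique()
    if len(counts) != g * e * b or (counts != 1).any():
        raise PanelError(
            "unbalanced phenotype table: every genotype must appear exactly once "
            "in every environment x block (REML for unbalanced data is out of scope)"
        )
    y = table["value"].to_numpy()
    grand = y.mean()
    gm = table.groupby("genotype")["value"].mean()
    ss_g = e * b * float(((gm - grand) ** 2).sum())

    if e > 1:
        gem = table.groupby(["genotype", "environment"])["value"].mean()
        em = table.groupby("environment")["value"].mean()
        dev = gem - gm.reindex(gem.index.get_level_values(0)).to_numpy() \
            - em.reindex(gem.index.get_level_values(1)).to_numpy() + grand
        ss_gxe = b * float((dev**2).sum())
        ms_gxe = ss_gxe / ((g - 1) * (e - 1))
    else:
        ms_gxe = None

    # error SS by subtraction from the total
    ss_total = float(((y - grand) ** 2).sum())
    em_all = table.groupby("environment")["value"].mean()
    ss_e = g * b * float(((em_all - grand) ** 2).sum())
    bem = table.groupby(["environment", "block"])["value"].mean()
    ss_b = g * float(((bem - em_all.reindex(bem.index.get_level_values(0)).to_numpy())
                      ** 2).sum())
    ss_gxe_val = 0.0 if e == 1 else ss_gxe
    ss_err = ss_total - ss_g - ss_e - ss_b - ss_gxe_val
    df_err = (g - 1) * (b - 1) * e
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    ms_g = ss_g / (g - 1)

    truncated = False
    sigma_eps2 = max(ms_err, 0.0)
    if e > 1:
        sigma_gxe2 = (ms_gxe - ms_err) / b
        sigma_g2 = (ms_g - ms_gxe) / (b * e)
    else:
        sigma_gxe2 = 0.0
        sigma_g2 = (ms_g - ms_err) / b
    if sigma_gxe2 < 0:
        sigma_gxe2, truncated = 0.0, True
    if sigma_g2 < 0:
        sigma_g2, truncated = 0.0, True
    return VarianceComponents(sigma_g2=float(sigma_g2), sigma_gxe2=float(sigma_gxe2),
                              sigma_eps2=float(sigma_eps2), n_blocks=b, n_envs=e,
                              truncated=truncated)


def heritability(vc: VarianceComponents) -> float:
    """Entry-mean heritability; NaN when all components are zero."""
    denom = vc.sigma_g2 + vc.sigma_gxe2 / vc.n_envs \
        + vc.sigma_eps2 / (vc.n_blocks * vc.n_envs)
    if denom == 0:
        return math.nan
    return vc.sigma_g2 / denom


def repeatability(vc: VarianceComponents) -> float:
    """Entry-mean repeatability (single-environment form); NaN if degenerate."""
    denom = vc.sigma_g2 + vc.sigma_eps2 / vc.n_blocks
    if denom == 0:
        return math.nan
    return vc.sigma_g2 / denom


def balanced_blup_blue(table: pd.DataFrame,
                       vc: VarianceComponents | None = None) -> pd.DataFrame:
    """Per-genotype BLUE and BLUP under the balanced design.

    BLUE is the genotype mean; BLUP shrinks the centered mean by the
    entry-mean heritability: ``BLUP = h2 * (mean - grand_mean)``.
    """
    vc = vc or anova_variance_components(table)
    h2 = heritability(vc)
    gm = table.groupby("genotype")["value"].mean()
    grand = table["value"].mean()
    shrink = 0.0 if math.isnan(h2) else h2
    return pd.DataFrame({
        "genotype": gm.index,
        "blue": gm.to_numpy(),
        "blup": shrink * (gm.to_numpy() - grand),
    })
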