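"""Cross-platform adequacy assessment.

Each platform's per-gene sensitivity to tumor biology is summarized by a
3-d.f. moderated F statistic for equal mean expression across the four
ER/PR receptor groups (reference -/-; dummies for +/-, -/+, +/+):

    y_ig = a_g + x_i' b_g + e_ig

The agreement of the two platforms' F vectors over shared gene identifiers
(Spearman rank correlation) measures whether a degraded-RNA platform (e.g.
FFPE arrays) preserves the biological ranking established by a fresh-frozen
platform.  Per-platform sample sizes, and hence denominator degrees of
freedom, may differ freely.
"""

from __future__ import annotations

import pandas as pd

from . import statcore

__all__ = ["receptor_design", "receptor_f_stats", "cross_platform_concordance"]

GROUP_LEVELS = ("+-", "-+", "++")  # dummies against reference "--"


def receptor_design(samples: pd.DataFrame, strict: bool = False) -> pd.DataFrame:
    """Intercept + 3 receptor-group dummies from ER/PR status columns.

    Samples missing ER or PR are excluded.  With ``strict`` an empty group
    raises; otherwise the aliased dummy is dropped downstream with a warning.
    """
    ok = samples["er"].isin(["+", "-"]) & samples["pr"].isin(["+", "-"])
    sub = samples.loc[ok]
    group = sub["er"].astype(str) + sub["pr"].astype(str)
    design = pd.DataFrame({"intercept": 1.0}, index=sub.index)
    for lvl in GROUP_LEVELS:
        design[f"group_{lvl}"] = (group == lvl).astype(float)
    empty = [lvl for lvl in GROUP_LEVELS + ("--",) if (group == lvl).sum() == 0]
    if empty and strict:
        raise ValueError(f"empty receptor groups: {empty}")
    return design


def receptor_f_stats(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    prior_policy: str = "eb",
    strict: bool = False,
) -> pd.DataFrame:
    """Per-gene moderated F (3 d.f.) for receptor-group mean differences.

    ``prior_policy='eb'`` estimates the empirical-Bayes variance prior from
    the fit set; ``'none'`` uses the classical F (no shrinkage, d0=0 limit).
    Returns a frame (F, p, df_num, df_den) indexed by gene.
    """
    design = receptor_design(samples, strict=strict)
    design, dropped = statcore.drop_aliased(design, keep=("intercept",))
    group_cols = [c for c in design.columns if c.startswith("group_")]
    if dropped:
        import logging

        logging.getLogger(__name__).warning(
            "receptor design: dropped empty/aliased groups %s; %d-d.f. test", dropped, len(group_cols)
        )
    fits = statcore.ols_fit(expr[design.index], design)
    if prior_policy == "eb":
        prior = statcore.estimate_variance_prior(fits.sigma2, fits.df_resid)
    elif prior_policy == "none":
        prior = statcore.VariancePrior(d0=0.0, s02=1.0)  # classical F, no shrinkage
    else:
        raise ValueError("prior_policy must be 'eb' or 'none'")
    return statcore.moderated_f(fits, prior, group_cols)


def cross_platform_concordance(f1: pd.Series, f2: pd.Series) -> tuple[float, int]:
    """Spearman correlation of two per-gene F vectors over shared ids.

    Identifier matching is exact and case-sensitive.  Returns (rho, n shared).
    """
    shared = f1.index.intersection(f2.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared gene identifiers; need >= 3")
    rho = statcore.spearman_corr(f1.loc[shared].to_numpy(), f2.loc[shared].to_numpy())
    return rho, len(shared)
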