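"""Per-SNP, per-gene eQTL scans in tissue strata, the paired tumor/normal
interaction scan, and cis/trans annotation.

For each SNP s and gene g within a stratum the model is

    y_ig = b0 + X_i' b1 + b2 * D_is + e_ig

with X_i the adjustment covariates (age at diagnosis, year of diagnosis,
assay-plate dummies, optional expression-PC scores) and D_is the allelic
dosage in [0, 2].  All genes for a SNP are fit against the one shared
design, an empirical-Bayes variance prior is estimated from that fit set,
the dosage coefficient is tested with a moderated t, and Benjamini-Hochberg
adjustment is applied within the SNP's gene list — FDR is controlled per
SNP, per tissue type.

The paired scan restricts to subjects contributing both a tumor and an
adjacent-normal specimen, adds subject fixed effects, a tissue indicator,
and the tissue x dosage product, and tests the product coefficient.
Between-subject covariates (dosage main effect, age, year) are absorbed by
the subject dummies and automatically dropped as aliased.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import statcore
from .synthetic_data import StudyBundle

log = logging.getLogger(__name__)

__all__ = ["STRATA", "select_stratum", "build_design", "scan", "paired_interaction_scan", "annotate_cis_trans"]

STRATA = ("er_pos", "er_neg", "normal", "tumor")

RECORD_COLUMNS = [
    "snp",
    "gene",
    "stratum",
    "beta",
    "t",
    "p",
    "q",
    "n",
]


def select_stratum(samples: pd.DataFrame, stratum: str) -> pd.Index:
    """Sample ids belonging to a stratum.

    ``er_pos`` / ``er_neg`` are tumor samples with the given ER status
    (ER-missing samples are excluded from ER strata); ``normal`` is all
    adjacent-normal samples; ``tumor`` is all tumor samples regardless of ER.
    """
    if stratum == "er_pos":
        mask = (samples["tissue"] == "tumor") & (samples["er"] == "+")
    elif stratum == "er_neg":
        mask = (samples["tissue"] == "tumor") & (samples["er"] == "-")
    elif stratum == "normal":
        mask = samples["tissue"] == "normal"
    elif stratum == "tumor":
        mask = samples["tissue"] == "tumor"
    else:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    return samples.index[mask]


def build_design(
    samples: pd.DataFrame,
    covariates: tuple[str, ...] = ("age_dx", "year_dx", "plate"),
    pc_scores: pd.DataFrame | None = None,
    plate_dummies: bool = True,
) -> pd.DataFrame:
    """Adjustment design: intercept, age, year, plate dummies, PC scores.

    ``plate_dummies=False`` enters the plate label as a single numeric code
    instead of indicator columns.
    """
    parts = {"intercept": pd.Series(1.0, index=samples.index)}
    for cov in covariates:
        if cov == "plate":
            if plate_dummies:
                dummies = pd.get_dummies(samples["plate"], prefix="plate", drop_first=True)
                for c in dummies.columns:
                    parts[c] = dummies[c].astype(float)
            else:
                parts["plate"] = samples["plate"].astype("category").cat.codes.astype(float)
        else:
            parts[cov] = samples[cov].astype(float)
    design = pd.DataFrame(parts, index=samples.index)
    if pc_scores is not None and pc_scores.shape[1]:
        design = design.join(pc_scores.loc[samples.index])
    return design


def _scan_one_snp(expr, design_base, dose, snp, stratum, n):
    """Fit all genes for one SNP; returns a records frame or None if skipped."""
    design = design_base.copy()
    design["dosage"] = dose
    design, dropped = statcore.drop_aliased(design, keep=("intercept", "dosage"))
    if "dosage" in dropped:
        log.warning("SNP %s: dosage aliased with covariates in %s; skipped", snp, stratum)
        return None
    if dropped:
        log.info("SNP %s: dropped aliased covariates %s", snp, dropped)
    fits = statcore.ols_fit(expr, design)
    prior = statcore.estimate_variance_prior(fits.sigma2, fits.df_resid)
    tt = statcore.moderated_t(fits, prior, "dosage")
    return pd.DataFrame(
        {
            "snp": snp,
            "gene": expr.index,
            "stratum": stratum,
            "beta": fits.coef["dosage"].to_numpy(),
            "t": tt["t"].to_numpy(),
            "p": tt["p"].to_numpy(),
            "q": statcore.bh_adjust(tt["p"].to_numpy()),
            "n": n,
        }
    )


def scan(
    bundle: StudyBundle,
    stratum: str,
    covariates: tuple[str, ...] = ("age_dx", "year_dx", "plate"),
    pc_scores: pd.DataFrame | None = None,
    snps: list[str] | None = None,
    plate_dummies: bool = True,
) -> pd.DataFrame:
    """Per-SNP moderated-t eQTL scan within one tissue stratum.

    Returns one row per (SNP, gene) with effect, t, p and the per-SNP BH q.
    Monomorphic SNPs within the stratum are skipped and logged.
    """
    ids = select_stratum(bundle.samples, stratum)
    if len(ids) == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    expr = bundle.expression[ids]
    design_base = build_design(
        bundle.samples.loc[ids], covariates, pc_scores=pc_scores, plate_dummies=plate_dummies
    )
    if len(ids) < design_base.shape[1] + 2:
        raise ValueError(f"insufficient samples in stratum {stratum!r}: n={len(ids)}")
    records = []
    n_skipped = 0
    for snp in snps if snps is not None else bundle.dosage.index:
        dose = bundle.dosage.loc[snp, ids].to_numpy(dtype=float)
        if np.var(dose) == 0:
            n_skipped += 1
            log.info("SNP %s monomorphic in stratum %s; skipped", snp, stratum)
            continue
        rec = _scan_one_snp(expr, design_base, dose, snp, stratum, len(ids))
        if rec is not None:
            records.append(rec)
    if n_skipped:
        log.warning("%d monomorphic SNPs skipped in stratum %s", n_skipped, stratum)
    if not records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(records, ignore_index=True)


def paired_interaction_scan(
    bundle: StudyBundle,
    covariates: tuple[str, ...] = ("age_dx", "year_dx", "plate"),
    snps: list[str] | None = None,
) -> pd.DataFrame:
    """Tumor-vs-normal interaction scan on complete pairs.

    The design holds subject fixed effects, a tissue indicator (tumor=1),
    any within-subject covariates that survive aliasing, and the
    tissue x dosage product; the product coefficient is tested with a
    moderated t and BH-adjusted per SNP.  Stratum label:
    ``tumor_normal_interaction``.
    """
    samples = bundle.samples
    counts = samples.groupby("subject")["tissue"].nunique()
    paired_subjects = counts.index[counts == 2]
    ids = samples.index[samples["subject"].isin(paired_subjects)]
    if len(paired_subjects) < 2:
        raise ValueError("need at least 2 complete tumor/normal pairs")
    sub = samples.loc[ids]
    n_excl = len(samples) - len(ids)
    if n_excl:
        log.info("paired scan: excluded %d unpaired samples", n_excl)

    expr = bundle.expression[ids]
    design_base = pd.DataFrame({"intercept": pd.Series(1.0, index=ids)})
    subj_dummies = pd.get_dummies(sub["subject"], prefix="subj", drop_first=True).astype(float)
    design_base = design_base.join(subj_dummies)
    for cov in covariates:
        if cov == "plate":
            dummies = pd.get_dummies(sub["plate"], prefix="plate", drop_first=True)
            design_base = design_base.join(dummies.astype(float))
        else:
            design_base[cov] = sub[cov].astype(float)
    tissue = (sub["tissue"] == "tumor").astype(float)
    design_base["tissue"] = tissue

    records = []
    for snp in snps if snps is not None else bundle.dosage.index:
        dose = bundle.dosage.loc[snp, ids].to_numpy(dtype=float)
        design = design_base.copy()
        design["dosage"] = dose
        design["tissue_x_dosage"] = tissue.to_numpy() * dose
        design, dropped = statcore.drop_aliased(
            design, keep=("intercept", "tissue", "tissue_x_dosage")
        )
        if "tissue_x_dosage" in dropped or np.var(dose) == 0:
            log.info("SNP %s: interaction not estimable; skipped", snp)
            continue
        if dropped:
            log.info("SNP %s paired design: dropped aliased columns %s", snp, dropped)
        fits = statcore.ols_fit(expr, design)
        prior = statcore.estimate_variance_prior(fits.sigma2, fits.df_resid)
        tt = statcore.moderated_t(fits, prior, "tissue_x_dosage")
        records.append(
            pd.DataFrame(
                {
                    "snp": snp,
                    "gene": expr.index,
                    "stratum": "tumor_normal_interaction",
                    "beta": fits.coef["tissue_x_dosage"].to_numpy(),
                    "t": tt["t"].to_numpy(),
                    "p": tt["p"].to_numpy(),
                    "q": statcore.bh_adjust(tt["p"].to_numpy()),
                    "n": len(ids),
                }
            )
        )
    if not records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    return pd.concat(records, ignore_index=True)


def annotate_cis_trans(
    records: pd.DataFrame,
    snp_coords: pd.DataFrame,
    gene_coords: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Label each record cis or trans.

    cis iff SNP and gene share a chromosome and the distance from the SNP to
    the nearest gene boundary is <= window (0 inside the gene body); records
    with missing coordinates are labelled ``unknown`` and logged.
    """
    out = records.copy()
    labels = []
    sc = snp_coords
    gc = gene_coords
    for snp, gene in zip(out["snp"], out["gene"]):
        if snp not in sc.index or gene not in gc.index:
            log.warning("missing coordinates for %s or %s", snp, gene)
            labels.append("unknown")
            continue
        s = sc.loc[snp]
        g = gc.loc[gene]
        if s["chrom"] != g["chrom"]:
            labels.append("trans")
            continue
        pos = s["pos"]
        if g["start"] <= pos <= g["end"]:
            dist = 0
        else:
            dist = min(abs(pos - g["start"]), abs(pos - g["end"]))
        labels.append("cis" if dist <= window else "trans")
    out["label"] = labels
    out["snp_chrom"] = [sc.loc[s, "chrom"] if s in sc.index else None for s in out["snp"]]
    out["snp_pos"] = [sc.loc[s, "pos"] if s in sc.index else np.nan for s in out["snp"]]
    out["gene_chrom"] = [gc.loc[g, "chrom"] if g in gc.index else None for g in out["gene"]]
    out["gene_start"] = [gc.loc[g, "start"] if g in gc.index else np.nan for g in out["gene"]]
    return out
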