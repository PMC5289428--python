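"""Gene-set QTL ("fQTL") scanning: per-gene Z-scoring, stacked
repeated-measures regression per (SNP, gene set), and genotype-permutation
FDR.

Each gene is standardized to mean 0, SD 1 across samples.  For a gene set
with m member genes, the m z-profiles are stacked into one response vector
of length m*n and regressed on

    z_jk = b0 + b1 * YrDx_k + b2 * AgeDx_k + b3 * Dosage_k + e_jk

with the covariates repeated for every gene; b3 is the change in the mean
set-level z-score per copy of the minor allele.  The model treats member
genes as repeated measures on one process and assumes they share a common
residual variance; the t statistic for b3 has (m*n - 4) residual df.

FDR is estimated by permuting the sample-to-genotype assignment: one shared
permutation of the sample labels per round is applied to the whole dosage
matrix, preserving the correlation structure within the expression data and
among the SNPs, and all (SNP, set) statistics are recomputed.  The FDR at an
observed |t| is the mean number of permutation statistics at or above it
divided by the number of observed statistics at or above it, capped at 1 and
made monotone.

Because the stacked design is the small per-sample design tiled m times,
the stacked OLS collapses algebraically: the coefficients equal the OLS of
the per-set mean z-profile on the small design, and the pooled residual sum
of squares follows from per-set sufficient statistics.  The scan and the
permutation loop use this collapsed form; ``fqtl_fit`` is the direct
stacked fit and the two agree to machine precision.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import StudyBundle
from .eqtl import select_stratum

log = logging.getLogger(__name__)

__all__ = [
    "zscore_standardize",
    "fqtl_fit",
    "fqtl_scan",
    "permutation_fdr",
]

MIN_SET_SIZE = 5


def zscore_standardize(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene (row) to mean 0, sample SD 1 (n-1 denominator).

    Constant genes cannot be standardized; they are dropped with a warning.
    """
    mean = expr.mean(axis=1)
    sd = expr.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        log.warning("dropping %d constant genes from z-scoring", int(constant.sum()))
    keep = expr.index[~constant]
    return expr.loc[keep].sub(mean[keep], axis=0).div(sd[keep], axis=0)


def _small_design(year, age, dosage) -> np.ndarray:
    n = len(dosage)
    return np.column_stack([np.ones(n), np.asarray(year, float), np.asarray(age, float), np.asarray(dosage, float)])


def fqtl_fit(z: pd.DataFrame, genes: list[str], dosage, year, age):
    """Direct stacked OLS for one gene set.  Returns (beta3, t, p, df).

    The response is the member genes' z-rows stacked end to end; the
    intercept, year, age, and dosage columns are tiled to match.
    """
    genes = [g for g in genes if g in z.index]
    m = len(genes)
    if m == 0:
        raise ValueError("no resolvable genes in set")
    dosage = np.asarray(dosage, dtype=float)
    if np.var(dosage) == 0:
        raise ValueError("monomorphic dosage")
    Xs = _small_design(year, age, dosage)
    n, p = Xs.shape
    X = np.tile(Xs, (m, 1))
    y = z.loc[genes].to_numpy(dtype=float).reshape(-1)
    coef, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("stacked design is rank deficient")
    df = m * n - p
    resid = y - X @ coef
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[p - 1, p - 1])
    t = float(coef[p - 1] / se)
    pval = float(2.0 * stats.t.sf(abs(t), df))
    return float(coef[p - 1]), t, pval, df


class _SetStatistics:
    """Precomputed per-set sufficient statistics for the collapsed fit.

    For set i with member z-rows Z_i (m_i x n): S1_i = column sums (n-vector)
    and Q_i = total sum of squares.  For any dosage vector the stacked OLS
    then needs only the small design.
    """

    def __init__(self, z: pd.DataFrame, gene_sets: dict[str, list[str]], min_size: int = MIN_SET_SIZE):
        self.names: list[str] = []
        self.sizes: list[int] = []
        s1 = []
        q = []
        for name, genes in gene_sets.items():
            resolved = [g for g in genes if g in z.index]
            n_dropped = len(genes) - len(resolved)
            if n_dropped:
                log.info("set %s: %d unresolvable gene ids dropped", name, n_dropped)
            if len(resolved) < min_size:
                log.info("set %s below min size (%d < %d); skipped", name, len(resolved), min_size)
                continue
            Z = z.loc[resolved].to_numpy(dtype=float)
            self.names.append(name)
            self.sizes.append(Z.shape[0])
            s1.append(Z.sum(axis=0))
            q.append(float((Z * Z).sum()))
        self.S1 = np.asarray(s1)  # n_sets x n
        self.Q = np.asarray(q)
        self.m = np.asarray(self.sizes, dtype=float)
        self.n = z.shape[1]

    def stats_for_dosage(self, year, age, dosage):
        """(beta3, t, p, df) arrays over all retained sets for one SNP."""
        Xs = _small_design(year, age, dosage)
        n, p = Xs.shape
        xtx = Xs.T @ Xs
        xtx_inv = np.linalg.inv(xtx)
        XtS = self.S1 @ Xs  # n_sets x p: stacked X'y
        # stacked X'X = m * Xs'Xs, so beta = (Xs'Xs)^{-1} Xs'S1 / m,
        # i.e. the OLS of the per-set MEAN z-profile on the small design
        B = (XtS @ xtx_inv.T) / self.m[:, None]
        quad = np.einsum("ij,jk,ik->i", B, xtx, B)
        rss = self.Q - 2.0 * np.einsum("ij,ij->i", B, XtS) + self.m * quad
        df = self.m * n - p
        sigma2 = np.maximum(rss, 0.0) / df
        se = np.sqrt(sigma2 * xtx_inv[p - 1, p - 1] / self.m)
        beta3 = B[:, p - 1]
        t = beta3 / se
        pval = 2.0 * stats.t.sf(np.abs(t), df)
        return beta3, t, pval, df


def fqtl_scan(
    bundle: StudyBundle,
    stratum: str,
    gene_sets: dict[str, list[str]] | None = None,
    min_size: int = MIN_SET_SIZE,
    n_permutations: int = 1000,
    seed: int = 0,
    per_snp_permutation: bool = False,
) -> pd.DataFrame:
    """Full fQTL scan in one stratum with genotype-permutation FDR.

    Returns one row per (SNP, gene set) with beta3, t, nominal p, the
    permutation FDR, and the set size used.  ``n_permutations=0`` skips the
    FDR column (nominal results only).
    """
    if gene_sets is None:
        gene_sets = bundle.gene_sets
    ids = select_stratum(bundle.samples, stratum)
    if len(ids) == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    z = zscore_standardize(bundle.expression[ids])
    year = bundle.samples.loc[ids, "year_dx"].to_numpy(dtype=float)
    age = bundle.samples.loc[ids, "age_dx"].to_numpy(dtype=float)
    dosages = bundle.dosage[ids]

    ss = _SetStatistics(z, gene_sets, min_size=min_size)
    if not ss.names:
        raise ValueError("no gene sets of sufficient size")

    snps = []
    for snp in dosages.index:
        if np.var(dosages.loc[snp].to_numpy(dtype=float)) == 0:
            log.info("SNP %s monomorphic in stratum %s; skipped", snp, stratum)
            continue
        snps.append(snp)

    rows = []
    obs_t = []
    for snp in snps:
        d = dosages.loc[snp].to_numpy(dtype=float)
        beta3, t, pval, df = ss.stats_for_dosage(year, age, d)
        obs_t.append(np.abs(t))
        for j, name in enumerate(ss.names):
            rows.append((snp, name, stratum, beta3[j], t[j], pval[j], ss.sizes[j]))
    records = pd.DataFrame(
        rows, columns=["snp", "set", "stratum", "beta", "t", "p", "set_size"]
    )
    if n_permutations <= 0:
        return records

    if n_permutations < 100:
        log.warning("B=%d permutations gives coarse FDR resolution", n_permutations)
    rng = np.random.default_rng(seed)
    n = len(ids)
    perm_stats = np.empty((n_permutations, len(snps) * len(ss.names)))
    for b in range(n_permutations):
        if per_snp_permutation:
            stats_b = []
            for snp in snps:
                perm = rng.permutation(n)
                d = dosages.loc[snp].to_numpy(dtype=float)[perm]
                stats_b.append(np.abs(ss.stats_for_dosage(year, age, d)[1]))
            perm_stats[b] = np.concatenate(stats_b)
        else:
            perm = rng.permutation(n)  # one shared permutation per round
            stats_b = []
            for snp in snps:
                d = dosages.loc[snp].to_numpy(dtype=float)[perm]
                stats_b.append(np.abs(ss.stats_for_dosage(year, age, d)[1]))
            perm_stats[b] = np.concatenate(stats_b)

    observed = np.concatenate(obs_t)
    records["fdr"] = permutation_fdr(observed, perm_stats)
    return records


def permutation_fdr(observed, perm_stats) -> np.ndarray:
    """Tail-ratio FDR of each observed statistic against permutation rounds.

    ``perm_stats`` is a (B, K') array of permutation statistics (K' need not
    equal len(observed); each round is scaled to the observed list size).
    FDR(t*) = mean_b[#{perm_b >= t*} * K/K'] / #{obs >= t*}, capped at 1,
    then made monotone nonincreasing in the statistic by the q-value
    convention (running minimum from the least significant end).
    """
    observed = np.asarray(observed, dtype=float)
    perm_stats = np.asarray(perm_stats, dtype=float)
    if perm_stats.ndim != 2:
        raise ValueError("perm_stats must be a (B, K) array")
    if not np.all(np.isfinite(observed)):
        raise ValueError("observed statistics must be finite")
    B, Kp = perm_stats.shape
    K = observed.size
    scale = K / Kp

    order = np.argsort(observed)[::-1]  # descending
    obs_sorted = observed[order]
    flat = np.sort(perm_stats.reshape(-1))
    # mean tail count over rounds = total tail count / B
    tail_perm = (flat.size - np.searchsorted(flat, obs_sorted, side="left")) / B * scale
    tail_obs = np.arange(1, K + 1, dtype=float)
    # ties in observed: every tied record shares the full tied tail count
    for i in range(K - 2, -1, -1):
        if obs_sorted[i] == obs_sorted[i + 1]:
            tail_obs[i] = tail_obs[i + 1]
    raw = np.minimum(tail_perm / tail_obs, 1.0)
    # monotone: record i gets the best FDR achievable at any threshold <= its
    # statistic, i.e. the minimum of raw over it and all less significant rows
    mono = np.minimum.accumulate(raw[::-1])[::-1]
    out = np.empty(K)
    out[order] = mono
    return out
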