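"""Sample-level quality control for archival (FFPE) expression studies.

Three operators, applied in the order a study would:

1. control-probe AUC filtering — each sample's ability to separate positive
   from negative control probes is summarized by a Mann-Whitney AUC, and
   samples below threshold (default 0.55, strict less-than) are dropped;
2. technical-replicate concordance — minimum pairwise Pearson correlation
   within each replicate group;
3. principal-component batch adjustment — the leading sample-space PCs of
   centered expression are screened for batch association by one-way ANOVA
   and the associated components are either clipped from the matrix or
   returned as regression covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import StudyBundle

log = logging.getLogger(__name__)

__all__ = [
    "QcReport",
    "probe_signal_auc",
    "filter_samples_by_auc",
    "replicate_concordance",
    "pc_batch_adjust",
]


@dataclass
class QcReport:
    auc: pd.Series | None = None  # per-sample AUC
    auc_threshold: float | None = None
    failed_samples: list[str] = field(default_factory=list)
    replicate_min_r: dict[str, float] = field(default_factory=dict)
    pcs_tested: int = 0
    pc_batch_p: pd.Series | None = None
    clipped_pcs: list[int] = field(default_factory=list)
    pc_mode: str | None = None  # "clip" or "covariate"
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to a long key/value table for TSV export."""
        rows: list[tuple[str, str, str]] = []
        if self.auc is not None:
            for s, a in self.auc.items():
                flag = "fail" if s in self.failed_samples else "pass"
                rows.append(("sample_auc", str(s), f"{a:.6g}|{flag}"))
        for g, r in self.replicate_min_r.items():
            rows.append(("replicate_min_r", g, f"{r:.6g}"))
        if self.pc_batch_p is not None:
            for k, p in self.pc_batch_p.items():
                rows.append(("pc_batch_p", f"PC{k}", f"{p:.6g}"))
        for k in self.clipped_pcs:
            rows.append(("clipped_pc", f"PC{k}", self.pc_mode or ""))
        for note in self.notes:
            rows.append(("note", "", note))
        return pd.DataFrame(rows, columns=["metric", "key", "value"])


def probe_signal_auc(pos, neg) -> float:
    """Mann-Whitney AUC separating positive from negative probe signals.

    AUC = (#{pos > neg pairs} + 0.5 * #{ties}) / (n_pos * n_neg).
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("probe signal vectors must be nonempty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def filter_samples_by_auc(bundle: StudyBundle, threshold: float = 0.55):
    """Drop samples whose control-probe AUC is strictly below ``threshold``.

    Retained samples keep their original order in every bundle component.
    """
    if bundle.control_pos is None or bundle.control_neg is None:
        raise ValueError("bundle has no control-probe signals")
    auc = pd.Series(
        {
            s: probe_signal_auc(bundle.control_pos[s], bundle.control_neg[s])
            for s in bundle.expression.columns
        }
    )
    failed = [s for s in auc.index if auc[s] < threshold]
    kept = [s for s in auc.index if auc[s] >= threshold]
    if not kept:
        raise ValueError("no samples remain after AUC filtering")
    report = QcReport(auc=auc, auc_threshold=threshold, failed_samples=failed)
    return bundle.subset_samples(kept), report


def replicate_concordance(expr: pd.DataFrame, groups: dict[str, list[str]]) -> dict[str, float]:
    """Minimum pairwise Pearson r of expression columns within each group."""
    out = {}
    for name, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"replicate group {name!r} has fewer than 2 samples")
        cols = expr[list(members)].to_numpy(dtype=float)
        if np.any(cols.std(axis=0) == 0):
            raise ValueError(f"constant expression column in replicate group {name!r}")
        r = np.corrcoef(cols.T)
        iu = np.triu_indices(len(members), k=1)
        out[name] = float(r[iu].min())
    return out


def pc_batch_adjust(
    expr: pd.DataFrame,
    batch,
    n_pcs: int = 50,
    alpha: float = 0.05,
    mode: str = "clip",
):
    """Screen leading expression PCs for batch association; clip the hits.

    The genes x samples matrix is row-centered and decomposed by SVD; sample
    scores of the first ``n_pcs`` components are each tested against batch by
    one-way ANOVA.  Components with p < alpha are, depending on ``mode``,
    subtracted from the matrix as rank-one terms ("clip") or left in place
    and returned as covariate scores ("covariate").  Returns
    (adjusted expr, clipped-PC score frame, QcReport).
    """
    if mode not in ("clip", "covariate"):
        raise ValueError("mode must be 'clip' or 'covariate'")
    batch = pd.Series(np.asarray(batch), index=expr.columns)
    report = QcReport(pc_mode=mode)
    if batch.nunique() < 2:
        report.notes.append("single batch: no adjustment performed")
        return expr.copy(), pd.DataFrame(index=expr.columns), report

    X = expr.to_numpy(dtype=float)
    row_means = X.mean(axis=1, keepdims=True)
    Xc = X - row_means
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_pcs = min(n_pcs, (s > 1e-12 * s[0]).sum())
    report.pcs_tested = int(n_pcs)

    levels = [batch[batch == b].index for b in batch.unique()]
    pvals = {}
    clipped = []
    for k in range(n_pcs):
        scores = pd.Series(s[k] * Vt[k], index=expr.columns)
        p = stats.f_oneway(*[scores[idx].to_numpy() for idx in levels]).pvalue
        pvals[k + 1] = float(p)
        if p < alpha:
            clipped.append(k + 1)
    report.pc_batch_p = pd.Series(pvals)
    report.clipped_pcs = clipped

    scores_frame = pd.DataFrame(
        {f"PC{k}": s[k - 1] * Vt[k - 1] for k in clipped}, index=expr.columns
    )
    if mode == "covariate" or not clipped:
        return expr.copy(), scores_frame, report

    Xadj = Xc.copy()
    for k in clipped:
        Xadj -= s[k - 1] * np.outer(U[:, k - 1], Vt[k - 1])
    Xadj += row_means
    log.info("pc_batch_adjust clipped %d/%d PCs: %s", len(clipped), n_pcs, clipped)
    return pd.DataFrame(Xadj, index=expr.index, columns=expr.columns), scores_frame, report
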