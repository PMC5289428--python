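"""Synthetic study generator with planted truth.

Emulates the statistical structure of a paired tumor / adjacent-normal
FFPE expression study with germline genotype dosages: Hardy-Weinberg
dosages at configurable minor-allele frequencies, age / year-of-diagnosis
covariate effects, assay-plate batch shifts visible on leading principal
components, ER/PR receptor-group mean differences, subject-shared baselines
for tumor/normal pairs, gene sets with set-level dosage effects, and
positive / negative control-probe signals of varying quality.  Every
planted effect is recorded in a TruthTable so downstream scans can be
scored for power and false-discovery control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "StudyBundle",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_control_probes",
    "simulate_bundle",
]

N_CHROMS = 22  # synthetic autosomes
CHROM_LENGTH = 120_000_000


@dataclass
class StudyBundle:
    """All inputs a scan consumes, with consistent sample ids throughout."""

    expression: pd.DataFrame  # genes x samples, log scale
    dosage: pd.DataFrame  # snps x samples, values in [0, 2]
    samples: pd.DataFrame  # sample id index: subject, tissue, er, pr, age_dx, year_dx, plate
    snp_coords: pd.DataFrame  # snp id index: chrom, pos (1-based)
    gene_coords: pd.DataFrame  # gene id index: chrom, start, end
    gene_sets: dict[str, list[str]] = field(default_factory=dict)
    control_pos: pd.DataFrame | None = None  # probes x samples
    control_neg: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None  # planted-effect ledger

    def __post_init__(self):
        self.validate()

    def validate(self):
        ids = list(self.expression.columns)
        if list(self.dosage.columns) != ids or list(self.samples.index) != ids:
            raise ValueError("sample ids differ across expression, dosage, and annotation")
        dv = self.dosage.to_numpy()
        if np.nanmin(dv) < 0 or np.nanmax(dv) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        for comp in (self.control_pos, self.control_neg):
            if comp is not None and list(comp.columns) != ids:
                raise ValueError("control-probe sample ids differ from expression")
        tissues = set(self.samples["tissue"].unique())
        if not tissues <= {"tumor", "normal"}:
            raise ValueError(f"unknown tissue labels: {tissues - {'tumor', 'normal'}}")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def subset_samples(self, sample_ids) -> "StudyBundle":
        """Restrict every component to the given samples, preserving order."""
        sample_ids = list(sample_ids)
        return StudyBundle(
            expression=self.expression[sample_ids],
            dosage=self.dosage[sample_ids],
            samples=self.samples.loc[sample_ids],
            snp_coords=self.snp_coords,
            gene_coords=self.gene_coords,
            gene_sets=self.gene_sets,
            control_pos=None if self.control_pos is None else self.control_pos[sample_ids],
            control_neg=None if self.control_neg is None else self.control_neg[sample_ids],
            truth=self.truth,
        )


@dataclass
class SimConfig:
    """Study-generator settings.

    Defaults mirror the structure of a postmenopausal breast-cancer FFPE
    cohort: ~70% of tumors ER+, mean age at diagnosis 57, diagnoses spread
    over 1990-2004, nine assay plates, MAFs spanning 0.015-0.50, and 70%
    of subjects contributing a paired adjacent-normal specimen.
    """

    n_subjects: int = 300
    paired_fraction: float = 0.7
    n_snps: int = 40
    mafs: np.ndarray | None = None  # drawn U(0.015, 0.5) when None
    n_genes: int = 2000
    n_gene_sets: int = 0
    gene_set_size_range: tuple[int, int] = (10, 50)
    age_effect_sd: float = 0.01  # per-gene age-slope SD, log-units per year
    year_effect_sd: float = 0.01
    n_plates: int = 9
    batch_shift: float = 0.0  # per-gene per-plate shift SD, log-units
    subject_sd: float = 0.5  # subject-level baseline SD shared by a pair
    tumor_shift_sd: float = 0.3  # per-gene tumor-vs-normal offset SD
    noise_sd: float = 1.0
    er_pos_fraction: float = 0.70
    pr_pos_fraction: float = 0.60
    er_shift: float = 0.0  # mean shift on receptor-responsive genes
    er_gene_fraction: float = 0.1
    planted_eqtl: list[tuple[str, str, float]] = field(default_factory=list)
    planted_interaction: list[tuple[str, str, float]] = field(default_factory=list)
    planted_fqtl: list[tuple[str, str, float]] = field(default_factory=list)
    control_probe_delta: float = 3.0  # positive-minus-negative probe shift
    n_control_probes: int = 200
    dosage_jitter: float = 0.0  # imputation-style continuous jitter SD
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_snps", "n_genes", "n_plates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mafs is not None:
            self.mafs = np.asarray(self.mafs, dtype=float)
            if np.any(self.mafs <= 0) or np.any(self.mafs > 0.5):
                raise ValueError("MAFs must lie in (0, 0.5]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def simulate_genotypes(n: int, mafs, seed, jitter: float = 0.0) -> np.ndarray:
    """Hard-call HWE dosages, optionally jittered toward continuous values.

    Returns an (n_snps, n) array with genotypes drawn from
    {(1-p)^2, 2p(1-p), p^2}; with ``jitter`` > 0, Gaussian noise emulating
    imputation uncertainty is added and the result clipped to [0, 2].
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("MAFs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, mafs[:, None], size=(len(mafs), n)).astype(float)
    if jitter > 0:
        dosage = np.clip(dosage + rng.normal(0.0, jitter, size=dosage.shape), 0.0, 2.0)
    return dosage


def simulate_control_probes(quality, seed, n_probes: int = 200, mu: float = 3.0):
    """Positive/negative control-probe signals per sample.

    negatives ~ N(mu, 1); positives ~ N(mu + delta_i, 1) with delta_i >= 0
    the per-sample quality.  The expected separating AUC is Phi(delta/sqrt 2).
    """
    quality = np.asarray(quality, dtype=float)
    if np.any(quality < 0):
        raise ValueError("quality deltas must be >= 0")
    rng = np.random.default_rng(seed)
    neg = rng.normal(mu, 1.0, size=(n_probes, quality.size))
    pos = rng.normal(mu + quality[None, :], 1.0, size=(n_probes, quality.size))
    return pos, neg


def _sample_table(cfg: SimConfig, rng) -> pd.DataFrame:
    n_paired = int(round(cfg.paired_fraction * cfg.n_subjects))
    paired = np.zeros(cfg.n_subjects, dtype=bool)
    paired[rng.choice(cfg.n_subjects, size=n_paired, replace=False)] = True
    er = np.where(rng.random(cfg.n_subjects) < cfg.er_pos_fraction, "+", "-")
    pr = np.where(rng.random(cfg.n_subjects) < cfg.pr_pos_fraction, "+", "-")
    age = np.clip(rng.normal(57.0, 7.0, cfg.n_subjects), 40.0, 80.0)
    year = rng.integers(1990, 2005, cfg.n_subjects)
    rows = []
    for i in range(cfg.n_subjects):
        subj = f"SUBJ{i:04d}"
        rows.append((f"{subj}_T", subj, "tumor", er[i], pr[i], age[i], year[i]))
        if paired[i]:
            rows.append((f"{subj}_N", subj, "normal", er[i], pr[i], age[i], year[i]))
    df = pd.DataFrame(
        rows, columns=["sample", "subject", "tissue", "er", "pr", "age_dx", "year_dx"]
    ).set_index("sample")
    df.index.name = None
    df["plate"] = [f"P{j % cfg.n_plates + 1}" for j in rng.permutation(len(df))]
    return df


def _coords(rng, ids, is_gene: bool) -> pd.DataFrame:
    chrom = rng.integers(1, N_CHROMS + 1, len(ids))
    pos = rng.integers(1, CHROM_LENGTH, len(ids))
    if is_gene:
        length = rng.integers(2_000, 200_000, len(ids))
        return pd.DataFrame(
            {"chrom": [f"chr{c}" for c in chrom], "start": pos, "end": pos + length}, index=ids
        )
    return pd.DataFrame({"chrom": [f"chr{c}" for c in chrom], "pos": pos}, index=ids)


def _gene_sets(cfg: SimConfig, genes, rng) -> dict[str, list[str]]:
    lo, hi = cfg.gene_set_size_range
    sets = {}
    for k in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        sets[f"SET{k:03d}"] = list(members)
    return sets


def simulate_expression(
    cfg: SimConfig,
    dosage: pd.DataFrame,
    samples: pd.DataFrame,
    rng,
    gene_sets: dict[str, list[str]] | None = None,
):
    """Build the expression matrix plus the planted-effect TruthTable.

    expression = gene baseline + subject baseline + tumor offset
               + age and year covariate terms + plate shift + receptor shift
               + planted dosage effects (+ tissue x dosage interactions on
                 tumor samples, + set-level shifts on gene-set members)
               + N(0, noise_sd) noise.
    """
    genes = [f"G{j:05d}" for j in range(cfg.n_genes)]
    sample_ids = list(samples.index)
    n = len(sample_ids)
    subjects = samples["subject"].to_numpy()
    subj_codes, subj_idx = np.unique(subjects, return_inverse=True)

    baseline = rng.normal(7.0, 1.0, cfg.n_genes)
    age_coef = rng.normal(0.0, cfg.age_effect_sd, cfg.n_genes)
    year_coef = rng.normal(0.0, cfg.year_effect_sd, cfg.n_genes)
    age_c = samples["age_dx"].to_numpy() - samples["age_dx"].mean()
    year_c = samples["year_dx"].to_numpy() - samples["year_dx"].mean()

    Y = baseline[:, None] + np.outer(age_coef, age_c) + np.outer(year_coef, year_c)

    subj_base = rng.normal(0.0, cfg.subject_sd, (cfg.n_genes, len(subj_codes)))
    Y += subj_base[:, subj_idx]
    tumor = (samples["tissue"] == "tumor").to_numpy().astype(float)
    Y += np.outer(rng.normal(0.0, cfg.tumor_shift_sd, cfg.n_genes), tumor)

    if cfg.batch_shift > 0:
        plates = samples["plate"].to_numpy()
        for p in np.unique(plates):
            shift = rng.normal(0.0, cfg.batch_shift, cfg.n_genes)
            Y[:, plates == p] += shift[:, None]

    if cfg.er_shift != 0:
        n_resp = max(1, int(cfg.er_gene_fraction * cfg.n_genes))
        resp = rng.choice(cfg.n_genes, size=n_resp, replace=False)
        er_pos = (samples["er"] == "+").to_numpy().astype(float)
        Y[resp] += cfg.er_shift * er_pos[None, :]

    gene_pos = {g: j for j, g in enumerate(genes)}
    truth_rows = []

    def _dose(snp):
        if snp not in dosage.index:
            raise KeyError(f"planted effect references unknown SNP {snp!r}")
        return dosage.loc[snp].to_numpy()

    for snp, gene, beta in cfg.planted_eqtl:
        if gene not in gene_pos:
            raise KeyError(f"planted effect references unknown gene {gene!r}")
        Y[gene_pos[gene]] += beta * _dose(snp)
        truth_rows.append(("eqtl", snp, gene, beta))
    for snp, gene, delta in cfg.planted_interaction:
        if gene not in gene_pos:
            raise KeyError(f"planted effect references unknown gene {gene!r}")
        Y[gene_pos[gene]] += delta * _dose(snp) * tumor
        truth_rows.append(("interaction", snp, gene, delta))
    for snp, set_name, shift in cfg.planted_fqtl:
        if gene_sets is None or set_name not in gene_sets:
            raise KeyError(f"planted effect references unknown gene set {set_name!r}")
        d = _dose(snp)
        for g in gene_sets[set_name]:
            Y[gene_pos[g]] += shift * d
        truth_rows.append(("fqtl", snp, set_name, shift))

    Y += rng.normal(0.0, cfg.noise_sd, Y.shape)
    truth = pd.DataFrame(truth_rows, columns=["type", "snp", "target", "effect"])
    expr = pd.DataFrame(Y, index=genes, columns=sample_ids)
    return expr, truth


def simulate_bundle(cfg: SimConfig) -> StudyBundle:
    """Generate a complete StudyBundle under ``cfg``; fully seed-determined."""
    rng = np.random.default_rng(cfg.seed)
    samples = _sample_table(cfg, rng)
    mafs = cfg.mafs
    if mafs is None:
        mafs = rng.uniform(0.015, 0.5, cfg.n_snps)
    elif len(mafs) != cfg.n_snps:
        raise ValueError("len(mafs) must equal n_snps")

    snp_ids = [f"rs{900000 + s}" for s in range(cfg.n_snps)]
    subj_ids = sorted(samples["subject"].unique())
    subj_dos = simulate_genotypes(
        len(subj_ids), mafs, rng.integers(2**31), jitter=cfg.dosage_jitter
    )
    col = {s: k for k, s in enumerate(subj_ids)}
    dose = subj_dos[:, [col[s] for s in samples["subject"]]]
    dosage = pd.DataFrame(dose, index=snp_ids, columns=samples.index)

    genes = [f"G{j:05d}" for j in range(cfg.n_genes)]
    gene_sets = _gene_sets(cfg, genes, rng)
    expr, truth = simulate_expression(cfg, dosage, samples, rng, gene_sets=gene_sets)

    quality = np.full(len(samples), cfg.control_probe_delta, dtype=float)
    pos, neg = simulate_control_probes(
        quality, rng.integers(2**31), n_probes=cfg.n_control_probes
    )
    probe_ids_p = [f"POS{j:04d}" for j in range(cfg.n_control_probes)]
    probe_ids_n = [f"NEG{j:04d}" for j in range(cfg.n_control_probes)]

    return StudyBundle(
        expression=expr,
        dosage=dosage,
        samples=samples,
        snp_coords=_coords(rng, snp_ids, is_gene=False),
        gene_coords=_coords(rng, genes, is_gene=True),
        gene_sets=gene_sets,
        control_pos=pd.DataFrame(pos, index=probe_ids_p, columns=samples.index),
        control_neg=pd.DataFrame(neg, index=probe_ids_n, columns=samples.index),
        truth=truth,
    )
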