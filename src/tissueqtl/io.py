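"""File formats: expression / dosage / annotation TSV, VCF dosage, GMT gene
sets, study-bundle directories, and result tables with provenance headers.

Conventions: genomic coordinates are 1-based inclusive (dbSNP/VCF style);
strand is irrelevant to every computation here and ignored; the missing
value token is ``NA`` and downstream fits are per-gene complete-case.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_data import StudyBundle

log = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_dosages",
    "read_annotations",
    "read_gene_sets",
    "write_gene_sets",
    "read_bundle",
    "write_bundle",
    "write_results",
    "load_config",
]

NA_TOKEN = "NA"


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene id, header of sample ids.

    ``NA`` tokens become NaN; non-numeric cells and duplicate gene ids are
    errors naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    dup = df.index[df.index.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene id(s) in {path}: {sorted(set(dup))}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        vals = df[col].mask(df[col] == NA_TOKEN, np.nan)
        try:
            out[col] = vals.astype(float)
        except ValueError:
            bad = [(g, v) for g, v in vals.items() if _not_numeric(v)]
            g, v = bad[0]
            raise ValueError(f"non-numeric cell {v!r} at gene {g!r}, sample {col!r} in {path}") from None
    return out


def _not_numeric(v) -> bool:
    if v is np.nan or (isinstance(v, float) and np.isnan(v)):
        return False
    try:
        float(v)
        return False
    except (TypeError, ValueError):
        return True


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="gene")


def read_dosages(path, format: str = "tsv"):
    """Read a dosage matrix plus SNP coordinates.

    TSV dialect: columns ``snp, chrom, pos`` then per-sample dosages.
    VCF dialect: per-genotype ``DS`` field, falling back to the GT
    alternate-allele count.  Returns (dosage genes x samples frame,
    snp-coordinate frame); all dosages checked into [0, 2].
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if not {"chrom", "pos"} <= set(df.columns[:2]):
            raise ValueError("dosage TSV must start with columns: snp, chrom, pos")
        coords = df[["chrom", "pos"]].copy()
        dosage = df.drop(columns=["chrom", "pos"]).astype(float)
    elif format == "vcf":
        dosage, coords = _read_vcf_dosages(path)
    else:
        raise ValueError("format must be 'tsv' or 'vcf'")
    vals = dosage.to_numpy()
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
        bad = dosage.index[np.where((vals < 0) | (vals > 2))[0][0]]
        raise ValueError(f"dosage outside [0, 2] at SNP {bad!r}")
    return dosage, coords


def _read_vcf_dosages(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ds = var.format("DS")
        if ds is not None:
            rows.append(np.asarray(ds, dtype=float).reshape(-1))
        else:
            gt = var.gt_types  # cyvcf2: 0=hom ref, 1=het, 2=unknown, 3=hom alt
            if gt is None:
                raise ValueError(f"VCF record {ids[-1]} has neither DS nor GT")
            counts = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            rows.append(counts)
    dosage = pd.DataFrame(rows, index=ids, columns=samples)
    coords = pd.DataFrame({"chrom": chroms, "pos": poss}, index=ids)
    return dosage, coords


def read_annotations(path) -> pd.DataFrame:
    """Sample annotation TSV indexed by sample id.

    Expected columns: subject, tissue (tumor/normal), er, pr, age_dx,
    year_dx, plate.  ER/PR missing values stay as ``NA`` strings.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    required = {"subject", "tissue", "er", "pr", "age_dx", "year_dx", "plate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    df["age_dx"] = df["age_dx"].astype(float)
    df["year_dx"] = df["year_dx"].astype(float)
    return df


def read_gene_sets(path) -> dict[str, list[str]]:
    """GMT: tab-separated lines of set name, description, member gene ids.

    Duplicate genes within a set are dropped (logged); duplicate set names
    are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >= 1 gene")
            name, _desc, genes = parts[0], parts[1], parts[2:]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in {path}")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                log.info("set %s: %d duplicate gene ids removed", name, len(genes) - len(unique))
            sets[name] = unique
    return sets


def write_gene_sets(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_bundle(bundle: StudyBundle, outdir) -> None:
    """Write every bundle component as TSV files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(bundle.expression, outdir / "expression.tsv")
    dos = bundle.snp_coords.join(bundle.dosage)
    dos.to_csv(outdir / "dosage.tsv", sep="\t", index_label="snp")
    bundle.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    bundle.gene_coords.to_csv(outdir / "gene_coords.tsv", sep="\t", index_label="gene")
    if bundle.gene_sets:
        write_gene_sets(bundle.gene_sets, outdir / "gene_sets.gmt")
    if bundle.control_pos is not None:
        bundle.control_pos.to_csv(outdir / "control_pos.tsv", sep="\t", index_label="probe")
        bundle.control_neg.to_csv(outdir / "control_neg.tsv", sep="\t", index_label="probe")
    if bundle.truth is not None:
        bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def read_bundle(indir) -> StudyBundle:
    indir = Path(indir)
    expression = read_expression(indir / "expression.tsv")
    dosage, snp_coords = read_dosages(indir / "dosage.tsv", format="tsv")
    samples = read_annotations(indir / "samples.tsv")
    gene_coords = pd.read_csv(indir / "gene_coords.tsv", sep="\t", index_col=0)
    gene_sets = {}
    if (indir / "gene_sets.gmt").exists():
        gene_sets = read_gene_sets(indir / "gene_sets.gmt")
    cp = cn = None
    if (indir / "control_pos.tsv").exists():
        cp = pd.read_csv(indir / "control_pos.tsv", sep="\t", index_col=0)
        cn = pd.read_csv(indir / "control_neg.tsv", sep="\t", index_col=0)
    truth = None
    if (indir / "truth.tsv").exists():
        truth = pd.read_csv(indir / "truth.tsv", sep="\t")
    for frame in (expression, dosage, samples, gene_coords, snp_coords, cp, cn):
        if frame is not None:
            frame.index.name = None
            frame.columns.name = None
    return StudyBundle(
        expression=expression,
        dosage=dosage,
        samples=samples,
        snp_coords=snp_coords,
        gene_coords=gene_coords,
        gene_sets=gene_sets,
        control_pos=cp,
        control_neg=cn,
        truth=truth,
    )


def write_results(df: pd.DataFrame, path, seed=None, config: dict | None = None) -> None:
    """Result TSV with a provenance header (version, seed, config hash)."""
    from . import __version__

    cfg_hash = "na"
    if config is not None:
        blob = yaml.safe_dump(config, sort_keys=True).encode()
        cfg_hash = hashlib.sha256(blob).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# tissueqtl {__version__} seed={seed} config_sha256={cfg_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
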