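"""File formats: VCF / dosage-TSV genotypes, phenotypes, risk-allele specs,
and TSV/JSON result writers.

Formats
-------
* Genotypes: VCF 4.x with GT or DS (biallelic records only), or a dosage
  TSV whose first column is ``sample_id`` and whose remaining headers are
  ``snpid:counted_allele:other_allele`` with values counting the counted
  allele in [0, 2].  Headers without allele annotation are taken as
  already risk-oriented counts.
* Phenotype TSV: columns ``sample_id``, ``status`` (0 control / 1 case).
* Risk-allele spec TSV: columns ``snp_id``, ``risk_allele``, optional
  ``weight`` (default 1).

Orientation to the externally designated risk alleles happens on load;
per-SNP flip decisions and excluded individuals are logged.  Internal SNP
order equals the spec-file order: it defines the "first k SNPs" semantics
of subset analyses.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .smt import (
    GenotypeMatrix,
    RiskAlleleSpec,
    SMTResult,
    orient_to_risk_alleles,
)
from .study import StudyResult

__all__ = [
    "DatasetBundle",
    "draft_risk_spec_from_data",
    "load_dataset",
    "read_dosage_tsv",
    "read_phenotypes",
    "read_risk_spec",
    "read_vcf",
    "write_smt_result",
    "write_study_result",
]

log = logging.getLogger("supramult")


@dataclass(frozen=True)
class DatasetBundle:
    """Paths of one analysis dataset; samples are joined on their ids."""

    genotypes: str | Path
    phenotypes: str | Path
    risk_spec: str | Path
    dosage: bool = False  # prefer DS over GT when reading VCF


def read_risk_spec(path) -> RiskAlleleSpec:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "risk_allele": str})
    for col in ("snp_id", "risk_allele"):
        if col not in df.columns:
            raise ValueError(f"risk-allele spec is missing column {col!r}")
    weights = (
        df["weight"].astype(float).tolist()
        if "weight" in df.columns
        else None
    )
    return RiskAlleleSpec.from_lists(
        df["snp_id"].tolist(), df["risk_allele"].tolist(), weights
    )


def read_phenotypes(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise ValueError(f"phenotype file is missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in phenotype file: {dupes[:5]}")
    status = df["status"].astype(int)
    if not status.isin((0, 1)).all():
        raise ValueError("phenotype status must be coded 0/1")
    return pd.Series(status.to_numpy(), index=df["sample_id"].to_numpy())


def read_dosage_tsv(path) -> GenotypeMatrix:
    """Dosage/genotype TSV -> unoriented GenotypeMatrix.

    Individuals with any missing genotype in the set are excluded (the
    allele load needs every SNP); the exclusion count is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if df.columns[0] != "sample_id":
        raise ValueError("first column of a dosage TSV must be 'sample_id'")
    snp_cols = list(df.columns[1:])
    n0 = len(df)
    df = df.dropna(subset=snp_cols)
    if len(df) < n0:
        log.info("excluded %d individuals with missing genotypes", n0 - len(df))
    ids, alleles = [], []
    annotated = [":" in c for c in snp_cols]
    if any(annotated) and not all(annotated):
        raise ValueError("mix of allele-annotated and plain headers")
    for col in snp_cols:
        if ":" in col:
            snp, counted, other = col.split(":")
            ids.append(snp)
            alleles.append((counted, other))
        else:
            ids.append(col)
    vals = df[snp_cols].to_numpy(dtype=np.float64)
    dosage = bool(np.any(np.abs(vals - np.rint(vals)) > 1e-9))
    return GenotypeMatrix(
        values=vals,
        snp_ids=tuple(ids),
        sample_ids=tuple(df["sample_id"]),
        counted_alleles=tuple(alleles) if alleles else None,
        oriented=not alleles,
        dosage=dosage,
    )


def read_vcf(path, dosage: bool = False) -> GenotypeMatrix:
    """Biallelic VCF -> unoriented GenotypeMatrix counting the ALT allele.

    Uses the DS FORMAT field when ``dosage`` is requested, GT otherwise.
    Individuals with any missing genotype are excluded (logged).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, alleles, cols = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record not supported: {var.ID or var.POS}"
            )
        snp = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        ids.append(snp)
        alleles.append((var.ALT[0], var.REF))
        if dosage:
            ds = var.format("DS")
            if ds is None:
                raise ValueError(f"no DS field for {snp}")
            col = np.asarray(ds, dtype=np.float64).ravel()
        else:
            col = np.empty(len(samples))
            for i, gt in enumerate(var.genotypes):
                a = [x for x in gt[:-1] if x is not None]
                col[i] = np.nan if (len(a) < 2 or min(a) < 0) else float(sum(a))
        cols.append(col)
    vcf.close()
    vals = np.column_stack(cols)
    keep = np.isfinite(vals).all(axis=1)
    if not keep.all():
        log.info("excluded %d individuals with missing genotypes", (~keep).sum())
    return GenotypeMatrix(
        values=vals[keep],
        snp_ids=tuple(ids),
        sample_ids=tuple(s for s, k in zip(samples, keep) if k),
        counted_alleles=tuple(alleles),
        oriented=False,
        dosage=dosage,
    )


def read_genotypes(source, spec: RiskAlleleSpec, dosage: bool = False) -> GenotypeMatrix:
    """Read VCF or dosage TSV and orient counts to the spec's risk alleles.

    SNP columns are reordered to the spec-file order (which defines the
    set order and hence "first k SNPs" in subset analyses).
    """
    path = Path(source)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        G = read_vcf(path, dosage=dosage)
    else:
        G = read_dosage_tsv(path)
    order = [s for s in spec.snp_ids if s in set(G.snp_ids)]
    if len(order) != G.n_snps:
        extra = set(G.snp_ids) - set(spec.snp_ids)
        raise KeyError(f"SNPs missing from risk-allele spec: {sorted(extra)}")
    idx = [G.snp_ids.index(s) for s in order]
    from dataclasses import replace

    G = replace(
        G,
        values=G.values[:, idx],
        snp_ids=tuple(order),
        counted_alleles=None
        if G.counted_alleles is None
        else tuple(G.counted_alleles[i] for i in idx),
    )
    oriented = orient_to_risk_alleles(G, spec)
    if G.counted_alleles is not None:
        flipped = [
            s
            for s, (counted, _o) in zip(G.snp_ids, G.counted_alleles)
            if spec.risk_allele_of(s) != counted
        ]
        log.info("flipped %d/%d SNPs to the designated risk allele", len(flipped), G.n_snps)
    return oriented


def load_dataset(bundle: DatasetBundle):
    """Join genotypes and phenotypes on sample id -> (G, y, spec)."""
    spec = read_risk_spec(bundle.risk_spec)
    G = read_genotypes(bundle.genotypes, spec, dosage=bundle.dosage)
    pheno = read_phenotypes(bundle.phenotypes)
    if G.sample_ids is None:
        raise ValueError("genotype source carries no sample ids")
    common = [s for s in G.sample_ids if s in pheno.index]
    if not common:
        raise ValueError("no overlapping sample ids between genotypes and phenotypes")
    log.info(
        "joined %d individuals (%d genotyped, %d phenotyped)",
        len(common),
        len(G.sample_ids),
        len(pheno),
    )
    keep = [i for i, s in enumerate(G.sample_ids) if s in pheno.index]
    from dataclasses import replace

    G = replace(G, values=G.values[keep], sample_ids=tuple(common))
    y = pheno.loc[list(common)].to_numpy(dtype=float)
    return G, y, spec


def draft_risk_spec_from_data(G: GenotypeMatrix, y) -> RiskAlleleSpec:
    """Draft a risk-allele spec from the data's own marginal odds ratios.

    Marked ``data_derived``: orienting a priori SNP sets by the analysed
    sample itself biases the load test and should only be used for
    exploration, never for confirmatory runs.
    """
    y = np.asarray(y, dtype=float)
    risk = []
    for j, snp in enumerate(G.snp_ids):
        g = G.values[:, j]
        counted, other = (
            G.counted_alleles[j] if G.counted_alleles is not None else ("A", "B")
        )
        case_freq = g[y == 1].mean()
        ctrl_freq = g[y == 0].mean()
        risk.append(counted if case_freq >= ctrl_freq else other)
    spec = RiskAlleleSpec.from_lists(G.snp_ids, risk)
    return RiskAlleleSpec(
        spec.snp_ids, spec.risk_alleles, spec.weights, data_derived=True
    )


def write_smt_result(result: SMTResult, out_prefix, config: dict | None = None):
    """Write the threshold profile as TSV and the summary as JSON."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    profile_path = Path(str(prefix) + ".profile.tsv")
    result.profile.to_tsv(profile_path)
    summary = result.summary_dict()
    summary["version"] = __version__
    if config:
        summary["config"] = config
    json_path = Path(str(prefix) + ".summary.json")
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return profile_path, json_path


def write_study_result(result: StudyResult, out_prefix):
    """Write the study summary TSV and the per-replicate p-values (gzip TSV)."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    summary_path = Path(str(prefix) + ".summary.tsv")
    result.to_tsv(summary_path)
    pvals_path = Path(str(prefix) + ".pvalues.tsv.gz")
    result.pvalues.to_csv(pvals_path, sep="\t", compression="gzip")
    return summary_path, pvals_path
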