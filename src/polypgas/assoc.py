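"""Case/control contrast construction and association testing.

The triangulation design runs six GWAS over one cohort: four
polytoxicomania contrasts with mildly varied phenotype definitions
(set 1) and two disease-only contrasts (set 2).  Every contrast is a
:class:`PhenotypeDefinition` -- a declarative case rule, control rule and
implied exclusions -- evaluated deterministically over the sample table.

Association is an additive-dosage logistic regression per SNP with sex and
the first principal components as covariates (Wald tests), plus a
gene-based principal-component regression and a +/- flank SNP-to-gene
mapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import _glm
from .cohort import Cohort

GWAS_COLUMNS = ["CHR", "SNP", "BP", "A1", "BETA", "SE", "P", "N", "STATUS"]


@dataclass(frozen=True)
class CaseRule:
    """Who counts as a case: diagnosis plus a drug-class count window."""

    diagnosis: str = "patient"        # "patient" or "any"
    min_classes: int = 3
    max_classes: Optional[int] = None
    timing: str = "preadult"          # "preadult", "lifetime" or "adult_only"


@dataclass(frozen=True)
class ControlRule:
    """Who counts as a control among the non-cases."""

    pool: str = "both"                # "patients", "healthy" or "both"
    max_classes: int = 2
    min_classes: int = 0


@dataclass(frozen=True)
class PhenotypeDefinition:
    name: str
    case_rule: CaseRule
    control_rule: ControlRule
    description: str = ""


@dataclass
class ContrastAssignment:
    y: np.ndarray                # 1.0 case, 0.0 control, NaN excluded
    n_cases: int
    n_controls: int
    exclusion_reason: pd.Series  # "" for assigned samples


def _class_counts(samples: pd.DataFrame, timing: str) -> np.ndarray:
    if timing == "preadult":
        return samples["n_classes_preadult"].to_numpy()
    if timing in ("lifetime", "adult_only"):
        return samples["n_classes_lifetime"].to_numpy()
    raise ValueError(f"unknown timing {timing!r}")


def build_contrast(cohort: Cohort, definition: PhenotypeDefinition
                   ) -> ContrastAssignment:
    """Deterministic case/control assignment under one phenotype definition.

    Raises if the case and control rules overlap on any sample, or if either
    group is empty.
    """
    s = cohort.samples
    cr, xr = definition.case_rule, definition.control_rule

    counts = _class_counts(s, cr.timing)
    is_case = counts >= cr.min_classes
    if cr.max_classes is not None:
        is_case &= counts <= cr.max_classes
    if cr.timing == "adult_only":
        is_case &= s["n_classes_preadult"].to_numpy() < cr.min_classes
    if cr.diagnosis == "patient":
        is_case &= (s["diagnosis"] == "patient").to_numpy()
    elif cr.diagnosis != "any":
        raise ValueError(f"unknown case diagnosis {cr.diagnosis!r}")

    lifetime = s["n_classes_lifetime"].to_numpy()
    is_control = (lifetime <= xr.max_classes) & (lifetime >= xr.min_classes)
    if xr.pool == "patients":
        is_control &= (s["diagnosis"] == "patient").to_numpy()
    elif xr.pool == "healthy":
        is_control &= (s["diagnosis"] == "healthy").to_numpy()
    elif xr.pool != "both":
        raise ValueError(f"unknown control pool {xr.pool!r}")

    overlap = is_case & is_control
    if overlap.any():
        raise ValueError(
            f"{definition.name}: case and control rules overlap on "
            f"{int(overlap.sum())} samples"
        )

    y = np.full(len(s), np.nan)
    y[is_case] = 1.0
    y[is_control] = 0.0
    reason = np.full(len(s), "", dtype=object)
    excluded = ~is_case & ~is_control
    reason[excluded] = "matches neither case nor control rule"
    n_cases, n_controls = int(is_case.sum()), int(is_control.sum())
    if n_cases == 0 or n_controls == 0:
        raise ValueError(
            f"{definition.name}: empty group (cases={n_cases}, "
            f"controls={n_controls})"
        )
    return ContrastAssignment(y=y, n_cases=n_cases, n_controls=n_controls,
                              exclusion_reason=pd.Series(reason, name="reason"))


def default_contrast_grid() -> list[PhenotypeDefinition]:
    """The default six-contrast grid (an explicit emulation of the published
    design, whose exact per-GWAS definitions are not public).

    GWAS 1-4 contrast polytoxicomanic with non-polytoxicomanic individuals
    (varying onset window, case threshold and control pool); GWAS 5-6
    contrast diagnosis only.  Non-polytoxicomania filters are applied to
    patient and healthy control pools alike.
    """
    return [
        PhenotypeDefinition(
            "GWAS1", CaseRule("patient", 3, None, "preadult"),
            ControlRule("both", 2),
            "preadult polytox patients vs non-polytox patients + healthy",
        ),
        PhenotypeDefinition(
            "GWAS2", CaseRule("patient", 3, None, "lifetime"),
            ControlRule("both", 2),
            "lifetime polytox patients vs non-polytox patients + healthy",
        ),
        PhenotypeDefinition(
            "GWAS3", CaseRule("patient", 3, None, "preadult"),
            ControlRule("both", 0),
            "preadult polytox patients vs drug-naive patients + healthy",
        ),
        PhenotypeDefinition(
            "GWAS4", CaseRule("patient", 4, None, "lifetime"),
            ControlRule("both", 2),
            ">=4-class lifetime polytox patients vs non-polytox controls",
        ),
        PhenotypeDefinition(
            "GWAS5", CaseRule("patient", 0, 2, "lifetime"),
            ControlRule("healthy", 2),
            "non-polytox patients vs non-polytox healthy (disease contrast)",
        ),
        PhenotypeDefinition(
            "GWAS6", CaseRule("patient", 0, None, "lifetime"),
            ControlRule("healthy", 8),
            "all patients vs all healthy (disease contrast)",
        ),
    ]


def gwas_logistic(cohort: Cohort, y: np.ndarray,
                  covariates: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-SNP additive logistic GWAS with Wald p-values.

    ``y`` may contain NaN for excluded samples (complete-case together with
    any NaN covariate rows); per-SNP missing genotypes drop that sample for
    that SNP only.  Returns a variant-ordered table with columns
    CHR, SNP, BP, A1, BETA, SE, P, N, STATUS; non-converged or separated
    fits carry P = NaN, never a silent 1.
    """
    y = np.asarray(y, dtype=float)
    used = np.isfinite(y)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        used &= np.all(np.isfinite(covariates), axis=1)
    if used.sum() < 2:
        raise ValueError("fewer than two usable samples")
    yy = y[used]
    if np.all(yy == yy[0]):
        raise ValueError("phenotype is constant among usable samples")

    n_used_samples = int(used.sum())
    if covariates is None:
        C = np.ones((n_used_samples, 1))
    else:
        C = np.column_stack([np.ones(n_used_samples), covariates[used]])

    G = cohort.dosages()[used]
    fit = _glm.gwas_logistic_batch(G, yy, C)

    v = cohort.variants
    return pd.DataFrame(
        {
            "CHR": v["chrom"].to_numpy(),
            "SNP": v["id"].to_numpy(),
            "BP": v["pos"].to_numpy(),
            "A1": v["a1"].to_numpy(),
            "BETA": fit.beta,
            "SE": fit.se,
            "P": fit.p,
            "N": fit.n_used,
            "STATUS": fit.status,
        }
    )


@dataclass
class GeneResult:
    gene_id: str
    n_snps: int
    n_pcs_retained: int
    statistic: float
    p: float


def gene_pc_regression(gene_genotypes: np.ndarray, y: np.ndarray,
                       covariates: Optional[np.ndarray] = None,
                       variance_kept: float = 0.999,
                       gene_id: str = "") -> GeneResult:
    """Gene-based principal-component regression test.

    Principal components of the standardized gene SNP submatrix are
    retained up to ``variance_kept`` of the variance and tested jointly by
    a likelihood-ratio test against the covariate-only logistic model
    (chi-square with df = number of retained components).
    """
    y = np.asarray(y, dtype=float)
    used = np.isfinite(y)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        used &= np.all(np.isfinite(covariates), axis=1)
    yy = y[used]
    if yy.size == 0 or np.all(yy == yy[0]):
        raise ValueError("phenotype is constant among usable samples")

    G = np.asarray(gene_genotypes, dtype=float)[used]
    if G.ndim == 1:
        G = G[:, None]
    miss = ~np.isfinite(G) | (G < 0)
    G = np.where(miss, np.nan, G)
    mean = np.nanmean(G, axis=0)
    idx = np.where(~np.isfinite(G))
    G[idx] = np.take(np.where(np.isfinite(mean), mean, 0.0), idx[1])
    G -= G.mean(axis=0)
    sd = G.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("gene submatrix has no polymorphic SNP")
    Z = G[:, keep] / sd[keep]

    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    var = S**2
    frac = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(frac, variance_kept) + 1)
    k = min(k, np.sum(var > 1e-12))
    pcs = U[:, :k] * S[:k]

    if covariates is None:
        C = np.ones((yy.size, 1))
    else:
        C = np.column_stack([np.ones(yy.size), covariates[used]])
    beta0, _, _ = _glm.fit_logistic(C, yy)
    ll0 = _glm.logistic_loglik(C, yy, beta0)
    Xf = np.column_stack([C, pcs])
    beta1, _, _ = _glm.fit_logistic(Xf, yy)
    ll1 = _glm.logistic_loglik(Xf, yy, beta1)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    p = float(stats.chi2.sf(lrt, df=k))
    return GeneResult(gene_id=gene_id, n_snps=int(Z.shape[1]),
                      n_pcs_retained=k, statistic=float(lrt),
                      p=max(p, np.finfo(float).tiny))


def read_bed_annotation(path) -> pd.DataFrame:
    """Gene intervals from a BED file (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValueError("BED annotation needs at least chrom/start/end/name")
    out = df.iloc[:, :4].copy()
    out.columns = ["chrom", "start", "end", "id"]
    out["strand"] = df.iloc[:, 5] if df.shape[1] >= 6 else "+"
    return out


def read_gff_genes(path, feature: str = "gene") -> pd.DataFrame:
    """Gene intervals from a GFF3 file (1-based inclusive, converted to BED
    half-open coordinates)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end", "score",
                            "strand", "frame", "attributes"])
    df = df[df["type"] == feature].copy()

    def _gene_id(attrs: str) -> str:
        for part in str(attrs).split(";"):
            key, _, val = part.strip().partition("=")
            if key in ("ID", "gene_id", "Name"):
                return val
        return str(attrs)

    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"].astype(int) - 1,
            "end": df["end"].astype(int),
            "id": df["attributes"].map(_gene_id),
            "strand": df["strand"],
        }
    )


def map_snps_to_genes(variants: pd.DataFrame, annotation: pd.DataFrame,
                      flank: int = 10_000) -> pd.DataFrame:
    """Assign SNPs to every gene whose flank-extended interval contains them.

    Annotation intervals follow the BED convention (0-based half-open);
    SNP positions are 1-based and converted explicitly.  A SNP exactly
    ``flank`` bases from a gene edge is mapped; one base further is not.
    Emits a warning for SNP chromosomes absent from the annotation.
    """
    snp_chroms = set(np.asarray(variants["chrom"]).astype(str))
    ann_chroms = set(np.asarray(annotation["chrom"]).astype(str))
    missing = snp_chroms - ann_chroms
    if missing:
        warnings.warn(
            f"chromosomes {sorted(missing)} have no annotated genes; "
            "their SNPs stay unmapped"
        )
    pos0 = variants["pos"].to_numpy() - 1  # 0-based SNP coordinate
    chrom = np.asarray(variants["chrom"]).astype(str)
    rows = []
    for _, gene in annotation.iterrows():
        lo = int(gene["start"]) - flank
        hi = int(gene["end"]) + flank
        hit = (chrom == str(gene["chrom"])) & (pos0 >= lo) & (pos0 < hi)
        for j in np.flatnonzero(hit):
            rows.append((variants["id"].iat[j], gene["id"]))
    return pd.DataFrame(rows, columns=["snp", "gene"])
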