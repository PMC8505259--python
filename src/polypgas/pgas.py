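"""The multiple GWAS-PGAS triangulation.

SNPs consistently associated (p < alpha_poly) in all four polytoxicomania
contrasts, with LD-neighbor support (a same-clump member at
p < alpha_neighbor) in each of them, are retained; SNPs associated with
either disease-only contrast (p < alpha_disease) are subtracted.  Reported
alongside: the raw (pre-clump, no-neighbor) intersection, per-contrast
significant-set sizes, the 6x6 Jaccard matrix and exclusive
(UpSet-style) intersection counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import assoc, gqc, synthio
from .cohort import Cohort


@dataclass
class PgasParams:
    alpha_poly: float = 0.01       # consistency threshold across GWAS 1-4
    alpha_neighbor: float = 0.05   # LD-neighbor support threshold
    alpha_disease: float = 0.05    # subtraction threshold for GWAS 5-6
    clump_p1: float = 0.01         # index-variant p threshold
    clump_r2: float = 0.5
    clump_kb: float = 250.0
    require_neighbor: bool = True
    alpha_set: float = 0.05        # threshold for Jaccard/UpSet significant sets
    anchor_gwas: int = 0           # which GWAS result drives clumping (0-based)
    min_overlap: int = 30

    def __post_init__(self) -> None:
        for name in ("alpha_poly", "alpha_neighbor", "alpha_disease", "clump_p1",
                     "alpha_set"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.clump_kb <= 0:
            raise ValueError("clump_kb must be positive")


@dataclass
class Clump:
    index: int                      # positional index of the index SNP
    index_p: float
    members: list[tuple[int, float]]  # (positional index, r^2 to index)


@dataclass
class ClumpSet:
    clumps: list[Clump]
    assignment: np.ndarray          # per-SNP clump id, -1 = unassigned

    def clump_of(self, snp_idx: int) -> int:
        return int(self.assignment[snp_idx])


def ld_r2(x: np.ndarray, y: np.ndarray, min_overlap: int = 30) -> float:
    """Squared Pearson correlation of two dosage vectors (pairwise complete).

    Returns NaN for constant columns; raises when the non-missing overlap is
    below ``min_overlap``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = (x >= 0) & (y >= 0) & np.isfinite(x) & np.isfinite(y)
    if int(ok.sum()) < min_overlap:
        raise ValueError(
            f"only {int(ok.sum())} overlapping samples (minimum {min_overlap})"
        )
    a, b = x[ok], y[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump(result: pd.DataFrame, genotypes: np.ndarray,
          params: PgasParams) -> ClumpSet:
    """Greedy LD-based clumping of one GWAS result.

    Repeatedly takes the unassigned SNP with the smallest p <= clump_p1 as
    an index (ties broken by chromosome then position) and assigns as
    members every unassigned SNP within clump_kb with r^2 >= clump_r2.
    """
    p = result["P"].to_numpy(dtype=float)
    chrom = result["CHR"].to_numpy()
    pos = result["BP"].to_numpy()
    m = len(p)
    Z = gqc._standardized(genotypes, dtype=np.float64)
    n = Z.shape[0]

    order = np.lexsort((pos, chrom, p))  # p ascending, ties by (chrom, pos)
    assignment = np.full(m, -1, dtype=np.int64)
    clumps: list[Clump] = []
    half = params.clump_kb * 1000.0
    for j in order:
        if assignment[j] >= 0 or not np.isfinite(p[j]) or p[j] > params.clump_p1:
            continue
        cid = len(clumps)
        assignment[j] = cid
        near = np.flatnonzero(
            (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= half)
            & (assignment < 0)
        )
        members: list[tuple[int, float]] = []
        if near.size:
            r = (Z[:, near].T @ Z[:, j]) / n
            r2 = r * r
            for b, rr in zip(near, r2):
                if rr >= params.clump_r2:
                    assignment[b] = cid
                    members.append((int(b), float(rr)))
        clumps.append(Clump(index=int(j), index_p=float(p[j]), members=members))
    return ClumpSet(clumps=clumps, assignment=assignment)


def neighbor_support(clump_: Clump, result: pd.DataFrame,
                     alpha_neighbor: float = 0.05) -> bool:
    """True iff >= 1 clump member other than the index has p < alpha_neighbor
    in the given GWAS result.  Singleton clumps have no support."""
    p = result["P"].to_numpy(dtype=float)
    return any(
        np.isfinite(p[b]) and p[b] < alpha_neighbor for b, _ in clump_.members
    )


def jaccard_matrix(sets: Sequence[set]) -> np.ndarray:
    """Pairwise Jaccard indices; two empty sets have similarity 1 by
    convention."""
    k = len(sets)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            union = len(sets[i] | sets[j])
            out[i, j] = out[j, i] = (
                1.0 if union == 0 else len(sets[i] & sets[j]) / union
            )
    return out


def intersection_counts(sets: Sequence[set]) -> dict[tuple[int, ...], int]:
    """Exclusive (UpSet-style) intersection sizes over all nonempty subsets.

    Keys are sorted tuples of set indices; each element of the union is
    counted exactly once, under the subset of sets that contain it.
    """
    counts: dict[tuple[int, ...], int] = {}
    union = set().union(*sets) if sets else set()
    for item in union:
        pattern = tuple(i for i, s in enumerate(sets) if item in s)
        counts[pattern] = counts.get(pattern, 0) + 1
    return counts


@dataclass
class PgasReport:
    """Result of the intersection-subtraction procedure over six GWAS."""

    final_snps: list[str]
    raw_snps: list[str]
    n_final: int
    n_raw: int
    per_gwas_significant: list[int]
    jaccard: list[list[float]]
    upset: dict[str, int]
    final_clumps: list[dict]
    params: dict
    truth_summary: Optional[dict] = None
    gene_mapping: Optional[list[dict]] = None
    stage_counts: Optional[dict] = None
    seed: Optional[int] = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=2,
                          allow_nan=False, default=str)


def pgas_intersect(results: Sequence[pd.DataFrame], clumps: ClumpSet,
                   params: PgasParams) -> PgasReport:
    """Apply the intersection-subtraction criteria over six GWAS results.

    ``results`` must share one variant panel in identical order.  A
    candidate (clump index SNP) enters the final set iff its p-value is
    below ``alpha_poly`` in all of GWAS 1-4, its clump has neighbor support
    in all of GWAS 1-4 (when ``require_neighbor``), and its p-value is at or
    above ``alpha_disease`` in both GWAS 5 and 6.  SNPs with an undefined
    p-value in any contrast are never candidates.
    """
    if len(results) != 6:
        raise ValueError("pgas_intersect expects exactly six GWAS results")
    snp_ids = results[0]["SNP"].to_numpy()
    for r in results[1:]:
        if len(r) != len(snp_ids) or not np.array_equal(r["SNP"].to_numpy(),
                                                        snp_ids):
            raise ValueError("GWAS results cover different variant panels")
    P = np.column_stack([r["P"].to_numpy(dtype=float) for r in results])

    valid = np.all(np.isfinite(P), axis=1)
    poly_ok = np.all(P[:, :4] < params.alpha_poly, axis=1)
    disease_free = np.all(P[:, 4:] >= params.alpha_disease, axis=1)
    raw_mask = valid & poly_ok & disease_free
    raw_snps = [str(s) for s in snp_ids[raw_mask]]

    final_ids: list[str] = []
    final_clumps: list[dict] = []
    for cl in clumps.clumps:
        j = cl.index
        if not valid[j] or not (poly_ok[j] and disease_free[j]):
            continue
        if params.require_neighbor:
            if not all(
                neighbor_support(cl, results[g], params.alpha_neighbor)
                for g in range(4)
            ):
                continue
        final_ids.append(str(snp_ids[j]))
        final_clumps.append(
            {
                "index_snp": str(snp_ids[j]),
                "index_p": [float(P[j, g]) for g in range(6)],
                "members": [str(snp_ids[b]) for b, _ in cl.members],
            }
        )

    sig_sets = [
        set(snp_ids[np.isfinite(P[:, g]) & (P[:, g] < params.alpha_set)])
        for g in range(6)
    ]
    jac = jaccard_matrix(sig_sets)
    upset = {
        "+".join(f"GWAS{i + 1}" for i in pattern): int(count)
        for pattern, count in sorted(intersection_counts(sig_sets).items())
    }

    return PgasReport(
        final_snps=sorted(final_ids),
        raw_snps=sorted(raw_snps),
        n_final=len(final_ids),
        n_raw=len(raw_snps),
        per_gwas_significant=[len(s) for s in sig_sets],
        jaccard=[[float(v) for v in row] for row in jac],
        upset=upset,
        final_clumps=final_clumps,
        params={k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in vars(params).items()},
    )


def score_against_truth(report: PgasReport, cohort: Cohort,
                        clumps: ClumpSet,
                        disease_results: Sequence[pd.DataFrame],
                        alpha_disease: float = 0.05) -> dict:
    """Truth-recovery summary for a simulated cohort.

    A planted locus counts as recovered when it is in the final set itself
    or when the index SNP of its clump is (i.e. it is represented through an
    LD proxy at the clumping r^2).
    """
    truth = cohort.truth
    if truth is None:
        raise ValueError("cohort carries no simulation truth")
    ids = cohort.variants["id"].to_numpy()
    final = set(report.final_snps)
    id_to_idx = {s: i for i, s in enumerate(ids)}
    final_idx = [id_to_idx[s] for s in final]
    chrom = cohort.variants["chrom"].to_numpy()
    G = cohort.genotypes  # ld_r2 masks negative (missing) codes itself

    def recovered(j: int, r2_min: float = 0.5) -> bool:
        """In the final set itself, or tagged by a final index SNP at
        r^2 > r2_min (LD-proxy representation)."""
        if ids[j] in final:
            return True
        for f in final_idx:
            if chrom[f] != chrom[j]:
                continue
            r2 = ld_r2(G[:, f], G[:, j], min_overlap=10)
            if np.isfinite(r2) and r2 > r2_min:
                return True
        return False

    summary: dict = {}
    for kind in ("polytox", "disease", "pleiotropic"):
        idx = truth.planted_index(kind)
        summary[f"n_{kind}"] = int(idx.size)
        summary[f"{kind}_recovered"] = int(sum(recovered(int(j)) for j in idx))
        summary[f"{kind}_in_final"] = int(sum(ids[j] in final for j in idx))

    # subtraction semantics: pleiotropic loci must be excluded whenever their
    # disease-contrast p < alpha_disease
    pleio = truth.planted_index("pleiotropic")
    violations = 0
    for j in pleio:
        pvals = [float(r["P"].iloc[j]) for r in disease_results]
        flagged = any(np.isfinite(p) and p < alpha_disease for p in pvals)
        if flagged and ids[j] in final:
            violations += 1
    summary["pleiotropic_subtraction_violations"] = int(violations)
    return summary


@dataclass
class PipelineResult:
    report: PgasReport
    qc: gqc.QCResult
    gwas_results: list[pd.DataFrame]
    contrasts: list[assoc.ContrastAssignment]
    clumps: ClumpSet
    cohort: Cohort


def run_pgas_pipeline(
    cohort: Optional[Cohort] = None,
    sim_config: Optional[synthio.SimConfig] = None,
    qc_params: Optional[gqc.QCParams] = None,
    definitions: Optional[Sequence[assoc.PhenotypeDefinition]] = None,
    pgas_params: Optional[PgasParams] = None,
    seed: int = 0,
    annotation: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """End-to-end run: simulate/ingest -> QC -> contrasts -> 6 GWAS ->
    clump -> intersect -> report.

    Exactly one of ``cohort`` or ``sim_config`` must be given.  Fully
    seeded: a fixed seed yields a byte-identical report.
    """
    if (cohort is None) == (sim_config is None):
        raise ValueError("provide exactly one of cohort or sim_config")
    if sim_config is not None:
        cohort = synthio.simulate_phenotypes(
            synthio.simulate_genotypes(sim_config), sim_config
        )
    qc_params = qc_params or gqc.QCParams()
    pgas_params = pgas_params or PgasParams()
    definitions = list(definitions or assoc.default_contrast_grid())
    if len(definitions) != 6:
        raise ValueError("the triangulation needs exactly six contrasts")

    try:
        qc = gqc.run_qc(cohort, qc_params, seed=seed)
    except Exception as err:  # pragma: no cover - stage naming contract
        raise RuntimeError(f"QC stage failed: {err}") from err
    cc = qc.cohort

    covariates = np.column_stack(
        [(cc.samples["sex"].to_numpy() == 2).astype(float), qc.pcs]
    )

    contrasts: list[assoc.ContrastAssignment] = []
    results: list[pd.DataFrame] = []
    for d in definitions:
        try:
            ca = assoc.build_contrast(cc, d)
            res = assoc.gwas_logistic(cc, ca.y, covariates)
        except Exception as err:
            raise RuntimeError(f"association stage failed in {d.name}: {err}"
                               ) from err
        contrasts.append(ca)
        results.append(res)

    try:
        clumps = clump(results[pgas_params.anchor_gwas], cc.genotypes,
                       pgas_params)
        report = pgas_intersect(results, clumps, pgas_params)
    except Exception as err:
        raise RuntimeError(f"PGAS stage failed: {err}") from err

    report.stage_counts = dict(qc.report.stage_counts)
    report.seed = int(seed)
    if cc.truth is not None:
        report.truth_summary = score_against_truth(
            report, cc, clumps, results[4:], pgas_params.alpha_disease
        )
    if annotation is not None:
        mapping = assoc.map_snps_to_genes(
            cc.variants[cc.variants["id"].isin(report.final_snps)], annotation
        )
        report.gene_mapping = mapping.to_dict(orient="records")
    return PipelineResult(report=report, qc=qc, gwas_results=results,
                          contrasts=contrasts, clumps=clumps, cohort=cc)
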