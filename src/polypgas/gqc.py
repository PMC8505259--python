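"""Genotype and sample quality control.

Pipeline order (fixed, reported in the QC report): variant filters
(MAF, exact Hardy-Weinberg) -> LD pruning of a marker set -> relatedness
exclusion (PLINK-style method-of-moments PI_HAT) -> PCA -> ancestry-outlier
exclusion on PC1/PC2 -> PCA recomputed on the survivors.  All boundary
comparisons are strict, matching the conventions "MAF > 0.05",
"HWE p > 0.001", "PIHAT > 0.185".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.linalg import svds
from scipy.special import gammaln, logsumexp

from .cohort import Cohort


@dataclass
class QCParams:
    maf_min: float = 0.05
    hwe_p_min: float = 0.001
    pihat_max: float = 0.185
    pc1_sd: float = 3.0
    pc2_sd: float = 5.0
    n_pcs: int = 10
    prune_window_kb: float = 250.0
    prune_step: int = 5
    prune_r2_max: float = 0.5
    #: optional stricter re-prune of the marker set used for the PI_HAT
    #: relatedness estimate only (values >= prune_r2_max disable it); at
    #: desk-scale panel sizes the block count, not the marker count,
    #: limits the estimator, so the default applies no extra pruning
    relatedness_r2_max: float = 1.0
    #: long-range LD regions to drop before pruning; (chrom, start, end),
    #: BED convention (0-based half-open) against 1-based variant positions
    exclude_regions: Sequence[tuple[int, int, int]] = ()
    min_overlap_variants: int = 50

    def __post_init__(self) -> None:
        if min(self.maf_min, self.hwe_p_min, self.pihat_max) < 0:
            raise ValueError("thresholds must be positive")
        if self.pc1_sd < 1 or self.pc2_sd < 1:
            raise ValueError("PC SD multipliers must be >= 1")


@dataclass
class QCReport:
    variant_table: pd.DataFrame   # counts, MAF, HWE p, pass flag + reason
    sample_table: pd.DataFrame    # exclusion reason in {related, ancestry_outlier, none}
    stage_counts: dict            # survivors at each pipeline stage


@dataclass
class QCResult:
    cohort: Cohort                # survivors only (samples and variants)
    report: QCReport
    pcs: np.ndarray               # (n_survivors, n_pcs), recomputed post-exclusion
    pruned_variant_idx: np.ndarray  # indices (into kept variants) of the pruned set


# --- per-variant statistics ---

def allele_stats(column: np.ndarray) -> tuple[int, int, int, float]:
    """Genotype counts (n0, n1, n2) and minor allele frequency of one variant.

    Missing calls (negative codes) are excluded.  An all-missing column
    returns MAF = NaN.
    """
    column = np.asarray(column)
    n0 = int(np.sum(column == 0))
    n1 = int(np.sum(column == 1))
    n2 = int(np.sum(column == 2))
    n = n0 + n1 + n2
    if n == 0:
        return n0, n1, n2, float("nan")
    alt = (n1 + 2 * n2) / (2 * n)
    return n0, n1, n2, min(alt, 1.0 - alt)


def genotype_counts(geno: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (n0, n1, n2) per variant column."""
    n0 = (geno == 0).sum(axis=0)
    n1 = (geno == 1).sum(axis=0)
    n2 = (geno == 2).sum(axis=0)
    return n0, n1, n2


def hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test (two-sided, Wigginton-style).

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one.
    Monomorphic variants return p = 1 by convention.
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("no observed genotypes")
    rare = 2 * min(n0, n2) + n1
    if rare == 0:
        return 1.0
    return _hwe_exact_from_rare(n, rare, n1)


def _hwe_exact_from_rare(n: int, rare: int, het_obs: int) -> float:
    # support: heterozygote counts with the parity of the rare-allele count
    h = np.arange(rare % 2, min(rare, 2 * n - rare) + 1, 2)
    # log P(h) up to a constant: conditional distribution of het count given
    # allele counts: P(h) prop. 2^h * n! / (n_AA! h! n_aa!)
    n_rr = (rare - h) // 2
    n_cc = n - n_rr - h
    logp = h * np.log(2.0) - gammaln(n_rr + 1) - gammaln(h + 1) - gammaln(n_cc + 1)
    logp -= logsumexp(logp)
    obs = logp[np.searchsorted(h, het_obs)]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-10])))
    return min(p, 1.0)


def hwe_exact_many(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Vector of exact HWE p-values (one call of :func:`hwe_exact` per variant)."""
    out = np.ones(len(n0))
    for j in range(len(n0)):
        tot = n0[j] + n1[j] + n2[j]
        if tot == 0:
            out[j] = np.nan
        else:
            out[j] = hwe_exact(int(n0[j]), int(n1[j]), int(n2[j]))
    return out


def filter_variants(cohort: Cohort, params: QCParams) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep variants with MAF > maf_min and HWE p > hwe_p_min (strict).

    Returns (kept positional indices in original order, per-variant report).
    """
    g = cohort.genotypes
    n0, n1, n2 = genotype_counts(g)
    tot = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = (n1 + 2 * n2) / (2 * np.maximum(tot, 1))
    maf = np.minimum(alt, 1 - alt)
    maf = np.where(tot > 0, maf, np.nan)
    hwe_p = hwe_exact_many(n0, n1, n2)

    passed = np.zeros(len(maf), dtype=bool)
    reason = np.full(len(maf), "", dtype=object)
    all_missing = tot == 0
    low_maf = ~all_missing & ~(maf > params.maf_min)
    hwe_fail = ~all_missing & ~low_maf & ~(hwe_p > params.hwe_p_min)
    passed = ~(all_missing | low_maf | hwe_fail)
    reason[all_missing] = "all_missing"
    reason[low_maf] = "maf"
    reason[hwe_fail] = "hwe"
    report = pd.DataFrame(
        {
            "id": cohort.variants["id"],
            "n0": n0,
            "n1": n1,
            "n2": n2,
            "maf": maf,
            "hwe_p": hwe_p,
            "pass": passed,
            "reason": reason,
        }
    )
    return np.flatnonzero(passed), report


# --- LD pruning ---

def _standardized(geno: np.ndarray, dtype=np.float32) -> np.ndarray:
    """Mean-imputed, centred, unit-variance dosage matrix (columns)."""
    g = geno.astype(dtype)
    miss = geno < 0
    g[miss] = np.nan
    mean = np.nanmean(g, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0).astype(dtype)
    idx = np.where(miss)
    g[idx] = mean[idx[1]]
    g -= mean
    sd = g.std(axis=0)
    sd[sd == 0] = 1.0
    return g / sd


def read_exclude_regions_bed(path) -> list[tuple[int, int, int]]:
    """Long-range LD regions from a BED file (0-based half-open) as
    (chrom, start, end) tuples for :attr:`QCParams.exclude_regions`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    chroms = df["chrom"].astype(str).str.removeprefix("chr").astype(int)
    return list(zip(chroms, df["start"].astype(int), df["end"].astype(int)))


def _in_regions(chrom: np.ndarray, pos: np.ndarray,
                regions: Sequence[tuple[int, int, int]]) -> np.ndarray:
    hit = np.zeros(len(pos), dtype=bool)
    for (c, start, end) in regions:
        hit |= (chrom == c) & (pos - 1 >= start) & (pos - 1 < end)
    return hit


def ld_prune(cohort: Cohort, params: QCParams) -> np.ndarray:
    """Greedy windowed LD pruning; returns surviving positional indices.

    Variants inside ``exclude_regions`` are removed first.  Windows of
    ``prune_window_kb`` slide by ``prune_step`` variants; within a window,
    for every surviving pair with r^2 > ``prune_r2_max`` the lower-MAF
    member is removed (tie: the lower index is kept).
    """
    chrom = cohort.variants["chrom"].to_numpy()
    pos = cohort.variants["pos"].to_numpy()
    m = len(pos)
    alive = ~_in_regions(chrom, pos, params.exclude_regions)
    cand = np.flatnonzero(alive)
    if cand.size == 0:
        return cand

    Z = _standardized(cohort.genotypes[:, cand])
    n = Z.shape[0]
    sub_chrom = chrom[cand]
    sub_pos = pos[cand]
    _, _, _, mafs = zip(*(allele_stats(cohort.genotypes[:, j]) for j in cand))
    mafs = np.asarray(mafs)

    window_bp = params.prune_window_kb * 1000.0
    mm = cand.size
    # window end (inclusive) per variant: same chromosome, within window_bp
    ends = np.empty(mm, dtype=np.int64)
    for c in np.unique(sub_chrom):
        idx = np.flatnonzero(sub_chrom == c)
        p = sub_pos[idx]
        ends[idx] = idx[0] + np.searchsorted(p, p + window_bp, side="right") - 1
    band = int(np.max(ends - np.arange(mm))) if mm else 0

    r2 = np.full((mm, band), np.nan, dtype=np.float32)
    chunk = 512
    for s in range(0, mm, chunk):
        e = min(s + chunk, mm)
        hi = min(mm, ends[e - 1] + 1)
        block = (Z[:, s:e].T @ Z[:, s:hi]) / n
        for j in range(s, e):
            w = ends[j] - j
            if w > 0:
                r2[j, :w] = block[j - s, j - s + 1: j - s + 1 + w] ** 2

    sub_alive = np.ones(mm, dtype=bool)
    for start in range(0, mm, params.prune_step):
        stop = ends[start]
        for a in range(start, stop + 1):
            if not sub_alive[a]:
                continue
            w = ends[a] - a
            if w <= 0:
                continue
            seg = r2[a, : min(w, stop - a)]
            for d in np.flatnonzero(seg > params.prune_r2_max):
                b = a + 1 + d
                if not sub_alive[a]:
                    break
                if not sub_alive[b]:
                    continue
                if mafs[a] > mafs[b] or (mafs[a] == mafs[b]):
                    sub_alive[b] = False  # keep higher MAF; tie keeps lower index
                else:
                    sub_alive[a] = False
    return cand[sub_alive]


# --- relatedness ---

def _ibs_expectations(freqs: np.ndarray,
                      allele_counts: Optional[tuple[np.ndarray, np.ndarray]] = None
                      ) -> tuple[float, float, float, float, float]:
    """Summed IBS-state probabilities under IBD 0/1 across variants.

    When ``allele_counts`` (per-variant A1 allele count X, total called
    allele count T) is given, frequency monomials are replaced by their
    unbiased falling-factorial estimators (the finite-sample correction of
    the PLINK method of moments); otherwise plug-in products of ``freqs``
    are used.
    """
    if allele_counts is None:
        p = np.asarray(freqs, dtype=np.float64)
        q = 1.0 - p
        p2q2 = p**2 * q**2
        p3q = p**3 * q
        pq3 = p * q**3
        p4 = p**4
        q4 = q**4
        p2q = p**2 * q
        pq2 = p * q**2
        p3 = p**3
        q3 = q**3
    else:
        x, t = (np.asarray(a, dtype=np.float64) for a in allele_counts)
        y = t - x

        def ff(a: np.ndarray, k: int) -> np.ndarray:
            out = np.ones_like(a)
            for i in range(k):
                out = out * (a - i)
            return out

        d2 = ff(t, 2)
        d3 = ff(t, 3)
        d4 = ff(t, 4)
        with np.errstate(invalid="ignore", divide="ignore"):
            p2q2 = ff(x, 2) * ff(y, 2) / d4
            p3q = ff(x, 3) * y / d4
            pq3 = x * ff(y, 3) / d4
            p4 = ff(x, 4) / d4
            q4 = ff(y, 4) / d4
            p2q = ff(x, 2) * y / d3
            pq2 = x * ff(y, 2) / d3
            p3 = ff(x, 3) / d3
            q3 = ff(y, 3) / d3
        for arr in (p2q2, p3q, pq3, p4, q4, p2q, pq2, p3, q3):
            arr[~np.isfinite(arr)] = 0.0
    s0_ibs0 = float(np.sum(2 * p2q2))
    s0_ibs1 = float(np.sum(4 * p3q + 4 * pq3))
    s0_ibs2 = float(np.sum(p4 + q4 + 4 * p2q2))
    s1_ibs1 = float(np.sum(2 * p2q + 2 * pq2))
    s1_ibs2 = float(np.sum(p3 + q3 + p2q + pq2))
    return s0_ibs0, s0_ibs1, s0_ibs2, s1_ibs1, s1_ibs2


def _pihat_from_ibs(n0, n1, n2, valid, m_total, expect) -> np.ndarray:
    s0_ibs0, s0_ibs1, s0_ibs2, s1_ibs1, s1_ibs2 = expect
    scale = valid / m_total
    with np.errstate(invalid="ignore", divide="ignore"):
        z0 = n0 / (s0_ibs0 * scale)
        z1 = (n1 - z0 * s0_ibs1 * scale) / (s1_ibs1 * scale)
        z2 = (n2 - z0 * s0_ibs2 * scale - z1 * s1_ibs2 * scale) / valid
    z0 = np.clip(z0, 0.0, 1.0)
    z1 = np.clip(z1, 0.0, 1.0)
    z2 = np.clip(z2, 0.0, 1.0)
    tot = z0 + z1 + z2
    with np.errstate(invalid="ignore", divide="ignore"):
        z1 = np.where(tot > 0, z1 / tot, 0.0)
        z2 = np.where(tot > 0, z2 / tot, 0.0)
    return np.clip(z2 + 0.5 * z1, 0.0, 1.0)


def ibd_pihat(gi: np.ndarray, gj: np.ndarray, freqs: np.ndarray,
              min_overlap: int = 50) -> float:
    """Method-of-moments PI_HAT for one sample pair.

    ``freqs`` are A1 allele frequencies estimated from the analysis sample.
    Raises if fewer than ``min_overlap`` variants are non-missing in both.
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    ok = (gi >= 0) & (gj >= 0)
    if int(ok.sum()) < min_overlap:
        raise ValueError(
            f"only {int(ok.sum())} overlapping non-missing variants "
            f"(minimum {min_overlap}); PI_HAT undefined"
        )
    a, b = gi[ok], gj[ok]
    diff = np.abs(a - b)
    n_ibs0 = int(np.sum(diff == 2))
    n_ibs1 = int(np.sum(diff == 1))
    n_ibs2 = int(np.sum(diff == 0))
    expect = _ibs_expectations(np.asarray(freqs)[ok])
    out = _pihat_from_ibs(
        np.array([n_ibs0], dtype=float),
        np.array([n_ibs1], dtype=float),
        np.array([n_ibs2], dtype=float),
        np.array([float(ok.sum())]),
        float(ok.sum()),
        expect,
    )
    return float(out[0])


def pihat_matrix(geno: np.ndarray, freqs: Optional[np.ndarray] = None) -> np.ndarray:
    """All-pairs PI_HAT via indicator matmuls.

    IBS expectations use the finite-sample-corrected moment estimators with
    allele counts taken from ``geno`` itself, scaled per pair by the
    valid-variant fraction.  ``freqs`` is accepted for API symmetry but the
    counts drive the correction.
    """
    n, m = geno.shape
    nc0, nc1, nc2 = genotype_counts(geno)
    x = (nc1 + 2 * nc2).astype(np.float64)
    t = (2 * (nc0 + nc1 + nc2)).astype(np.float64)
    i0 = (geno == 0).astype(np.float32)
    i1 = (geno == 1).astype(np.float32)
    i2 = (geno == 2).astype(np.float32)
    valid_mask = (geno >= 0).astype(np.float32)
    n_ibs2 = i0 @ i0.T + i1 @ i1.T + i2 @ i2.T
    n_ibs0 = i0 @ i2.T + i2 @ i0.T
    valid = valid_mask @ valid_mask.T
    n_ibs1 = valid - n_ibs2 - n_ibs0
    expect = _ibs_expectations(None, allele_counts=(x, t))
    pihat = _pihat_from_ibs(
        n_ibs0.astype(np.float64),
        n_ibs1.astype(np.float64),
        n_ibs2.astype(np.float64),
        valid.astype(np.float64),
        float(m),
        expect,
    )
    np.fill_diagonal(pihat, 1.0)
    return pihat


def resolve_relatedness(pairs: Sequence[tuple[int, int, float]],
                        diagnosis: Sequence[str], seed: int,
                        pihat_max: float = 0.185) -> list[tuple[int, str]]:
    """Exclusion list for related pairs (PI_HAT above the threshold).

    Pairs are processed greedily in order of descending PI_HAT.  In a
    patient/healthy pair the healthy member is excluded (priority to patient
    samples); same-label pairs lose a uniformly random member under the
    given seed.  Returns ``[(sample_index, "related"), ...]``.
    """
    rng = np.random.default_rng([seed, 0x1BD])
    flagged = [p for p in pairs if p[2] > pihat_max]
    flagged.sort(key=lambda t: (-t[2], t[0], t[1]))
    excluded: set[int] = set()
    diagnosis = list(diagnosis)
    for i, j, _ in flagged:
        if i in excluded or j in excluded:
            continue
        di, dj = diagnosis[i], diagnosis[j]
        if di == "patient" and dj != "patient":
            excluded.add(j)
        elif dj == "patient" and di != "patient":
            excluded.add(i)
        else:
            excluded.add(i if rng.random() < 0.5 else j)
    return [(i, "related") for i in sorted(excluded)]


# --- PCA and ancestry outliers ---

def pca_samples(geno: np.ndarray, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Top principal components of the standardized genotype matrix.

    Missing genotypes are mean-imputed per variant before centring and
    scaling.  Returns (scores, loadings); each component's sign is fixed so
    that its largest-|loading| entry is positive.
    """
    Z = _standardized(geno, dtype=np.float64)
    keep = Z.std(axis=0) > 0
    Z = Z[:, keep]
    if n_pcs >= min(Z.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds the matrix rank bound {min(Z.shape)}")
    v0 = np.ones(min(Z.shape))
    U, S, Vt = svds(Z, k=n_pcs, tol=0, v0=v0)
    order = np.argsort(S)[::-1]
    U, S, Vt = U[:, order], S[order], Vt[order]
    flip = np.sign(Vt[np.arange(n_pcs), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    scores = U * S * flip
    return scores, (Vt.T * flip)


def ancestry_outliers(pc1: np.ndarray, pc2: np.ndarray,
                      params: QCParams) -> np.ndarray:
    """Indices of ancestry outliers: |PCk - mean| strictly > multiplier * SD."""
    pc1 = np.asarray(pc1, dtype=float)
    pc2 = np.asarray(pc2, dtype=float)
    if len(pc1) < 3:
        raise ValueError("ancestry-outlier detection needs at least 3 samples")
    out1 = np.abs(pc1 - pc1.mean()) > params.pc1_sd * pc1.std()
    out2 = np.abs(pc2 - pc2.mean()) > params.pc2_sd * pc2.std()
    return np.flatnonzero(out1 | out2)


# --- full QC pipeline ---

def run_qc(cohort: Cohort, params: QCParams, seed: int = 0) -> QCResult:
    """Run the full QC pipeline and return survivors, report and final PCs."""
    stage = {"samples_initial": cohort.n_samples,
             "variants_initial": cohort.n_variants}

    kept_var, variant_report = filter_variants(cohort, params)
    stage["variants_pass"] = int(kept_var.size)
    c1 = cohort.subset(variant_idx=kept_var)

    pruned = ld_prune(c1, params)
    stage["pruned_markers"] = int(pruned.size)
    g_pruned = c1.genotypes[:, pruned]

    # relatedness on the pruned marker set (optionally re-pruned stricter)
    if params.relatedness_r2_max < params.prune_r2_max:
        strict = dataclasses.replace(
            params, prune_r2_max=params.relatedness_r2_max, exclude_regions=()
        )
        c_pruned = c1.subset(variant_idx=pruned)
        ibd_idx = ld_prune(c_pruned, strict)
        g_ibd = c_pruned.genotypes[:, ibd_idx]
    else:
        g_ibd = g_pruned
    stage["relatedness_markers"] = int(g_ibd.shape[1])
    ph = pihat_matrix(g_ibd)
    iu = np.triu_indices(cohort.n_samples, k=1)
    above = ph[iu] > params.pihat_max
    pairs = [(int(i), int(j), float(v)) for i, j, v in
             zip(iu[0][above], iu[1][above], ph[iu][above])]
    diagnosis = c1.samples["diagnosis"].tolist()
    related = resolve_relatedness(pairs, diagnosis, seed, params.pihat_max)
    related_idx = np.array([i for i, _ in related], dtype=np.int64)

    reason = np.full(cohort.n_samples, "none", dtype=object)
    reason[related_idx] = "related"
    survivors = np.flatnonzero(reason == "none")
    stage["samples_after_related"] = int(survivors.size)

    # PCA on survivors, ancestry outliers on PC1/PC2
    scores, _ = pca_samples(g_pruned[survivors], params.n_pcs)
    out_local = ancestry_outliers(scores[:, 0], scores[:, 1], params)
    reason[survivors[out_local]] = "ancestry_outlier"
    survivors = np.flatnonzero(reason == "none")
    stage["samples_after_ancestry"] = int(survivors.size)

    # recompute PCs on the final sample set; these feed association
    final_scores, _ = pca_samples(g_pruned[survivors], params.n_pcs)

    sample_report = pd.DataFrame(
        {"fid": cohort.samples["fid"], "iid": cohort.samples["iid"],
         "exclusion_reason": reason}
    )
    report = QCReport(variant_table=variant_report, sample_table=sample_report,
                      stage_counts=stage)
    return QCResult(
        cohort=c1.subset(sample_idx=survivors),
        report=report,
        pcs=final_scores,
        pruned_variant_idx=pruned,
    )
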