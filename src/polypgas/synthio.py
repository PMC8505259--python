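"""Synthetic cohort generation.

Emulates the statistical structure of a deeply phenotyped schizophrenia
case/control genetics cohort: biallelic autosomal SNPs with a configurable
MAF spectrum, block LD (latent-uniform copying), population stratification
(Balding-Nichols), sex, disease status, per-drug-class use with
preadult/adult onset driven by a shared liability, and six binary
environmental risk factors.

Planted loci come in three classes:

``polytox``
    affect only the shared drug-use liability,
``disease``
    affect only the disease liability,
``pleiotropic``
    affect both.

Effect sizes are specified as allelic odds ratios.  For the disease
phenotype the log odds ratio enters the logistic liability directly; for
the derived polytoxicomania phenotype (>= 3 of ``n_drug_classes`` drug
classes used) the liability-scale coefficient is calibrated numerically so
that the implied marginal allelic odds ratio on lifetime polytoxicomania
matches the configured value (the several-of-K threshold sharpens the link
function, so a naive ``log(OR)`` would overshoot).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort, SimTruth

DRUG_CLASS_NAMES = [
    "cocaine",
    "opioids",
    "hallucinogens",
    "amphetamines",
    "ecstasy",
    "barbiturates",
    "benzodiazepines",
    "inhalants",
]

RISK_NAMES = [
    "urbanicity",
    "cannabis",
    "alcohol",
    "physical_abuse",
    "sexual_abuse",
    "migration",
]

#: Observed prevalences of the six preadult environmental risks in the
#: reference patient cohort (fractions).
DEFAULT_RISK_PREVALENCES = (0.431, 0.383, 0.200, 0.165, 0.133, 0.108)

PlantedKind = Literal["polytox", "disease", "pleiotropic"]


@dataclass(frozen=True)
class PlantedLocus:
    """A variant with a known effect, planted into the simulation."""

    kind: PlantedKind
    maf: float
    odds_ratio: float

    def __post_init__(self) -> None:
        if self.kind not in ("polytox", "disease", "pleiotropic"):
            raise ValueError(f"unknown planted-locus kind {self.kind!r}")
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("planted MAF must be in (0, 0.5]")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults follow the reference study design where stated (sample sizes,
    risk prevalences, male fraction, eight drug classes) and otherwise use
    desk-scale values documented in the methods note.
    """

    n_patients: int = 1718
    n_controls: int = 2111
    n_snps: int = 5000
    n_subpops: int = 2
    fst: float = 0.005
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_len: int = 20
    ld_decay: float = 0.85
    n_drug_classes: int = 8
    planted_loci: Sequence[PlantedLocus] = ()
    risk_prevalences: Sequence[float] = DEFAULT_RISK_PREVALENCES
    env_effect: float = 0.35
    missing_rate: float = 0.002
    seed: int = 0
    # emulation knobs (not part of the study design, documented defaults)
    male_fraction: float = 0.66
    preadult_prob: float = 0.8
    polytox_rate: float = 0.21

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0 or self.n_snps <= 0:
            raise ValueError("cohort dimensions must be positive")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if not 0.0 <= self.fst <= 0.5:
            raise ValueError("fst must lie in [0, 0.5]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if self.ld_block_len < 1:
            raise ValueError("ld_block_len must be >= 1")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must lie in [0, 1)")
        for name in ("missing_rate", "male_fraction", "preadult_prob", "polytox_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.planted_loci) > self.n_snps:
            raise ValueError("more planted loci than SNPs")
        if any(not 0.0 <= p <= 1.0 for p in self.risk_prevalences):
            raise ValueError("risk prevalences must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_patients + self.n_controls


def _drug_class_names(k: int) -> list[str]:
    names = list(DRUG_CLASS_NAMES[:k])
    names += [f"class{i + 1}" for i in range(len(names), k)]
    return names


def _risk_names(k: int) -> list[str]:
    names = list(RISK_NAMES[:k])
    names += [f"risk{i + 1}" for i in range(len(names), k)]
    return names


def _assign_chromosomes(n_snps: int, block_len: int) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic chromosome labels and sorted 1-based positions (1 kb grid).

    Blocks never straddle a chromosome boundary so that LD stays
    intra-chromosomal.
    """
    block_id = np.arange(n_snps) // block_len
    n_blocks = block_id[-1] + 1
    n_chrom = min(22, n_blocks)
    chrom_of_block = 1 + (np.arange(n_blocks) * n_chrom) // n_blocks
    chrom = chrom_of_block[block_id]
    pos = np.empty(n_snps, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = (np.arange(idx.size) + 1) * 1000
    return chrom.astype(np.int16), pos


def simulate_genotypes(config: SimConfig) -> Cohort:
    """Draw a genotyped cohort without phenotypes.

    Ancestral allele frequencies are uniform over ``maf_range``;
    subpopulation frequencies follow the Balding-Nichols model with the
    configured Fst; within-block LD is induced by a latent-uniform copying
    chain: haplotype ``h`` at SNP ``j`` reuses the latent uniform of SNP
    ``j - 1`` with probability ``ld_decay`` (never across block or
    chromosome boundaries) and thresholds it at the subpopulation allele
    frequency.  Copying preserves the marginal frequency of every SNP, so
    Hardy-Weinberg holds within subpopulations regardless of ``ld_decay``.
    Missing calls are completely at random at ``missing_rate``.
    """
    rng = np.random.default_rng([config.seed, 0x5EED])
    n, m = config.n_samples, config.n_snps

    # Ancestral frequencies: one base frequency per LD block with a small
    # per-SNP jitter.  SNPs in strong LD necessarily have similar allele
    # frequencies (a shared copying history caps r^2 by the frequency
    # mismatch), so block-level frequencies are what makes ld_decay an
    # effective r^2 dial.
    block_len = config.ld_block_len
    block_id = np.arange(m) // block_len
    n_blocks = int(block_id[-1]) + 1
    lo, hi = config.maf_range
    base = rng.uniform(lo, hi, size=n_blocks)
    anc = np.clip(base[block_id] + rng.normal(0.0, 0.02, size=m), lo, hi)

    # Planted loci occupy the central SNP of distinct LD blocks, with their
    # ancestral frequency pinned to the configured MAF (and the block base
    # moved there so that LD neighbors are informative proxies).
    planted_class = np.array(["null"] * m, dtype=object)
    if config.planted_loci:
        if len(config.planted_loci) > n_blocks:
            raise ValueError("more planted loci than LD blocks")
        blocks = rng.choice(n_blocks, size=len(config.planted_loci), replace=False)
        for locus, b in zip(config.planted_loci, blocks):
            in_block = np.flatnonzero(block_id == b)
            anc[in_block] = np.clip(
                locus.maf + rng.normal(0.0, 0.02, size=in_block.size), lo, hi
            )
            j = int(in_block[min(block_len // 2, in_block.size - 1)])
            anc[j] = locus.maf
            planted_class[j] = locus.kind

    if config.fst > 0 and config.n_subpops > 1:
        a = anc * (1 - config.fst) / config.fst
        b = (1 - anc) * (1 - config.fst) / config.fst
        sub_freq = rng.beta(a, b, size=(config.n_subpops, m))
        sub_freq = np.clip(sub_freq, 1e-4, 1 - 1e-4)
    else:
        sub_freq = np.broadcast_to(anc, (config.n_subpops, m)).copy()

    subpop = np.arange(n) % config.n_subpops
    chrom, pos = _assign_chromosomes(m, block_len)

    # Latent-uniform copying chain per haplotype.
    fresh_vals = rng.random(size=(2 * n, m))
    copy_mask = rng.random(size=(2 * n, m)) < config.ld_decay
    block_start = (np.arange(m) % block_len) == 0
    copy_mask[:, block_start] = False
    src = np.where(~copy_mask, np.arange(m)[None, :], -1)
    src = np.maximum.accumulate(src, axis=1)
    latent = np.take_along_axis(fresh_vals, src, axis=1)

    hap_freq = sub_freq[np.repeat(subpop, 2), :]
    haplo = latent < hap_freq
    geno = (haplo[0::2, :].astype(np.int8) + haplo[1::2, :].astype(np.int8))

    if config.missing_rate > 0:
        geno[rng.random(size=geno.shape) < config.missing_rate] = -1

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "id": [f"snp{j + 1:06d}" for j in range(m)],
            "pos": pos,
            "a1": "A",  # counted (alternate) allele
            "a2": "G",
            "anc_freq": anc,
            "planted": planted_class,
        }
    )
    samples = pd.DataFrame(
        {
            "fid": [f"F{i + 1}" for i in range(n)],
            "iid": [f"S{i + 1}" for i in range(n)],
            "sex": np.zeros(n, dtype=np.int8),
            "diagnosis": ["unknown"] * n,
            "subpop": subpop.astype(np.int16),
        }
    )
    return Cohort(geno, variants, samples)


def _imputed_dosage(geno: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Float dosages of selected variant columns, missing -> column mean."""
    g = geno[:, cols].astype(np.float64)
    miss = geno[:, cols] < 0
    g[miss] = np.nan
    mean = np.nanmean(g, axis=0)
    mean = np.where(np.isfinite(mean), mean, 0.0)
    ix = np.where(miss)
    g[ix] = mean[ix[1]]
    return g


def _frac_logit_slope(g: np.ndarray, p: np.ndarray, n_iter: int = 40) -> float:
    """Slope of a two-parameter logistic fit of fractional outcomes on g."""
    beta = np.zeros(2)
    X = np.column_stack([np.ones_like(g), g])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = X.T @ (p - mu)
        hess = (X * w[:, None]).T @ X
        try:
            delta = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta += delta
        if np.max(np.abs(delta)) < 1e-10:
            break
    return float(beta[1])


def _polytox_prob(s: np.ndarray, thresh: float, n_classes: int) -> np.ndarray:
    """P(>= 3 of ``n_classes`` class liabilities exceed ``thresh`` | shared s)."""
    p_use = stats.norm.cdf(s - thresh)
    return stats.binom.sf(2, n_classes, p_use)


def _calibrate_liability(
    g_eff: np.ndarray,
    target_log_or: np.ndarray,
    env_term: np.ndarray,
    n_classes: int,
    rate: float,
) -> tuple[np.ndarray, float]:
    """Solve per-locus liability coefficients and the class-use threshold.

    Finds ``kappa`` such that the marginal allelic log-odds of lifetime
    polytoxicomania per planted locus equals ``target_log_or``, and a common
    class threshold holding the marginal polytoxicomania rate at ``rate``.
    Fixed point over loci with the threshold re-solved each round.
    """
    kappa = target_log_or.copy()
    # centred dosages keep the liability scale anchored at zero regardless of
    # the number of planted loci (centring leaves every slope unchanged)
    g_eff = g_eff - g_eff.mean(axis=0)

    def solve_thresh(score: np.ndarray) -> float:
        lo = float((score + env_term).min()) - 10.0
        hi = float((score + env_term).max()) + 10.0

        def f(t: float) -> float:
            return float(np.mean(_polytox_prob(score + env_term, t, n_classes)) - rate)

        return optimize.brentq(f, lo, hi, xtol=1e-10)

    thresh = 0.0
    for _ in range(3):
        score = g_eff @ kappa
        thresh = solve_thresh(score)
        for j in range(g_eff.shape[1]):
            if target_log_or[j] == 0.0:
                kappa[j] = 0.0
                continue
            s_minus = score - g_eff[:, j] * kappa[j]

            def f(k: float, j=j, s_minus=s_minus) -> float:
                p = _polytox_prob(s_minus + k * g_eff[:, j] + env_term, thresh,
                                  n_classes)
                return _frac_logit_slope(g_eff[:, j], p) - target_log_or[j]

            hi = abs(target_log_or[j]) * 3 + 1.0
            lo, hi = (0.0, hi) if target_log_or[j] > 0 else (-hi, 0.0)
            try:
                kappa[j] = optimize.brentq(f, lo, hi, xtol=1e-8)
            except ValueError:
                kappa[j] = target_log_or[j]  # bracket failure: fall back
            score = s_minus + g_eff[:, j] * kappa[j]
        thresh = solve_thresh(score)
    return kappa, thresh


def simulate_phenotypes(cohort: Cohort, config: SimConfig) -> Cohort:
    """Attach sex, environmental risks, disease status and drug-use history.

    Disease status is assigned by ranking a logistic-noise liability built
    from disease and pleiotropic loci and declaring the top ``n_patients``
    samples patients (case/control ascertainment preserves the logistic
    slope, i.e. the planted allelic odds ratios).  Drug use follows the
    shared-liability threshold model described in the module docstring; drug
    use is simulated independently of diagnosis so that polytox-specific
    loci carry no disease signal.  Returns a new cohort carrying a
    :class:`~polypgas.cohort.SimTruth`.
    """
    if cohort.n_samples != config.n_samples:
        raise ValueError(
            f"cohort has {cohort.n_samples} samples, config expects {config.n_samples}"
        )
    rng = np.random.default_rng([config.seed, 0xA11])
    n = cohort.n_samples
    geno = cohort.genotypes
    planted = cohort.variants["planted"].to_numpy()

    samples = cohort.samples.copy()
    samples["sex"] = np.where(rng.random(n) < config.male_fraction, 1, 2).astype(np.int8)

    risk_names = _risk_names(len(config.risk_prevalences))
    risks = np.empty((n, len(risk_names)), dtype=np.int8)
    for k, prev in enumerate(config.risk_prevalences):
        risks[:, k] = rng.random(n) < prev
    for k, name in enumerate(risk_names):
        samples[f"risk_{name}"] = risks[:, k]
    risk_count = risks.sum(axis=1)
    samples["n_risks"] = risk_count

    # --- disease liability and case/control status ---
    dis_cols = np.flatnonzero(np.isin(planted, ["disease", "pleiotropic"]))
    dis_score = np.zeros(n)
    if dis_cols.size:
        g_dis = _imputed_dosage(geno, dis_cols)
        dis_score = g_dis @ _match_effects(cohort, ("disease", "pleiotropic"),
                                           config)
    disease_liab = dis_score + rng.logistic(size=n)
    patient = np.zeros(n, dtype=bool)
    patient[np.argsort(-disease_liab, kind="stable")[: config.n_patients]] = True
    samples["diagnosis"] = np.where(patient, "patient", "healthy")
    age = np.where(patient, rng.normal(40.3, 13.1, n), rng.normal(33.7, 12.2, n))
    samples["age"] = np.clip(age, 18, 85).round(1)

    # --- shared drug-use liability ---
    poly_cols = np.flatnonzero(np.isin(planted, ["polytox", "pleiotropic"]))
    env_term = config.env_effect * risk_count.astype(float)
    n_classes = config.n_drug_classes
    if poly_cols.size:
        g_poly = _imputed_dosage(geno, poly_cols)
        g_poly = g_poly - g_poly.mean(axis=0)
        target = _match_effects(cohort, ("polytox", "pleiotropic"), config)
        kappa, thresh = _calibrate_liability(g_poly, target, env_term,
                                             n_classes, config.polytox_rate)
        shared = g_poly @ kappa + env_term
    else:
        def f(t: float) -> float:
            return float(np.mean(_polytox_prob(env_term, t, n_classes))
                         - config.polytox_rate)

        thresh = optimize.brentq(f, -20.0, 20.0, xtol=1e-10)
        shared = env_term

    class_names = _drug_class_names(n_classes)
    noise = rng.standard_normal((n, n_classes))
    used = shared[:, None] + noise > thresh
    preadult_draw = rng.random((n, n_classes)) < config.preadult_prob
    onset = np.where(used, np.where(preadult_draw, "preadult", "adult"), "never")
    onsets = pd.DataFrame(onset, columns=class_names)

    n_lifetime = used.sum(axis=1)
    n_preadult = (onset == "preadult").sum(axis=1)
    for name in class_names:
        samples[f"onset_{name}"] = onsets[name].to_numpy()
    samples["n_classes_lifetime"] = n_lifetime
    samples["n_classes_preadult"] = n_preadult
    group = np.where(
        n_preadult >= 3, "preadult", np.where(n_lifetime >= 3, "adult", "non_polytox")
    )
    samples["consumption_group"] = group

    truth = SimTruth(
        variant_class=pd.Series(planted, name="variant_class"),
        drug_liability=shared,
        disease_liability=disease_liab,
        onsets=onsets,
    )
    return Cohort(geno, cohort.variants, samples, truth)


def _match_effects(cohort: Cohort, kinds: tuple[str, ...],
                   config: SimConfig) -> np.ndarray:
    """Log odds ratios of planted loci of the given kinds, in column order.

    Loci of the same kind are matched to genome columns in planting order
    (columns of a kind appear in the order their loci were planted because
    blocks were drawn once and zipped with the locus list).
    """
    planted = cohort.variants["planted"].to_numpy()
    cols = np.flatnonzero(np.isin(planted, kinds))
    # Loci of one kind were planted at rng-chosen blocks, so genome order
    # need not equal planting order; match by the pinned ancestral frequency
    # and fall back to planting order when frequencies are not unique.
    out = np.empty(cols.size)
    anc = cohort.variants["anc_freq"].to_numpy()
    loci_by_kind = {k: [l for l in config.planted_loci if l.kind == k] for k in kinds}
    used = {k: [False] * len(loci_by_kind[k]) for k in kinds}
    for i, j in enumerate(cols):
        k = planted[j]
        cands = loci_by_kind[k]
        pick = None
        for idx, l in enumerate(cands):
            if not used[k][idx] and abs(l.maf - anc[j]) < 1e-9:
                pick = idx
                break
        if pick is None:  # frequencies not unique; take first unused
            pick = next(idx for idx in range(len(cands)) if not used[k][idx])
        used[k][pick] = True
        out[i] = math.log(cands[pick].odds_ratio)
    return out
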