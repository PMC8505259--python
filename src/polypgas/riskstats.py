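"""Environmental-risk accumulation statistics.

Consumption-group assignment (non-polytox / adult / preadult polytox),
stratified exposure-count tables, Cochran-Armitage and Jonckheere-Terpstra
trend tests with permutation p-values, odds ratios with conditional-exact
zero-cell handling, chi-square/Fisher tests and variance-inflation-factor
screening.

Permutation p-values use the add-one estimator ``(1 + exceed) / (B + 1)``
and a mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

CONSUMPTION_GROUPS = ["non_polytox", "adult", "preadult"]
RISK_STRATA = ["1", "2", "3+"]


# --- group assignment and risk counting ---

def assign_consumption_group(onsets: dict[str, str]) -> str:
    """Consumption group from per-drug-class onset labels.

    ``onsets`` maps drug-class name to one of ``{"never", "preadult",
    "adult"}``.  Caffeine is never counted as a drug.  Returns ``preadult``
    (>= 3 classes with preadult onset), ``adult`` (>= 3 lifetime classes but
    not preadult) or ``non_polytox``; an unknown label yields
    ``unclassified`` (excluded downstream).
    """
    n_pre = n_life = 0
    for name, onset in onsets.items():
        if name.lower() == "caffeine":
            continue
        if onset == "preadult":
            n_pre += 1
            n_life += 1
        elif onset == "adult":
            n_life += 1
        elif onset != "never":
            return "unclassified"
    if n_pre >= 3:
        return "preadult"
    if n_life >= 3:
        return "adult"
    return "non_polytox"


def risk_count(exposures: Sequence) -> tuple[int, bool]:
    """Count of positive risk flags and a completeness flag.

    Any missing flag (None/NaN) makes the count incomplete; the count then
    covers the observed flags only.
    """
    n = 0
    complete = True
    for v in exposures:
        if v is None or (isinstance(v, float) and np.isnan(v)):
            complete = False
        elif v:
            n += 1
    return n, complete


# --- stratified counts (consumption group x number of risks) ---

@dataclass
class StratifiedCounts:
    """Exposure counts by consumption group and risk-number stratum.

    ``counts`` is indexed by (group, stratum) with one column per risk
    factor; entries are numbers of exposed individuals.  ``denominators``
    (optional) carries the group-by-stratum cell sizes.
    """

    counts: pd.DataFrame
    denominators: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("exposure counts must be non-negative")

    def validate(self) -> list[str]:
        """Soft structural expectations; returns a list of violations."""
        issues = []
        if self.denominators is not None:
            key = ("preadult", "0")
            if key in self.denominators.index and self.denominators[key] != 0:
                issues.append(
                    "preadult group should be empty in the zero-risk stratum"
                )
        return issues

    @classmethod
    def from_samples(cls, samples: pd.DataFrame) -> "StratifiedCounts":
        """Tally exposed individuals from a per-sample table with
        ``consumption_group``, ``n_risks`` and ``risk_*`` columns."""
        risk_cols = [c for c in samples.columns if c.startswith("risk_")]
        strat = np.where(samples["n_risks"] >= 3, "3+",
                         samples["n_risks"].astype(str))
        rows = {}
        denoms = {}
        for grp in CONSUMPTION_GROUPS:
            for st in ["0"] + RISK_STRATA:
                sel = (samples["consumption_group"] == grp) & (strat == st)
                denoms[(grp, st)] = int(sel.sum())
                if st == "0":
                    continue
                rows[(grp, st)] = samples.loc[sel, risk_cols].sum()
        counts = pd.DataFrame(rows).T
        counts.index = pd.MultiIndex.from_tuples(counts.index,
                                                 names=["group", "stratum"])
        counts.columns = [c[len("risk_"):] for c in counts.columns]
        denominators = pd.Series(denoms)
        denominators.index = pd.MultiIndex.from_tuples(
            denominators.index, names=["group", "stratum"]
        )
        return cls(counts=counts.astype(int), denominators=denominators)

    def to_tsv(self, path) -> None:
        """TSV layout: one row per (group, stratum), one column per risk."""
        self.counts.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StratifiedCounts":
        """Read the layout written by :meth:`to_tsv` (columns ``group``,
        ``stratum``, then risk factors)."""
        df = pd.read_csv(path, sep="\t", dtype={"group": str, "stratum": str})
        df = df.set_index(["group", "stratum"])
        return cls(counts=df.astype(int))

    def __add__(self, other: "StratifiedCounts") -> "StratifiedCounts":
        counts = self.counts.add(other.counts, fill_value=0).astype(int)
        denoms = None
        if self.denominators is not None and other.denominators is not None:
            denoms = self.denominators.add(other.denominators, fill_value=0)
        return StratifiedCounts(counts=counts, denominators=denoms)


def table_totals(sc: StratifiedCounts) -> pd.Series:
    """Total exposed individuals per risk factor (sum over all group x
    stratum cells; the zero-risk stratum contributes no exposures by
    construction)."""
    return sc.counts.sum(axis=0)


def _reference_counts_frame() -> pd.DataFrame:
    # Exposed counts by (group, risk-number stratum) from the reference
    # deeply phenotyped schizophrenia cohort (columns: risk factors).
    data = {
        # stratum: {group: [cannabis, alcohol, urbanicity, migration,
        #                   physical_abuse, sexual_abuse]}
        ("preadult", "1"): [21, 0, 0, 0, 0, 0],
        ("adult", "1"): [32, 2, 7, 1, 3, 1],
        ("non_polytox", "1"): [52, 31, 191, 12, 30, 37],
        ("preadult", "2"): [38, 20, 10, 2, 5, 1],
        ("adult", "2"): [56, 21, 29, 7, 9, 6],
        ("non_polytox", "2"): [79, 38, 105, 28, 47, 37],
        ("preadult", "3+"): [61, 42, 43, 20, 22, 16],
        ("adult", "3+"): [55, 35, 41, 19, 24, 22],
        ("non_polytox", "3+"): [77, 57, 98, 44, 63, 44],
    }
    df = pd.DataFrame(
        data, index=["cannabis", "alcohol", "urbanicity", "migration",
                     "physical_abuse", "sexual_abuse"]
    ).T
    df.index = pd.MultiIndex.from_tuples(df.index, names=["group", "stratum"])
    return df


def reference_stratified_counts() -> StratifiedCounts:
    """The published group x risk-number exposure counts of the reference
    cohort (printed table), usable as input to :func:`table_totals`."""
    return StratifiedCounts(counts=_reference_counts_frame())


# --- categorical tests ---

def chi2_test(table: np.ndarray, correction: bool = False
              ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction by
    default).  Raises on a zero marginal."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square requires positive marginals")
    stat, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), int(df), float(p)


def fisher_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities no
    larger than the observed table's)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


# --- trend tests ---

@dataclass
class TrendResult:
    statistic: float
    p_asymptotic: float
    p_permutation: float
    n_permutations: int
    seed: int


def _ca_z(cases: np.ndarray, totals: np.ndarray, scores: np.ndarray
          ) -> np.ndarray:
    """Cochran-Armitage trend z; vectorised over leading axes of ``cases``."""
    N = totals.sum()
    R = cases.sum(axis=-1)
    pbar = R / N
    T = (cases * scores).sum(axis=-1) - pbar * (totals * scores).sum()
    var = pbar * (1 - pbar) * (
        (totals * scores**2).sum() - (totals * scores).sum() ** 2 / N
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(var > 0, T / np.sqrt(var), 0.0)


def cochran_armitage(table: np.ndarray, scores: Optional[Sequence[float]] = None,
                     n_permutations: int = 20_000, seed: int = 0) -> TrendResult:
    """Cochran-Armitage trend test for a 2xK table with permutation p.

    Rows are (non-event, event) counts over K ordered strata; ``scores``
    default to 0..K-1.  The permutation p conditions on the margins
    (multivariate hypergeometric resampling of event counts) and uses the
    add-one estimator.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2xK table")
    K = table.shape[1]
    scores = np.asarray(scores if scores is not None
                        else np.arange(K), dtype=float)
    totals = table.sum(axis=0)
    cases = table[1].astype(float)
    n_cases = int(cases.sum())
    if n_cases == 0 or n_cases == int(totals.sum()):
        return TrendResult(0.0, 1.0, 1.0, n_permutations, seed)

    z_obs = float(_ca_z(cases, totals.astype(float), scores))
    p_asym = float(2 * stats.norm.sf(abs(z_obs)))

    rng = np.random.default_rng([seed, 0xCA])
    perm = rng.multivariate_hypergeometric(totals, n_cases,
                                           size=n_permutations).astype(float)
    z_perm = _ca_z(perm, totals.astype(float), scores)
    exceed = int(np.sum(np.abs(z_perm) >= abs(z_obs) - 1e-12))
    p_perm = (1 + exceed) / (n_permutations + 1)
    return TrendResult(z_obs, p_asym, float(p_perm), n_permutations, seed)


def _jt_statistic_sorted(labels: np.ndarray, block_start: np.ndarray,
                         block_end: np.ndarray, n_groups: int) -> np.ndarray:
    """JT statistic for label matrices aligned to value-sorted order.

    ``labels`` is (B, n) of group codes in value-ascending order;
    ``block_start``/``block_end`` give, per position, the first index of its
    tie block and one past its last.  Pairs across ordered groups count 1
    when strictly increasing in value and 0.5 on ties.
    """
    B, n = labels.shape
    jt = np.zeros(B)
    for h in range(1, n_groups):
        less = (labels < h).astype(np.float64)
        cum = np.cumsum(less, axis=1)
        zero = np.zeros((B, 1))
        cum0 = np.concatenate([zero, cum], axis=1)  # cum0[:, i] = count in [0, i)
        before_block = cum0[:, block_start]         # strictly smaller values
        in_block = cum0[:, block_end] - before_block
        is_h = labels == h
        jt += np.sum(is_h * (before_block + 0.5 * in_block), axis=1)
    return jt


def jonckheere_terpstra(values: Sequence[float], groups: Sequence[int],
                        n_permutations: int = 20_000, seed: int = 0
                        ) -> TrendResult:
    """Jonckheere-Terpstra ordered-alternative test with permutation p.

    ``groups`` are ordinal codes 0..K-1; the statistic is the sum of
    pairwise Mann-Whitney counts over ordered group pairs (ties count 1/2).
    The asymptotic p uses the tie-corrected normal approximation; the
    permutation p shuffles group labels.
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(groups)
    if codes.dtype.kind not in "iu":
        _, codes = np.unique(codes, return_inverse=True)
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ValueError("need at least two ordered groups")
    n = values.size

    order = np.argsort(values, kind="stable")
    v_sorted = values[order]
    # tie blocks in the sorted sequence
    new_block = np.r_[True, v_sorted[1:] != v_sorted[:-1]]
    block_id = np.cumsum(new_block) - 1
    starts = np.flatnonzero(new_block)
    ends = np.r_[starts[1:], n]
    block_start = starts[block_id]
    block_end = ends[block_id]

    lab_obs = codes[order][None, :].astype(np.int8)
    jt_obs = float(_jt_statistic_sorted(lab_obs, block_start, block_end,
                                        n_groups)[0])

    # tie-corrected normal approximation
    ni = np.bincount(codes, minlength=n_groups).astype(float)
    tu = np.bincount(block_id).astype(float)
    mean = (n * n - np.sum(ni**2)) / 4.0
    a = (n * (n - 1) * (2 * n + 5) - np.sum(ni * (ni - 1) * (2 * ni + 5))
         - np.sum(tu * (tu - 1) * (2 * tu + 5))) / 72.0
    b = (np.sum(ni * (ni - 1) * (ni - 2)) * np.sum(tu * (tu - 1) * (tu - 2))
         ) / (36.0 * n * (n - 1) * (n - 2))
    c = (np.sum(ni * (ni - 1)) * np.sum(tu * (tu - 1))) / (8.0 * n * (n - 1))
    var = a + b + c
    if var <= 0 or np.all(values == values[0]):
        return TrendResult(jt_obs, 1.0, 1.0, n_permutations, seed)
    z = (jt_obs - mean) / np.sqrt(var)
    p_asym = float(2 * stats.norm.sf(abs(z)))

    rng = np.random.default_rng([seed, 0x17])
    lab = np.tile(codes.astype(np.int8), (n_permutations, 1))
    lab = rng.permuted(lab, axis=1)
    lab = lab[:, order]
    jt_perm = _jt_statistic_sorted(lab, block_start, block_end, n_groups)
    exceed = int(np.sum(np.abs(jt_perm - mean) >= abs(jt_obs - mean) - 1e-9))
    p_perm = (1 + exceed) / (n_permutations + 1)
    return TrendResult(jt_obs, p_asym, float(p_perm), n_permutations, seed)


# --- odds ratios ---

@dataclass
class OddsRatioResult:
    estimate: float        # may be +inf
    ci_low: float
    ci_high: float         # may be +inf
    method: str            # "wald" or "conditional-exact"

    def format(self) -> str:
        hi = "∞" if np.isinf(self.ci_high) else f"{self.ci_high:.1f}"
        lo = "0" if self.ci_low == 0 else f"{self.ci_low:.1f}"
        est = "∞" if np.isinf(self.estimate) else f"{self.estimate:.1f}"
        return f"OR = {est}, 95% CI [{lo}-{hi}]"


def _exact_or(a: int, b: int, c: int, d: int, alpha: float) -> OddsRatioResult:
    """Conditional-exact (noncentral hypergeometric) estimate and CI."""
    M = a + b + c + d
    n1 = a + b          # row-1 total
    t = a + c           # column-1 total
    xmin = max(0, t - (M - n1))
    xmax = min(t, n1)

    def dist(log_psi: float):
        return stats.nchypergeom_fisher(M, n1, t, np.exp(log_psi))

    # conditional MLE; boundary observations push the estimate to 0 / +inf
    if a == xmax:
        est = float("inf")
    elif a == xmin:
        est = 0.0
    else:
        res = optimize.minimize_scalar(
            lambda lp: -dist(lp).logpmf(a), bounds=(-25, 25), method="bounded",
            options={"xatol": 1e-8},
        )
        est = float(np.exp(res.x))

    half = alpha / 2.0

    def sf_at(lp: float) -> float:   # P(X >= a | psi)
        return float(dist(lp).sf(a - 1))

    def cdf_at(lp: float) -> float:  # P(X <= a | psi)
        return float(dist(lp).cdf(a))

    if a == xmin:
        lo = 0.0
    else:
        lo = float(np.exp(optimize.brentq(
            lambda lp: sf_at(lp) - half, -30, 30, xtol=1e-10)))
    if a == xmax:
        hi = float("inf")
    else:
        hi = float(np.exp(optimize.brentq(
            lambda lp: cdf_at(lp) - half, -30, 30, xtol=1e-10)))
    return OddsRatioResult(est, lo, hi, "conditional-exact")


def odds_ratio(table: np.ndarray, method: str = "auto",
               alpha: float = 0.05) -> OddsRatioResult:
    """Odds ratio of a 2x2 table.

    Without zero cells: the cross-product estimate with a Wald 95% CI on
    the log scale.  With any zero cell (or ``method="conditional-exact"``):
    conditional-exact inference under the noncentral hypergeometric
    likelihood, with 0/+inf bounds where the data sit on the support
    boundary (the "[50.8-inf]" reporting shape).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a non-negative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined for an empty margin")
    has_zero = min(a, b, c, d) == 0
    if method == "wald" and has_zero:
        raise ValueError("Wald odds ratio undefined with a zero cell")
    if method == "conditional-exact" or (method == "auto" and has_zero):
        return _exact_or(a, b, c, d, alpha)
    est = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zq = stats.norm.ppf(1 - alpha / 2)
    return OddsRatioResult(
        float(est), float(est * np.exp(-zq * se)), float(est * np.exp(zq * se)),
        "wald",
    )


# --- collinearity screening ---

def vif(X: np.ndarray, bound: float = 1.2) -> tuple[np.ndarray, bool]:
    """Variance inflation factors of the predictor columns.

    ``VIF_j = 1 / (1 - R^2_j)`` from regressing column j on the others
    (with an intercept).  A perfectly collinear predictor reports +inf.
    Returns (per-predictor VIFs, all-below-bound flag).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant predictor column")
    n, k = X.shape
    out = np.empty(k)
    for j in range(k):
        yj = X[:, j]
        Z = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out, bool(np.all(out < bound))
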