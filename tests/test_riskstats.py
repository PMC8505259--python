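"""Environmental-risk statistics: group rules, trend tests, odds ratios."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polypgas import riskstats as rs


# --- consumption groups and risk counts ---

@pytest.mark.parametrize(
    "onsets,expected",
    [
        ({"cocaine": "preadult", "opioids": "preadult", "ecstasy": "preadult"},
         "preadult"),
        ({"cocaine": "adult", "opioids": "adult"}, "non_polytox"),
        # one preadult class plus four lifetime classes: adult polytoxicomania
        ({"cocaine": "preadult", "opioids": "adult", "ecstasy": "adult",
          "inhalants": "adult"}, "adult"),
        # caffeine never counts as a drug
        ({"caffeine": "preadult", "cocaine": "preadult", "opioids": "preadult"},
         "non_polytox"),
        ({"cocaine": "weird"}, "unclassified"),
    ],
)
def test_consumption_group_rules(onsets, expected):
    assert rs.assign_consumption_group(onsets) == expected


def test_risk_count():
    assert rs.risk_count([False] * 6) == (0, True)
    assert rs.risk_count([True] * 6) == (6, True)
    assert rs.risk_count([True, True, False, False, False, False]) == (2, True)
    count, complete = rs.risk_count([True, None, False, float("nan"), True, False])
    assert count == 2 and not complete


# --- stratified counts and the printed reference table ---

def test_reference_table_totals():
    totals = rs.table_totals(rs.reference_stratified_counts())
    assert totals["cannabis"] == 471
    assert totals["alcohol"] == 246
    assert totals["urbanicity"] == 524
    assert totals["migration"] == 133
    assert totals["physical_abuse"] == 203
    assert totals["sexual_abuse"] == 164


def test_table_totals_additive_and_zero():
    ref = rs.reference_stratified_counts()
    doubled = ref + ref
    assert (rs.table_totals(doubled) == 2 * rs.table_totals(ref)).all()
    zero = rs.StratifiedCounts(counts=ref.counts * 0)
    assert (rs.table_totals(zero) == 0).all()


def test_stratified_counts_from_samples(small_sim_cohort):
    _, cohort = small_sim_cohort
    sc = rs.StratifiedCounts.from_samples(cohort.samples)
    # tallies match a direct pandas recount for one cell
    s = cohort.samples
    sel = (s["consumption_group"] == "non_polytox") & (s["n_risks"] == 2)
    assert sc.counts.loc[("non_polytox", "2"), "cannabis"] == int(
        s.loc[sel, "risk_cannabis"].sum()
    )
    assert sc.denominators[("non_polytox", "2")] == int(sel.sum())


# --- chi-square and Fisher ---

def test_chi2_proportional_rows_is_null():
    stat, df, p = rs.chi2_test([[10, 20, 30], [20, 40, 60]])
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_chi2_zero_marginal_raises():
    with pytest.raises(ValueError):
        rs.chi2_test([[0, 5], [0, 7]])


def _fisher_enumeration(table):
    """Two-sided Fisher p by exact-fraction hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return (Fraction(math.comb(r1, x) * math.comb(r2, c1 - x),
                         math.comb(n, c1)))

    obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        if pmf(x) <= obs:
            total += pmf(x)
    return float(total)


@pytest.mark.parametrize("table", [
    [[2, 8], [8, 2]],
    [[1, 9], [11, 3]],
    [[5, 0], [1, 4]],
    [[3, 3], [3, 3]],
])
def test_fisher_matches_enumeration(table):
    assert rs.fisher_2x2(table) == pytest.approx(_fisher_enumeration(table),
                                                 abs=1e-12)


def test_chi2_2x2_equals_squared_two_proportion_z():
    rng = np.random.default_rng(4)
    for _ in range(20):
        t = rng.integers(5, 60, size=(2, 2))
        stat, _, _ = rs.chi2_test(t)
        n1, n2 = t[0].sum(), t[1].sum()
        p1, p2 = t[0, 0] / n1, t[1, 0] / n2
        pbar = (t[0, 0] + t[1, 0]) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        assert stat == pytest.approx(z * z, rel=1e-10)


# --- Cochran-Armitage ---

def _ca_exact_p(table, scores=None):
    """Exact conditional two-sided trend p by full enumeration."""
    table = np.asarray(table)
    totals = table.sum(axis=0)
    n_cases = int(table[1].sum())
    scores = np.asarray(scores if scores is not None
                        else np.arange(table.shape[1]), dtype=float)
    z_obs = abs(rs._ca_z(table[1].astype(float), totals.astype(float), scores))
    total_p = Fraction(0)
    match_p = Fraction(0)
    denom = math.comb(int(totals.sum()), n_cases)
    ranges = [range(0, int(t) + 1) for t in totals]
    for combo in itertools.product(*ranges):
        if sum(combo) != n_cases:
            continue
        w = Fraction(math.prod(math.comb(int(t), x)
                               for t, x in zip(totals, combo)), denom)
        total_p += w
        z = abs(rs._ca_z(np.asarray(combo, dtype=float),
                         totals.astype(float), scores))
        if z >= z_obs - 1e-12:
            match_p += w
    assert total_p == 1
    return float(match_p)


def test_cochran_armitage_permutation_close_to_exact():
    table = [[3, 2, 1], [1, 2, 3]]  # total n = 12
    res = rs.cochran_armitage(table, n_permutations=20_000, seed=7)
    exact = _ca_exact_p(table)
    mc_sd = math.sqrt(exact * (1 - exact) / 20_000)
    assert abs(res.p_permutation - exact) <= 2 * mc_sd + 2 / 20_001


def test_cochran_armitage_flat_table_is_null():
    res = rs.cochran_armitage([[50, 50, 50, 50], [10, 10, 10, 10]],
                              n_permutations=2000, seed=1)
    assert abs(res.statistic) < 1e-12
    assert res.p_permutation > 0.9


def test_cochran_armitage_steep_trend():
    # 5%, 20%, 50%, 80% events at n=200 per stratum
    table = [[190, 160, 100, 40], [10, 40, 100, 160]]
    res = rs.cochran_armitage(table, n_permutations=20_000, seed=3)
    assert res.p_permutation == pytest.approx(1 / 20_001)
    # asymptotic and permutation tails agree in order of magnitude
    assert res.p_asymptotic < 1e-10


def test_cochran_armitage_two_strata_equals_two_proportion_z():
    table = np.array([[30, 50], [20, 10]])
    res = rs.cochran_armitage(table, n_permutations=10, seed=0)
    n1, n2 = table[:, 0].sum(), table[:, 1].sum()
    p1, p2 = table[1, 0] / n1, table[1, 1] / n2
    pbar = table[1].sum() / (n1 + n2)
    z = (p2 - p1) / math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    assert abs(abs(res.statistic) - abs(z)) < 1e-10


def test_cochran_armitage_degenerate():
    res = rs.cochran_armitage([[5, 5, 5], [0, 0, 0]], seed=0)
    assert res.p_permutation == 1.0


def test_permutation_p_valid_under_null():
    """P(p <= alpha) <= alpha + 3 MC SDs under an exchangeable null."""
    rng = np.random.default_rng(9)
    reps, B = 200, 400
    pvals = []
    for i in range(reps):
        counts = rng.multinomial(60, [1 / 3] * 3)
        events = np.array([rng.hypergeometric(20, 40, c) for c in counts])
        table = np.vstack([counts - events, events])
        pvals.append(rs.cochran_armitage(table, n_permutations=B,
                                         seed=100 + i).p_permutation)
    pvals = np.asarray(pvals)
    for alpha in (0.05, 0.01):
        sd = math.sqrt(alpha * (1 - alpha) / reps)
        assert (pvals <= alpha).mean() <= alpha + 3 * sd


# --- Jonckheere-Terpstra ---

def test_jt_two_groups_is_mann_whitney():
    rng = np.random.default_rng(2)
    x = rng.normal(size=15)
    y = rng.normal(0.5, size=12)
    res = rs.jonckheere_terpstra(np.r_[x, y], np.r_[[0] * 15, [1] * 12],
                                 n_permutations=100, seed=0)
    u = stats.mannwhitneyu(y, x, alternative="two-sided").statistic
    assert res.statistic == pytest.approx(u)


def test_jt_detects_ordered_shift_and_power_grows():
    rng = np.random.default_rng(3)
    pvals = []
    for shift in (0.0, 0.6, 1.2):
        vals = np.concatenate(
            [rng.normal(k * shift, 1, 40) for k in range(3)]
        )
        groups = np.repeat([0, 1, 2], 40)
        res = rs.jonckheere_terpstra(vals, groups, n_permutations=2000, seed=5)
        pvals.append(res.p_permutation)
    assert pvals[1] < pvals[0]
    assert pvals[2] <= pvals[1]
    assert pvals[2] < 0.01


def test_jt_null_pvalues_roughly_uniform():
    rng = np.random.default_rng(8)
    pvals = [
        rs.jonckheere_terpstra(rng.normal(size=36), np.repeat([0, 1, 2], 12),
                               n_permutations=300, seed=i).p_permutation
        for i in range(120)
    ]
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01


def test_jt_handles_ties():
    vals = [1, 1, 2, 2, 3, 3, 1, 2, 3]
    groups = [0, 0, 0, 1, 1, 1, 2, 2, 2]
    res = rs.jonckheere_terpstra(vals, groups, n_permutations=500, seed=0)
    assert np.isfinite(res.statistic)
    assert 0 < res.p_permutation <= 1


# --- odds ratios ---

def test_odds_ratio_cross_product():
    res = rs.odds_ratio([[10, 90], [50, 50]])
    assert res.estimate == pytest.approx(1 / 9, rel=1e-12)
    assert res.method == "wald"
    res = rs.odds_ratio([[20, 80], [20, 80]])
    assert res.estimate == pytest.approx(1.0)
    assert res.ci_low < 1 < res.ci_high


def _exact_or_grid_oracle(table, alpha=0.05):
    """Direct grid maximisation/inversion of the noncentral hypergeometric
    likelihood (independent of the scipy-based implementation path)."""
    (a, b), (c, d) = table
    M, n1, t = a + b + c + d, a + b, a + c
    xmin, xmax = max(0, t - (M - n1)), min(t, n1)
    support = np.arange(xmin, xmax + 1)
    logc = np.array([
        math.lgamma(n1 + 1) - math.lgamma(x + 1) - math.lgamma(n1 - x + 1)
        + math.lgamma(M - n1 + 1) - math.lgamma(t - x + 1)
        - math.lgamma(M - n1 - (t - x) + 1)
        for x in support
    ])

    def pmf(psi):
        w = logc + support * math.log(psi)
        w = np.exp(w - w.max())
        return w / w.sum()

    grid = np.exp(np.linspace(-12, 12, 4001))
    if a == xmax:
        est = math.inf
    elif a == xmin:
        est = 0.0
    else:
        lik = [pmf(psi)[a - xmin] for psi in grid]
        est = grid[int(np.argmax(lik))]
    lo = 0.0 if a == xmin else None
    hi = math.inf if a == xmax else None
    if lo is None:
        sf = np.array([pmf(psi)[a - xmin:].sum() for psi in grid])
        lo = grid[int(np.searchsorted(sf, alpha / 2))]
    if hi is None:
        cdf = np.array([pmf(psi)[: a - xmin + 1].sum() for psi in grid])
        hi = grid[len(cdf) - 1 - int(np.searchsorted(cdf[::-1], alpha / 2))]
    return est, lo, hi


def test_exact_odds_ratio_zero_cell():
    res = rs.odds_ratio([[15, 0], [10, 30]])
    assert res.method == "conditional-exact"
    assert math.isinf(res.estimate) and math.isinf(res.ci_high)
    est, lo, hi = _exact_or_grid_oracle([[15, 0], [10, 30]])
    assert math.isinf(est) and math.isinf(hi)
    assert res.ci_low == pytest.approx(lo, rel=0.02)


def test_exact_odds_ratio_interior_matches_grid_oracle():
    table = [[12, 3], [5, 14]]
    res = rs.odds_ratio(table, method="conditional-exact")
    est, lo, hi = _exact_or_grid_oracle(table)
    assert res.estimate == pytest.approx(est, rel=0.02)
    assert res.ci_low == pytest.approx(lo, rel=0.02)
    assert res.ci_high == pytest.approx(hi, rel=0.02)
    assert res.ci_low <= res.estimate <= res.ci_high


@given(st.lists(st.integers(0, 40), min_size=4, max_size=4))
@settings(max_examples=60, deadline=None)
def test_odds_ratio_symmetries(cells):
    a, b, c, d = cells
    t = np.array([[a, b], [c, d]])
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return
    base = rs.odds_ratio(t)
    both = rs.odds_ratio(t[::-1, ::-1])  # transpose both axes
    rows = rs.odds_ratio(t[::-1, :])     # swap one axis -> reciprocal
    if math.isfinite(base.estimate) and base.estimate > 0:
        assert both.estimate == pytest.approx(base.estimate, rel=1e-6)
        assert rows.estimate == pytest.approx(1 / base.estimate, rel=1e-6)
    elif math.isinf(base.estimate):
        assert math.isinf(both.estimate)
        assert rows.estimate == 0.0


def test_odds_ratio_empty_margin_raises():
    with pytest.raises(ValueError):
        rs.odds_ratio([[0, 0], [5, 5]])


# --- VIF ---

def test_vif_orthogonal_and_collinear():
    rng = np.random.default_rng(1)
    n = 500
    X = rng.standard_normal((n, 3))
    X, _ = np.linalg.qr(X)  # orthogonal columns
    v, ok = rs.vif(X)
    assert np.allclose(v, 1.0, atol=1e-8)
    assert ok
    Xdup = np.column_stack([X, X[:, 0]])
    v, ok = rs.vif(Xdup)
    assert np.isinf(v).any() and not ok


def test_vif_weakly_dependent_risks_below_bound():
    # risks at the study prevalences with mild shared dependence
    rng = np.random.default_rng(12)
    n = 4000
    shared = rng.standard_normal(n)
    prevs = [0.431, 0.383, 0.200, 0.165, 0.133, 0.108]
    X = np.column_stack([
        (0.25 * shared + rng.standard_normal(n)
         < stats.norm.ppf(p) * np.sqrt(1.0625)).astype(float)
        for p in prevs
    ])
    v, ok = rs.vif(X)
    assert ok, f"VIFs {v} exceed 1.2"


def test_stratified_counts_tsv_round_trip(tmp_path):
    ref = rs.reference_stratified_counts()
    ref.to_tsv(tmp_path / "counts.tsv")
    back = rs.StratifiedCounts.from_tsv(tmp_path / "counts.tsv")
    assert (rs.table_totals(back) == rs.table_totals(ref)).all()
    assert back.counts.loc[("preadult", "3+"), "cannabis"] == 61
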