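"""Clumping, neighbor support, intersection-subtraction and set reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import polypgas as pg
from polypgas import pgas
from conftest import make_hwe_genotypes


def _result_frame(pvals, chrom=None, pos=None):
    m = len(pvals)
    return pd.DataFrame(
        {
            "CHR": chrom if chrom is not None else np.ones(m, dtype=int),
            "SNP": [f"v{j}" for j in range(m)],
            "BP": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "A1": "A",
            "BETA": 0.0,
            "SE": 1.0,
            "P": np.asarray(pvals, dtype=float),
            "N": 100,
            "STATUS": "ok",
        }
    )


def _correlated_genotypes(rng, n, m, pairs):
    """HWE genotypes with selected column pairs made highly correlated."""
    geno = make_hwe_genotypes(rng, n, rng.uniform(0.2, 0.5, m))
    for a, b, flip in pairs:
        geno[:, b] = geno[:, a]
        if flip:
            mask = rng.random(n) < 0.05
            geno[mask, b] = rng.integers(0, 3, mask.sum())
    return geno


# --- ld_r2 ---

def test_ld_r2_identical_symmetric_and_independent():
    rng = np.random.default_rng(0)
    g = make_hwe_genotypes(rng, 400, [0.3, 0.4])
    assert pgas.ld_r2(g[:, 0], g[:, 0]) == pytest.approx(1.0)
    assert pgas.ld_r2(g[:, 0], g[:, 1]) == pgas.ld_r2(g[:, 1], g[:, 0])
    vals = []
    for _ in range(1000):
        h = make_hwe_genotypes(rng, 200, [0.3, 0.3])
        vals.append(pgas.ld_r2(h[:, 0], h[:, 1]))
    assert np.mean(vals) == pytest.approx(1 / 200, rel=0.3)


def test_ld_r2_constant_column_is_nan_and_overlap_guard():
    x = np.full(100, 1, dtype=np.int8)
    y = np.tile([0, 1, 2, 1], 25).astype(np.int8)
    assert np.isnan(pgas.ld_r2(x, y))
    with pytest.raises(ValueError, match="overlap"):
        pgas.ld_r2(np.full(100, -1, np.int8), y)


# --- clumping ---

def clump_reference(result, genotypes, params):
    """Straightforward quadratic-time reimplementation of the greedy spec."""
    p = result["P"].to_numpy(float)
    chrom = result["CHR"].to_numpy()
    pos = result["BP"].to_numpy()
    m = len(p)
    g = genotypes.astype(float)
    g[genotypes < 0] = np.nan

    def r2(a, b):
        ok = np.isfinite(g[:, a]) & np.isfinite(g[:, b])
        x, y = g[ok, a], g[ok, b]
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return np.corrcoef(x, y)[0, 1] ** 2

    assigned = {}
    clumps = []
    while True:
        cand = [j for j in range(m)
                if j not in assigned and np.isfinite(p[j])
                and p[j] <= params.clump_p1]
        if not cand:
            break
        j = min(cand, key=lambda k: (p[k], chrom[k], pos[k]))
        members = []
        assigned[j] = len(clumps)
        for b in range(m):
            if b in assigned or chrom[b] != chrom[j]:
                continue
            if abs(pos[b] - pos[j]) <= params.clump_kb * 1000:
                rr = r2(j, b)
                if np.isfinite(rr) and rr >= params.clump_r2:
                    assigned[b] = len(clumps)
                    members.append(b)
        clumps.append((j, sorted(members)))
    return clumps


def test_clump_all_above_threshold_is_empty():
    rng = np.random.default_rng(1)
    geno = make_hwe_genotypes(rng, 100, rng.uniform(0.2, 0.5, 5))
    res = _result_frame([0.5, 0.2, 0.9, 0.3, 0.11])
    cs = pgas.clump(res, geno, pg.PgasParams())
    assert cs.clumps == []
    assert (cs.assignment == -1).all()


def test_clump_five_snp_toy():
    """p = (.001, .2, .004, .03, .5); r2(1,2)=high, r2(3,4)=high, rest ~0
    -> clumps {v0:[v1]}, {v2:[v3]}; v4 unassigned."""
    rng = np.random.default_rng(2)
    geno = _correlated_genotypes(rng, 500, 5, [(0, 1, True), (2, 3, True)])
    res = _result_frame([0.001, 0.2, 0.004, 0.03, 0.5])
    cs = pgas.clump(res, geno, pg.PgasParams())
    assert len(cs.clumps) == 2
    assert cs.clumps[0].index == 0
    assert [b for b, _ in cs.clumps[0].members] == [1]
    assert cs.clumps[1].index == 2
    assert [b for b, _ in cs.clumps[1].members] == [3]
    assert cs.assignment[4] == -1


def test_clump_matches_reference_on_random_instances():
    params = pg.PgasParams(clump_p1=0.3, clump_r2=0.4, clump_kb=5.0)
    rng = np.random.default_rng(3)
    for rep in range(25):
        m = 30
        pairs = [(a, a + 1, True) for a in rng.choice(27, 4, replace=False)]
        geno = _correlated_genotypes(rng, 150, m, pairs)
        res = _result_frame(rng.random(m))
        got = pgas.clump(res, geno, params)
        want = clump_reference(res, geno, params)
        got_repr = [(c.index, sorted(b for b, _ in c.members))
                    for c in got.clumps]
        assert got_repr == want, f"instance {rep}"


def test_clump_window_monotonicity():
    """Doubling clump_kb never decreases any clump's member count."""
    rng = np.random.default_rng(4)
    geno = _correlated_genotypes(rng, 200, 30,
                                 [(0, 1, True), (10, 11, True), (20, 21, True)])
    res = _result_frame(rng.random(30) * 0.05)
    small = pgas.clump(res, geno, pg.PgasParams(clump_kb=3.0))
    big = pgas.clump(res, geno, pg.PgasParams(clump_kb=6.0))
    small_sizes = {c.index: len(c.members) for c in small.clumps}
    big_sizes = {c.index: len(c.members) for c in big.clumps}
    for idx, size in small_sizes.items():
        if idx in big_sizes:
            assert big_sizes[idx] >= size


def test_neighbor_support_cases():
    rng = np.random.default_rng(5)
    geno = _correlated_genotypes(rng, 300, 3, [(0, 1, True), (0, 2, True)])
    params = pg.PgasParams()
    res = _result_frame([0.001, 0.04, 0.3])
    cs = pgas.clump(res, geno, params)
    assert pgas.neighbor_support(cs.clumps[0], res) is True
    # members at p = 0.06 and 0.3 only -> no support
    res2 = _result_frame([0.001, 0.06, 0.3])
    assert pgas.neighbor_support(cs.clumps[0], res2) is False
    # singleton clump -> never supported
    solo = make_hwe_genotypes(rng, 300, [0.3])
    res3 = _result_frame([0.001])
    cs3 = pgas.clump(res3, solo, params)
    assert pgas.neighbor_support(cs3.clumps[0], res3) is False


# --- set reports ---

def test_jaccard_matrix_conventions():
    sets = [{"a", "b"}, {"b", "c"}, {"a", "b"}, set(), set(), {"x"}]
    J = pgas.jaccard_matrix(sets)
    assert np.allclose(J, J.T)
    assert np.allclose(np.diag(J), 1.0)
    assert J[0, 1] == pytest.approx(1 / 3)
    assert J[0, 2] == 1.0
    assert J[3, 4] == 1.0       # both empty -> 1 by convention
    assert J[0, 5] == 0.0       # disjoint


def test_intersection_counts_simple_and_partition():
    sets = [{"a", "b"}, set(), set()]
    counts = pgas.intersection_counts(sets)
    assert counts == {(0,): 2}
    rng = np.random.default_rng(6)
    universe = [f"s{i}" for i in range(40)]
    sets = [set(rng.choice(universe, rng.integers(0, 30), replace=False))
            for _ in range(6)]
    counts = pgas.intersection_counts(sets)
    # brute-force per-element pattern tally
    brute = {}
    for el in set().union(*sets):
        pat = tuple(i for i, s in enumerate(sets) if el in s)
        brute[pat] = brute.get(pat, 0) + 1
    assert counts == brute
    assert sum(counts.values()) == len(set().union(*sets))


@given(st.lists(st.frozensets(st.integers(0, 15), max_size=10),
                min_size=2, max_size=6))
@settings(max_examples=50, deadline=None)
def test_intersection_counts_partition_property(sets):
    counts = pgas.intersection_counts([set(s) for s in sets])
    assert sum(counts.values()) == len(set().union(*sets))
    for pattern, c in counts.items():
        assert c > 0 and len(pattern) >= 1


# --- intersection-subtraction rules ---

def _six_results(pmatrix, geno=None):
    m = pmatrix.shape[0]
    return [_result_frame(pmatrix[:, g]) for g in range(6)]


def _toy_panel(rng, m=4, n=400):
    geno = _correlated_genotypes(rng, n, m, [(0, 1, True)])
    return geno


def test_pgas_intersect_rule_applications():
    rng = np.random.default_rng(7)
    geno = _toy_panel(rng)
    params = pg.PgasParams()
    # v0 with supporting neighbor v1; p < .01 in GWAS1-4, null in 5-6
    P = np.full((4, 6), 0.5)
    P[0] = [0.005, 0.008, 0.003, 0.009, 0.2, 0.5]
    P[1] = [0.04, 0.04, 0.04, 0.04, 0.6, 0.6]
    results = _six_results(P)
    clumps = pgas.clump(results[0], geno, params)
    rep = pgas.pgas_intersect(results, clumps, params)
    assert rep.final_snps == ["v0"]
    assert "v0" in rep.raw_snps

    # GWAS5 p = 0.04 -> subtracted
    P2 = P.copy()
    P2[0, 4] = 0.04
    rep2 = pgas.pgas_intersect(_six_results(P2), clumps, params)
    assert rep2.final_snps == []

    # GWAS2 p = 0.02 -> consistency fails
    P3 = P.copy()
    P3[0, 1] = 0.02
    rep3 = pgas.pgas_intersect(_six_results(P3), clumps, params)
    assert rep3.final_snps == []


def test_pgas_intersect_requires_neighbor_unless_disabled():
    rng = np.random.default_rng(8)
    geno = _toy_panel(rng)
    P = np.full((4, 6), 0.5)
    P[0] = [0.005, 0.008, 0.003, 0.009, 0.2, 0.5]
    P[1] = [0.2, 0.2, 0.2, 0.2, 0.6, 0.6]  # neighbor not significant
    params = pg.PgasParams()
    clumps = pgas.clump(_six_results(P)[0], geno, params)
    rep = pgas.pgas_intersect(_six_results(P), clumps, params)
    assert rep.final_snps == []
    loose = pg.PgasParams(require_neighbor=False)
    rep2 = pgas.pgas_intersect(_six_results(P), clumps, loose)
    assert rep2.final_snps == ["v0"]
    # raw intersection never uses the neighbor criterion
    assert rep.raw_snps == rep2.raw_snps == ["v0"]


def test_pgas_intersect_threshold_monotonicity():
    rng = np.random.default_rng(9)
    geno = make_hwe_genotypes(rng, 300, rng.uniform(0.2, 0.5, 30))
    P = rng.random((30, 6)) * np.array([0.03, 0.03, 0.03, 0.03, 1, 1])
    results = _six_results(P)
    base = pg.PgasParams(require_neighbor=False)
    loose = pg.PgasParams(require_neighbor=False, alpha_poly=0.02,
                          alpha_disease=0.02, clump_p1=0.02)
    clumps_base = pgas.clump(results[0], geno, base)
    clumps_loose = pgas.clump(results[0], geno, loose)
    rep_base = pgas.pgas_intersect(results, clumps_base, base)
    rep_loose = pgas.pgas_intersect(results, clumps_loose, loose)
    # relaxing alpha_poly upward and alpha_disease downward widens the set
    assert set(rep_base.raw_snps) <= set(
        pgas.pgas_intersect(results, clumps_base,
                            pg.PgasParams(require_neighbor=False,
                                          alpha_poly=0.02)).raw_snps
    )


def test_pgas_intersect_panel_mismatch_raises():
    rng = np.random.default_rng(10)
    geno = _toy_panel(rng)
    P = np.full((4, 6), 0.5)
    results = _six_results(P)
    bad = results[-1].iloc[:-1]
    clumps = pgas.clump(results[0], geno, pg.PgasParams())
    with pytest.raises(ValueError, match="panels"):
        pgas.pgas_intersect(results[:5] + [bad], clumps, pg.PgasParams())


def test_pgas_report_json_deterministic():
    rng = np.random.default_rng(11)
    geno = _toy_panel(rng)
    P = np.full((4, 6), 0.5)
    P[0] = [0.005, 0.008, 0.003, 0.009, 0.2, 0.5]
    P[1] = [0.04] * 4 + [0.6, 0.6]
    results = _six_results(P)
    params = pg.PgasParams()
    clumps = pgas.clump(results[0], geno, params)
    a = pgas.pgas_intersect(results, clumps, params).to_json()
    b = pgas.pgas_intersect(results, clumps, params).to_json()
    assert a == b


# --- full pipeline on a small cohort ---

@pytest.fixture(scope="module")
def small_pipeline_runs():
    cfg = pg.SimConfig(
        n_patients=400, n_controls=400, n_snps=800, seed=41,
        planted_loci=[pg.PlantedLocus("polytox", 0.3, 2.5),
                      pg.PlantedLocus("disease", 0.3, 2.5)],
    )
    first = pg.run_pgas_pipeline(sim_config=cfg, seed=41)
    second = pg.run_pgas_pipeline(sim_config=cfg, seed=41)
    return first, second


def test_pipeline_fixed_seed_byte_identical_report(small_pipeline_runs):
    first, second = small_pipeline_runs
    assert first.report.to_json() == second.report.to_json()


def test_pipeline_structural_invariants(small_pipeline_runs):
    run, _ = small_pipeline_runs
    rep = run.report
    P = np.column_stack([r["P"].to_numpy(float) for r in run.gwas_results])
    ids = run.gwas_results[0]["SNP"].to_numpy()
    final_idx = [int(np.flatnonzero(ids == s)[0]) for s in rep.final_snps]
    params = pg.PgasParams()
    for j in final_idx:
        assert np.all(P[j, :4] < params.alpha_poly)
        assert np.all(P[j, 4:] >= params.alpha_disease)
    J = np.asarray(rep.jaccard)
    assert np.allclose(J, J.T) and np.allclose(np.diag(J), 1.0)
    assert sum(rep.upset.values()) == len(
        set().union(*[set(ids[np.isfinite(P[:, g])
                          & (P[:, g] < params.alpha_set)])
                      for g in range(6)])
    )
    # raw-set membership follows the raw intersection criteria
    for s in rep.final_snps:
        j = int(np.flatnonzero(ids == s)[0])
        assert np.all(P[j, :4] < params.alpha_poly)


def test_pipeline_rejects_bad_inputs():
    with pytest.raises(ValueError, match="exactly one"):
        pg.run_pgas_pipeline()
    cfg = pg.SimConfig(n_patients=50, n_controls=50, n_snps=40, seed=1)
    with pytest.raises(ValueError, match="six"):
        pg.run_pgas_pipeline(sim_config=cfg,
                             definitions=pg.default_contrast_grid()[:3])
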