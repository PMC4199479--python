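"""Single-variant regression, trait residualization, tiled stepwise
selection, Liptak meta-analysis, and pooled mega-analysis."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nf1mod as nm
from nf1mod.association import (
    ModelSpec,
    fit_ols,
    liptak_meta,
    mega_analysis,
    residualize_trait,
    single_variant_regression,
    tiled_regression,
)
from nf1mod.datatypes import DomainError

sm = pytest.importorskip("statsmodels.api")


def _random_fixture(rng, n=30):
    cov = pd.DataFrame({"age": rng.uniform(5, 60, n), "sex": rng.integers(0, 2, n).astype(float)})
    g = rng.binomial(2, 0.3, n).astype(float)
    y = 10 + 0.1 * cov["age"].to_numpy() + rng.normal(0, 4, n)
    return y, cov, g


# ---------------------------------------------------------------------------
# single-variant regression

def test_orthogonal_genotype_gives_zero_beta():
    """Genotype constructed orthogonal to the trait residual: beta 0, p 1."""
    n = 8
    age = np.array([20.0, 25, 30, 35, 40, 45, 50, 55])
    sex = np.array([0.0, 1, 0, 1, 0, 1, 0, 1])
    y = np.array([3.0, 7, 2, 9, 4, 8, 1, 6])
    g0 = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
    C = np.column_stack([np.ones(n), age, sex])
    H = C @ np.linalg.solve(C.T @ C, C.T)
    ry = y - H @ y
    rg = g0 - H @ g0
    g = g0 - (rg @ ry) / (ry @ ry) * y  # residualized g now orthogonal to ry
    res = single_variant_regression(y, pd.DataFrame({"age": age, "sex": sex}), g, ModelSpec(), "v")
    assert abs(res.beta) < 1e-12
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_planted_additive_effect_recovered():
    rng = np.random.default_rng(42)
    n = 500
    cov = pd.DataFrame({"age": rng.uniform(5, 60, n), "sex": rng.integers(0, 2, n).astype(float)})
    g = rng.binomial(2, 0.2, n).astype(float)
    y = 14 - 5.0 * g + 0.05 * cov["age"].to_numpy() + rng.normal(0, 2, n)
    res = single_variant_regression(y, cov, g, ModelSpec(), "v")
    assert -5.5 < res.beta < -4.5


def test_constant_genotype_flagged_not_raised():
    rng = np.random.default_rng(0)
    y, cov, _ = _random_fixture(rng)
    res = single_variant_regression(y, cov, np.ones(len(y)), ModelSpec(), "v")
    assert res.reason == "constant_genotype" and np.isnan(res.p_value)


def test_log_model_transforms_trait():
    rng = np.random.default_rng(3)
    y, cov, g = _random_fixture(rng)
    res_log = single_variant_regression(y, cov, g, ModelSpec(trait_transform="log"), "v")
    X = sm.add_constant(np.column_stack([cov.to_numpy(), g]))
    fit = sm.OLS(np.log10(y + 10), X).fit()
    assert res_log.model == "log_add"
    assert res_log.beta == pytest.approx(fit.params[-1], abs=1e-10)


def test_single_variant_matches_statsmodels_fixtures():
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y, cov, g = _random_fixture(rng)
        res = single_variant_regression(y, cov, g, ModelSpec(), "v")
        fit = sm.OLS(y, sm.add_constant(np.column_stack([cov.to_numpy(), g]))).fit()
        assert res.beta == pytest.approx(fit.params[-1], abs=1e-10)
        assert res.se == pytest.approx(fit.bse[-1], abs=1e-10)
        assert res.p_value == pytest.approx(fit.pvalues[-1], abs=1e-10)
        assert res.n_used == len(y)


# ---------------------------------------------------------------------------
# residualization

def test_residualize_centered_when_covariates_orthogonal():
    y = np.array([1.0, 2, 2, 1])
    cov = pd.DataFrame({"age": [1.0, -1, 1, -1], "sex": [1.0, 1, -1, -1]})
    out = residualize_trait(y, cov)
    assert np.allclose(out, y - y.mean())


def test_residualize_linear_trait_vanishes():
    age = np.arange(10.0)
    cov = pd.DataFrame({"age": age, "sex": np.tile([0.0, 1.0], 5)})
    out = residualize_trait(3 * age + 2, cov)
    assert np.allclose(out, 0, atol=1e-10)


def test_residualize_matches_hat_matrix_oracle(rng):
    y, cov, _ = _random_fixture(rng, n=25)
    out = residualize_trait(y, cov)
    fit = sm.OLS(y, sm.add_constant(cov.to_numpy())).fit()
    assert np.allclose(out, fit.resid, atol=1e-10)
    assert abs(np.nanmean(out)) < 1e-10


# ---------------------------------------------------------------------------
# tiled regression

def _oracle_tiled(y, X, column_tiles, positions, entry=0.05, stay=0.05,
                  tile_alpha=0.2, single_alpha=0.05):
    """Independent statsmodels re-implementation of the documented procedure."""
    events, screen = [], {}

    def fit(cols):
        sub = X[cols].to_numpy(dtype=float)
        keep = ~(np.isnan(y) | np.isnan(sub).any(axis=1))
        return sm.OLS(y[keep], sm.add_constant(sub[keep])).fit()

    def stepwise(cands, level):
        model = []
        while True:
            best, bp = None, np.inf
            for c in cands:
                if c in model:
                    continue
                p = fit(model + [c]).pvalues[-1]
                if p < bp:
                    best, bp = c, p
            if best is None or not bp < entry:
                break
            model.append(best)
            events.append((level, "enter", best))
            while len(model) > 1:
                ps = fit(model).pvalues[1:]
                w = int(np.argmax(ps))
                if ps[w] >= stay:
                    events.append((level, "remove", model[w]))
                    model.pop(w)
                else:
                    break
        return model

    by_tile = {}
    for c, t in column_tiles.items():
        by_tile.setdefault(t, []).append(c)
    survivors = []
    for t in sorted(by_tile):
        cols = sorted(by_tile[t], key=lambda c: positions[c])
        f_p = fit(cols).f_pvalue
        singles = [fit([c]).pvalues[-1] for c in cols]
        keep = f_p < tile_alpha or any(p < single_alpha for p in singles)
        screen[t] = keep
        if keep:
            survivors.extend(stepwise(cols, f"tile{t}"))
    by_chrom = {}
    for c in survivors:
        by_chrom.setdefault(positions[c][0], []).append(c)
    chrom_sel = []
    for ch in sorted(by_chrom):
        chrom_sel.extend(stepwise(by_chrom[ch], f"chrom:{ch}"))
    final = stepwise(chrom_sel, "genome")
    return final, events, screen


def _two_tile_fixture(seed=0, n=80, noise=1.0):
    """Two causal variants plus a strong proxy of their sum: the proxy
    enters the stepwise model first and is eliminated once both causal
    variants are in, exercising the backward look."""
    rng = np.random.default_rng(seed)
    v0 = rng.binomial(2, 0.4, n).astype(float)
    v1 = rng.binomial(2, 0.4, n).astype(float)
    v2 = np.clip(np.where(rng.random(n) < 0.85, np.round((v0 + v1) / 2),
                          rng.binomial(2, 0.4, n)), 0, 2).astype(float)
    nulls = rng.binomial(2, 0.3, (n, 3)).astype(float)
    y = v0 + v1 + noise * rng.normal(size=n)
    X = pd.DataFrame(np.column_stack([v0, v1, v2, nulls]),
                     columns=[f"v{j}" for j in range(6)])
    column_tiles = {f"v{j}": (0 if j < 3 else 1) for j in range(6)}
    positions = {f"v{j}": ("1", 100 * (j + 1)) for j in range(6)}
    return y, X, column_tiles, positions


def test_tiled_matches_independent_stepwise_oracle():
    """Step-for-step agreement with a statsmodels stepwise re-implementation."""
    y, X, column_tiles, positions = _two_tile_fixture()
    model = tiled_regression(y, X, column_tiles, positions)
    final, events, screen = _oracle_tiled(y, X, column_tiles, positions)
    got_events = [(lvl, act, col) for lvl, act, col, _ in model.trace
                  if act in ("enter", "remove")]
    assert got_events == events
    assert model.selected_ids == final
    assert {t: s["retained"] for t, s in model.screen.items()} == screen
    assert set(model.selected_ids) == {"v0", "v1"}  # causal pair, proxy eliminated
    assert ("tile0", "remove", "v2") in got_events


def test_tiled_empty_when_nothing_passes_screen():
    """Genotypes orthogonalized against the trait: both screens fail."""
    rng = np.random.default_rng(9)
    n = 40
    y = rng.normal(size=n)
    g = rng.normal(size=(n, 4))
    yc = (y - y.mean()) / np.linalg.norm(y - y.mean())
    g = g - g.mean(axis=0)
    g = g - np.outer(yc, yc @ g)  # exactly orthogonal to the trait
    X = pd.DataFrame(g, columns=[f"v{j}" for j in range(4)])
    tiles = {f"v{j}": j % 2 for j in range(4)}
    pos = {f"v{j}": ("1", j) for j in range(4)}
    model = tiled_regression(y, X, tiles, pos)
    assert model.selected == []
    assert set(model.screen) == {0, 1}
    assert not any(s["retained"] for s in model.screen.values())


def test_tiled_final_model_is_stepwise_fixed_point():
    y, X, column_tiles, positions = _two_tile_fixture(seed=7)
    model = tiled_regression(y, X, column_tiles, positions)
    assert model.selected, "fixture should select at least one variant"
    for _, beta, p in model.selected:
        assert p < 0.05
    removed = [c for _, act, c, _ in model.trace if act == "remove"]
    for c in removed:
        if c in model.selected_ids:
            continue
        sub = X[model.selected_ids + [c]].to_numpy()
        fit = sm.OLS(y, sm.add_constant(sub)).fit()
        assert fit.pvalues[-1] >= 0.05


def test_tiled_skips_overparameterized_joint_fit():
    """More variants than complete cases: tile screened on singles only."""
    rng = np.random.default_rng(1)
    n = 6
    X = pd.DataFrame(rng.binomial(2, 0.4, (n, 8)).astype(float),
                     columns=[f"v{j}" for j in range(8)])
    y = rng.normal(size=n)
    tiles = {c: 0 for c in X.columns}
    pos = {c: ("1", i) for i, c in enumerate(X.columns)}
    model = tiled_regression(y, X, tiles, pos)
    assert model.screen[0]["f_p"] is None


# ---------------------------------------------------------------------------
# Liptak meta-analysis

def test_liptak_single_cohort_is_identity():
    for p in (0.01, 0.3, 0.97):
        assert liptak_meta([p], [50]).combined_p == pytest.approx(p, abs=1e-12)


def test_liptak_equal_n_reduces_to_stouffer():
    ps = [0.02, 0.4, 0.6]
    m = liptak_meta(ps, [30, 30, 30])
    z = stats.norm.isf(ps)
    assert m.combined_z == pytest.approx(z.sum() / np.sqrt(3), abs=1e-12)


def test_liptak_all_half_is_half():
    assert liptak_meta([0.5, 0.5, 0.5], [89, 29, 62]).combined_p == pytest.approx(0.5, abs=1e-12)


def test_liptak_published_examples():
    m1 = liptak_meta([0.030, 0.329, 0.208], [89, 29, 62])
    assert m1.combined_p == pytest.approx(0.024, abs=0.002)
    m2 = liptak_meta([0.044, 0.699, 0.146], [89, 29, 62])
    assert m2.combined_p == pytest.approx(0.054, abs=0.002)


def test_liptak_domain_errors():
    with pytest.raises(DomainError):
        liptak_meta([0.0, 0.5], [10, 10])
    with pytest.raises(DomainError):
        liptak_meta([1.0], [10])
    with pytest.raises(DomainError):
        liptak_meta([0.5], [10, 20])


def test_liptak_signed_variant_flips_disagreeing_cohorts():
    unsigned = liptak_meta([0.05, 0.05], [50, 50])
    signed = liptak_meta([0.05, 0.05], [50, 50], betas=[1.0, -1.0], signed=True)
    assert unsigned.combined_p < 0.05
    assert signed.combined_p == pytest.approx(0.5, abs=1e-12)


# ---------------------------------------------------------------------------
# mega-analysis

def test_mega_pools_identical_cohorts():
    rng = np.random.default_rng(8)
    n = 200
    cov1 = pd.DataFrame({"age": rng.uniform(5, 60, n), "sex": rng.integers(0, 2, n).astype(float)})
    g1 = rng.binomial(2, 0.2, n).astype(float)
    y1 = 14 - 5.0 * g1 + rng.normal(0, 6, n)
    single = single_variant_regression(y1, cov1, g1, ModelSpec(), "v")
    y = np.concatenate([y1, y1])
    cov = pd.concat([cov1, cov1], ignore_index=True)
    g = np.concatenate([g1, g1])
    cohorts = ["A"] * n + ["B"] * n
    pooled = mega_analysis(y, cov, g, cohorts, ModelSpec(), "v")
    assert pooled.beta == pytest.approx(single.beta, abs=1e-8)
    assert pooled.se < single.se


def test_mega_invariant_to_cohort_intercept_shift():
    rng = np.random.default_rng(21)
    n = 120
    cov = pd.DataFrame({"age": rng.uniform(5, 60, n), "sex": rng.integers(0, 2, n).astype(float)})
    g = rng.binomial(2, 0.3, n).astype(float)
    y = 10 - 2.0 * g + rng.normal(0, 3, n)
    cohorts = ["A"] * (n // 2) + ["B"] * (n // 2)
    shifted = y + np.where(np.array(cohorts) == "B", 7.5, 0.0)
    r1 = mega_analysis(y, cov, g, cohorts, ModelSpec(), "v")
    r2 = mega_analysis(shifted, cov, g, cohorts, ModelSpec(), "v")
    assert r1.beta == pytest.approx(r2.beta, abs=1e-8)


def test_mega_requires_two_cohorts_and_flags_collinearity():
    rng = np.random.default_rng(4)
    n = 40
    cov = pd.DataFrame({"age": rng.uniform(5, 60, n), "sex": rng.integers(0, 2, n).astype(float)})
    g = rng.binomial(2, 0.3, n).astype(float)
    y = rng.normal(10, 2, n)
    with pytest.raises(DomainError):
        mega_analysis(y, cov, g, ["A"] * n, ModelSpec(), "v")
    cohorts = np.where(np.arange(n) < 20, "A", "B")
    g_coll = (cohorts == "B").astype(float)
    res = mega_analysis(y, cov, g_coll, cohorts, ModelSpec(), "v")
    assert res.reason == "collinear_design"


# ---------------------------------------------------------------------------
# OLS core

def test_fit_ols_matches_statsmodels_including_f_test(rng):
    n = 40
    X = np.column_stack([np.ones(n), rng.normal(size=(n, 3))])
    y = rng.normal(size=n)
    fit = fit_ols(X, y)
    ref = sm.OLS(y, X).fit()
    assert np.allclose(fit.beta, ref.params, atol=1e-10)
    assert np.allclose(fit.se, ref.bse, atol=1e-10)
    assert np.allclose(fit.p, ref.pvalues, atol=1e-10)
    assert fit.f_p == pytest.approx(ref.f_pvalue, abs=1e-10)
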