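"""Nested variance decomposition, r statistic and Beta comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rainbowseq import variance
from rainbowseq.simulate import (
    SyntheticConfig, simulate_cells_and_expression, truth_lineages,
)


def _balanced_labels(n_embryos, per_lineage):
    embryo, lin = [], []
    for e in range(n_embryos):
        embryo += [f"e{e}"] * 2 * per_lineage
        lin += ["A"] * per_lineage + ["B"] * per_lineage
    return np.array(embryo), np.array(lin)


def test_decompose_hand_oracle():
    # embryo1 lineage means (1,3), embryo2 (2,4), 2 cells/lineage, no noise
    y = [1, 1, 3, 3, 2, 2, 4, 4]
    embryo, lin = _balanced_labels(2, 2)
    vp = variance.decompose_gene(y, embryo, lin)
    assert vp.ss_embryo == pytest.approx(2.0)
    assert vp.ss_lineage == pytest.approx(8.0)
    assert vp.ss_residual == pytest.approx(0.0)
    assert vp.r == pytest.approx(0.8)


def test_constant_gene_r_undefined():
    embryo, lin = _balanced_labels(3, 2)
    vp = variance.decompose_gene(np.ones(12), embryo, lin)
    assert vp.ss_embryo == vp.ss_lineage == 0 and vp.r is None


def test_decomposition_conserves_total_ss(rng):
    embryo, lin = _balanced_labels(5, 3)
    Y = rng.normal(size=(100, len(embryo)))
    sse, ssl, ssr, *_ = variance.nested_ss_matrix(Y, embryo, lin)
    total = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    np.testing.assert_allclose(sse + ssl + ssr, total, rtol=1e-8)


def test_decomposition_matches_loop_oracle(rng):
    # direct group-mean computation, python loops, no shared code path
    embryo, lin = _balanced_labels(4, 2)
    for _ in range(20):
        y = rng.normal(size=len(embryo))
        grand = y.mean()
        sse = ssl = ssr = 0.0
        for e in set(embryo):
            ye = y[embryo == e]
            sse += len(ye) * (ye.mean() - grand) ** 2
            for l in ("A", "B"):
                yel = y[(embryo == e) & (lin == l)]
                ssl += len(yel) * (yel.mean() - ye.mean()) ** 2
                ssr += ((yel - yel.mean()) ** 2).sum()
        vp = variance.decompose_gene(y, embryo, lin)
        assert vp.ss_embryo == pytest.approx(sse, rel=1e-10)
        assert vp.ss_lineage == pytest.approx(ssl, rel=1e-10)
        assert vp.ss_residual == pytest.approx(ssr, rel=1e-10)


def test_matches_statsmodels_sequential_anova(rng):
    # independent route: type-I ANOVA with embryo then lineage-within-embryo
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    embryo, lin = _balanced_labels(3, 3)
    y = rng.normal(size=len(embryo))
    frame = pd.DataFrame({"y": y, "embryo": embryo, "lineage": lin})
    fit = smf.ols("y ~ C(embryo) + C(embryo):C(lineage)", frame).fit()
    tab = sm.stats.anova_lm(fit, typ=1)
    vp = variance.decompose_gene(y, embryo, lin)
    assert vp.ss_embryo == pytest.approx(tab.loc["C(embryo)", "sum_sq"])
    assert vp.ss_lineage == pytest.approx(
        tab.loc["C(embryo):C(lineage)", "sum_sq"])
    assert vp.ss_residual == pytest.approx(tab.loc["Residual", "sum_sq"])


def test_r_scale_location_invariant(rng):
    embryo, lin = _balanced_labels(4, 2)
    y = rng.normal(size=len(embryo))
    r0 = variance.decompose_gene(y, embryo, lin).r
    r1 = variance.decompose_gene(-3.7 * y + 11.0, embryo, lin).r
    assert r1 == pytest.approx(r0, rel=1e-10)


def test_shuffling_lineage_within_embryo_keeps_ss_embryo(rng):
    embryo, lin = _balanced_labels(4, 2)
    y = rng.normal(size=len(embryo))
    base = variance.decompose_gene(y, embryo, lin).ss_embryo
    shuffled = lin.copy()
    for e in set(embryo):
        idx = np.where(embryo == e)[0]
        shuffled[idx] = rng.permutation(shuffled[idx])
    assert variance.decompose_gene(y, embryo, shuffled).ss_embryo == \
        pytest.approx(base)


def test_design_validation():
    with pytest.raises(ValueError, match="2 embryos"):
        variance.decompose_gene([1, 2, 3, 4], ["e"] * 4,
                                ["A", "A", "B", "B"])
    with pytest.raises(ValueError, match="lacks both"):
        variance.decompose_gene(
            [1, 2, 3, 4], ["e1", "e1", "e2", "e2"], ["A", "B", "A", "A"])


def test_empirical_R_null_mean_and_planted_ranks():
    cfg = SyntheticConfig(seed=21, n_genes=2000, frac_lineage_genes=0.0,
                          embryo_sd=0.0, n_embryos_8cell=0)
    cells, fpkm, _ = simulate_cells_and_expression(cfg)
    cells = truth_lineages(cells)
    r = variance.empirical_R(fpkm, cells, "four_cell")
    d1, d2 = 9, 8
    assert r.mean() == pytest.approx(d1 / (d1 + d2), abs=0.02)

    planted_cfg = SyntheticConfig(seed=21, n_genes=500,
                                  frac_lineage_genes=0.1, lineage_effect=4.0,
                                  n_embryos_8cell=0)
    cells2, fpkm2, truth = simulate_cells_and_expression(planted_cfg)
    cells2 = truth_lineages(cells2)
    r2 = variance.empirical_R(fpkm2, cells2, "four_cell")
    null_median = r2.drop(truth.gene_id).median()
    planted_r = r2[truth.gene_id]
    assert (planted_r > null_median).mean() > 0.9


def test_empirical_R_empty_matrix(expr_data):
    cells, fpkm, _ = expr_data
    none = fpkm * 0.0
    assert variance.empirical_R(none, cells, "four_cell").empty


def test_compare_to_beta():
    rng = np.random.default_rng(0)
    draws = rng.beta(2, 2, size=10_000)
    (comp,) = variance.compare_to_beta(draws, params=[(2, 2)])
    assert comp.ks_distance < 0.02
    # uniform data vs Beta(1,1): analytic tail P(R >= 1-d) = d
    uni = rng.uniform(size=50_000)
    (u,) = variance.compare_to_beta(uni, params=[(1, 1)])
    for delta, emp, ana in u.tail_pairs:
        assert ana == pytest.approx(delta)
        assert emp == pytest.approx(delta, abs=0.01)
    # Q-Q points monotone in both coordinates
    bq = [p[0] for p in comp.qq_points]
    eq = [p[1] for p in comp.qq_points]
    assert bq == sorted(bq) and eq == sorted(eq)
    with pytest.raises(ValueError):
        variance.compare_to_beta([])
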