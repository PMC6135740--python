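"""Lineage ANOVA, q-values, shuffled background and KS comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rainbowseq import difftest
from rainbowseq.simulate import (
    SyntheticConfig, simulate_cells_and_expression, truth_lineages,
)


def _labels(n_embryos=5, per_lineage=2):
    embryo, lin = [], []
    for e in range(n_embryos):
        embryo += [f"e{e}"] * 2 * per_lineage
        lin += ["A"] * per_lineage + ["B"] * per_lineage
    return np.array(embryo), np.array(lin)


def test_null_p_uniform_and_planted_significant():
    rng = np.random.default_rng(1)
    embryo, lin = _labels(9, 2)
    Y = rng.normal(size=(1000, len(embryo)))
    _, p = difftest.anova_matrix(Y, embryo, lin)
    assert stats.kstest(p, "uniform").statistic < 0.05

    # planted effect of 4 residual sd
    y = rng.normal(size=len(embryo)) + 4.0 * (lin == "A")
    f, pv = difftest.anova_lineage(y, embryo, lin)
    assert pv < 1e-3


def test_anova_degenerate_inputs():
    embryo, lin = _labels(3, 2)
    with pytest.raises(ValueError):
        difftest.anova_lineage(np.ones(len(embryo)), embryo, lin)
    # one cell per embryo-lineage: no residual df
    e1, l1 = _labels(3, 1)
    with pytest.raises(ValueError):
        difftest.anova_lineage(np.arange(len(e1), dtype=float), e1, l1)


def test_compute_q_bh_oracle():
    np.testing.assert_allclose(
        difftest.compute_q([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    np.testing.assert_allclose(difftest.compute_q([1.0, 1.0]), [1.0, 1.0])
    np.testing.assert_allclose(difftest.compute_q([0.2]), [0.2])
    assert difftest.compute_q([]).size == 0
    with pytest.raises(ValueError):
        difftest.compute_q([0.1, 1.5])


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=30), st.data())
def test_compute_q_monotone_in_p(p_values, data):
    # raising one p-value never lowers any q-value
    p = np.array(p_values)
    i = data.draw(st.integers(0, len(p) - 1))
    bumped = p.copy()
    bumped[i] = data.draw(st.floats(p[i], 1.0))
    q0, q1 = difftest.compute_q(p), difftest.compute_q(bumped)
    assert (q1 >= q0 - 1e-12).all()


def test_shuffle_background_seeded_and_within_embryo(expr_data):
    cells, fpkm, _ = expr_data
    a = difftest.shuffle_background(fpkm, cells, "four_cell", seed=3)
    b = difftest.shuffle_background(fpkm, cells, "four_cell", seed=3)
    np.testing.assert_array_equal(a, b)
    c = difftest.shuffle_background(fpkm, cells, "four_cell", seed=4)
    assert not np.array_equal(a, c)
    pooled = difftest.shuffle_background(fpkm, cells, "four_cell",
                                         n_shuffles=3, seed=3)
    assert pooled.size == 3 * a.size
    with pytest.raises(ValueError):
        difftest.shuffle_background(fpkm, cells, "four_cell", n_shuffles=0)


def test_null_real_vs_background_indistinguishable():
    # calibration is checked on the p scale: under a global null BH q-values
    # collapse into a narrow band near 1 whose location varies by ensemble,
    # so only the p ensembles (and the q* exceedance counts) are comparable
    for seed in (1, 2, 3):
        cfg = SyntheticConfig(seed=seed, n_genes=2000,
                              frac_lineage_genes=0.0)
        cells, fpkm, _ = simulate_cells_and_expression(cfg)
        cells = truth_lineages(cells)
        tests = difftest.test_features(fpkm, cells, "four_cell")
        bg_p = difftest.shuffle_background(fpkm, cells, "four_cell",
                                           seed=seed, statistic="p")
        comp = difftest.compare_distributions(tests["p"].values, bg_p)
        assert comp.ks_p > 0.01
        bg_q = difftest.shuffle_background(fpkm, cells, "four_cell",
                                           seed=seed)
        qcomp = difftest.compare_distributions(tests["q"].values, bg_q)
        assert qcomp.n_real_below == 0 and qcomp.n_shuffled_below == 0


def test_null_type_i_error_calibrated():
    cfg = SyntheticConfig(seed=5, n_genes=3000, frac_lineage_genes=0.0)
    cells, fpkm, _ = simulate_cells_and_expression(cfg)
    cells = truth_lineages(cells)
    tests = difftest.test_features(fpkm, cells, "four_cell")
    for alpha in (0.01, 0.05):
        frac = (tests["p"] < alpha).mean()
        sd = np.sqrt(alpha * (1 - alpha) / len(tests))
        assert abs(frac - alpha) <= 3 * sd


def test_ks_p_decreases_with_effect_size():
    ks_p = []
    for effect in (0.0, 1.0, 2.0, 4.0):
        vals = []
        for seed in range(5):
            cfg = SyntheticConfig(seed=seed, n_genes=400,
                                  frac_lineage_genes=0.1,
                                  lineage_effect=effect)
            cells, fpkm, _ = simulate_cells_and_expression(cfg)
            cells = truth_lineages(cells)
            tests = difftest.test_features(fpkm, cells, "four_cell")
            bg = difftest.shuffle_background(fpkm, cells, "four_cell",
                                             seed=seed)
            vals.append(
                difftest.compare_distributions(tests["q"].values, bg).ks_p)
        ks_p.append(np.median(vals))
    assert all(a >= b for a, b in zip(ks_p, ks_p[1:]))


def test_compare_distributions_examples():
    rng = np.random.default_rng(0)
    same = rng.uniform(size=1000)
    comp = difftest.compare_distributions(same, same)
    assert comp.ks_stat == 0.0
    # Uniform(0,0.5) vs Uniform(0,1): CDF gap 0.5 at x=0.5
    real = rng.uniform(0, 0.5, size=10_000)
    bg = rng.uniform(0, 1, size=10_000)
    comp = difftest.compare_distributions(real, bg)
    assert comp.ks_stat == pytest.approx(0.5, abs=0.02)
    assert comp.ks_p == difftest.P_FLOOR
    with pytest.raises(ValueError):
        difftest.compare_distributions([], [0.5])
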