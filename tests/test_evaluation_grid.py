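"""Cross-validation mechanics, grid runner, summary tables."""

import numpy as np
import pandas as pd
import pytest

from tetrags import (
    FilterConfig,
    GridConfig,
    SimConfig,
    allele_ratio,
    fit_blup,
    pairwise_improvement,
    predictive_ability,
    run_grid,
    simulate_population,
    simulate_trial,
    summarize,
)


def test_perfect_mock_predictor_gives_unit_correlation(rng):
    X = rng.random((40, 10))
    y = rng.normal(size=40)

    def oracle(train_X, train_y, test_X):
        # returns the held-out truth by matching rows of X
        idx = [np.flatnonzero((X == row).all(axis=1))[0] for row in test_X]
        return y[idx]

    r, sd = predictive_ability(X, y, k=5, repeats=3, seed=0, predictor=oracle)
    assert r == pytest.approx(1.0)
    assert sd == pytest.approx(0.0, abs=1e-12)


def test_folds_partition_samples_each_repeat(rng):
    X = rng.random((33, 5))
    y = rng.normal(size=33)
    seen = []

    def recorder(train_X, train_y, test_X):
        seen.append(test_X.shape[0])
        assert train_X.shape[0] + test_X.shape[0] == 33
        return np.zeros(test_X.shape[0])

    predictive_ability(X, y, k=4, repeats=2, seed=1, predictor=recorder)
    # 2 repeats x 4 folds covering all 33 samples each repeat
    assert len(seen) == 8
    assert sum(seen) == 2 * 33
    assert max(seen) - min(seen) <= 1


def test_zero_variance_prediction_warns_and_scores_zero(rng):
    X = rng.random((20, 4))
    y = rng.normal(size=20)

    def flat(train_X, train_y, test_X):
        return np.zeros(test_X.shape[0])

    with pytest.warns(UserWarning):
        r, _ = predictive_ability(X, y, k=4, repeats=1, seed=0, predictor=flat)
    assert r == 0.0


@pytest.fixture(scope="module")
def small_grid_inputs():
    cfg = SimConfig(n_genotypes=40, n_loci=150, n_qtl=30, seed=77,
                    h2_target={"t": 0.6})
    gt, rc, ann = simulate_population(cfg)
    blups, _ = fit_blup(simulate_trial(gt, cfg), "t", "E1")
    return rc, ann, {"t": blups}


def test_default_factor_levels_give_108_rows_per_trait(small_grid_inputs):
    rc, ann, phenos = small_grid_inputs
    gc = GridConfig(k=4, repeats=1, seed=0)
    gr = run_grid(gc, rc, ann, phenos)
    assert len(gr) == 4 * 3 * 3 * 3  # depth x missing x parametrization x subset
    assert set(gr["trait"]) == {"t"}


def test_single_cell_grid_matches_direct_call(small_grid_inputs):
    rc, ann, phenos = small_grid_inputs
    gc = GridConfig(min_reads=(10,), max_missing=(0.2,),
                    parametrizations=("ratio",), subsets=("all",),
                    k=5, repeats=2, seed=9)
    gr = run_grid(gc, rc, ann, phenos)
    assert len(gr) == 1
    g = allele_ratio(rc, FilterConfig(min_reads=10, max_missing=0.2))
    from tetrags.evaluation_grid import _config_seed
    cs = _config_seed(9, "t", "all", "ratio", 0.2, 10)
    y = phenos["t"].reindex(rc.samples).to_numpy()
    r, sd = predictive_ability(g, y, k=5, repeats=2, seed=cs)
    assert gr["pred_ability_mean"].iloc[0] == pytest.approx(r)
    assert gr["n_markers"].iloc[0] == g.n_markers


def test_grid_rerun_is_identical_and_seed_sensitive(small_grid_inputs):
    rc, ann, phenos = small_grid_inputs
    gc = GridConfig(min_reads=(10,), max_missing=(0.2,),
                    parametrizations=("ratio",), k=4, repeats=2, seed=5)
    a = run_grid(gc, rc, ann, phenos)
    b = run_grid(gc, rc, ann, phenos)
    pd.testing.assert_frame_equal(a, b)
    gc2 = GridConfig(min_reads=(10,), max_missing=(0.2,),
                     parametrizations=("ratio",), k=4, repeats=2, seed=6)
    c = run_grid(gc2, rc, ann, phenos)
    assert not np.allclose(a["pred_ability_mean"], c["pred_ability_mean"])


def test_predictive_ability_increases_with_heritability():
    cfg0 = SimConfig(n_genotypes=80, n_loci=300, n_qtl=60, seed=31)
    gt, rc, ann = simulate_population(cfg0)
    tbv = gt.true_breeding_values[:, 0]
    a = (tbv - tbv.mean()) / tbv.std()
    X = gt.true_dosages.astype(float)
    means = []
    for h2 in (0.1, 0.8):
        rs = []
        for s in range(10):
            r = np.random.default_rng(1000 + s)
            noise_sd = np.sqrt((1 - h2) / h2)
            y = a + r.normal(0, noise_sd, size=80)
            rs.append(predictive_ability(X, y, k=5, repeats=2, seed=s)[0])
        means.append(np.mean(rs))
    assert means[1] > means[0]


def test_summarize_tables_and_tie_breaking():
    gr = pd.DataFrame({
        "trait": ["t"] * 4,
        "subset": ["all", "all", "genic", "genic"],
        "parametrization": ["ratio", "tetraploid", "ratio", "tetraploid"],
        "max_missing": [0.05] * 4,
        "min_reads": [10] * 4,
        "n_markers": [100, 50, 80, 50],
        "pred_ability_mean": [0.3, 0.3, 0.2, 0.1],
        "pred_ability_sd": [0.01] * 4,
    })
    s = summarize(gr)
    # tie at 0.3 broken by fewer markers
    assert s["best"].iloc[0]["n_markers"] == 50
    assert s["marginal_parametrization"]["ratio"] == pytest.approx(0.25)
    imp = s["improvement_parametrization"]
    assert imp.loc["ratio", "tetraploid"] == pytest.approx(25.0)


def test_pairwise_improvement_arithmetic():
    assert pairwise_improvement(0.232, 0.215) == pytest.approx(7.907, abs=1e-3)
    assert pairwise_improvement(1.0, 1.0) == 0.0


def test_na_configurations_do_not_abort(small_grid_inputs, rng):
    rc, ann, phenos = small_grid_inputs
    # absurd depth requirement: every marker is dropped, rows report NA
    gc = GridConfig(min_reads=(10_000,), max_missing=(0.05,),
                    parametrizations=("ratio",), k=4, repeats=1, seed=0)
    gr = run_grid(gc, rc, ann, phenos)
    assert gr["pred_ability_mean"].isna().all()
    assert (gr["n_markers"] == 0).all()
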