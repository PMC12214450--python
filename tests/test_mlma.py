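import numpy as np
import pandas as pd
import pytest

from contestmeta.dataio import DataError
from contestmeta.mlma import (
    MODERATOR_CELLS,
    RandomTerm,
    build_design,
    cell_means,
    dataset_frame,
    fit_dataset,
    reml_fit,
    reml_neg2_criterion,
    wald_qm,
)


def test_no_random_terms_equals_inverse_variance_weighted_mean():
    y = np.array([0.2, 0.6])
    v = np.array([0.04, 0.04])
    fit = reml_fit(y, v, np.ones((2, 1)), coef_names=["intercept"])
    assert fit.coef["intercept"] == pytest.approx(0.4, abs=1e-12)
    assert fit.se["intercept"] == pytest.approx(np.sqrt(1 / (25 + 25)), abs=1e-12)


def test_wls_closed_form_general():
    rng = np.random.default_rng(4)
    n = 15
    y = rng.normal(0.3, 0.4, n)
    v = rng.uniform(0.02, 0.3, n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    fit = reml_fit(y, v, X)
    W = np.diag(1 / v)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    assert np.allclose(fit.coef.to_numpy(), beta, atol=1e-12)
    assert np.allclose(
        fit.vcov.to_numpy(), np.linalg.inv(X.T @ W @ X), atol=1e-12
    )


def _toy_single_factor():
    # 6 observations, one random factor with 3 groups
    y = np.array([0.1, 0.5, 0.9, 0.3, -0.2, 0.6])
    v = np.array([0.05, 0.08, 0.04, 0.1, 0.06, 0.05])
    X = np.ones((6, 1))
    term = RandomTerm("g", ("a", "a", "b", "b", "c", "c"))
    return y, v, X, term


def test_reml_matches_grid_search_oracle():
    """Brute-force grid + refinement over sigma2 in [0, 2] agrees to 1e-4."""
    y, v, X, term = _toy_single_factor()

    def crit(s2):
        return reml_neg2_criterion(y, v, X, [term], [s2])

    grid = np.linspace(0.0, 2.0, 2001)
    values = [crit(s) for s in grid]
    best = grid[int(np.argmin(values))]
    lo, hi = max(best - 0.002, 0.0), best + 0.002
    fine = np.linspace(lo, hi, 4001)
    best_fine = fine[int(np.argmin([crit(s) for s in fine]))]

    fit = reml_fit(y, v, X, [term])
    assert fit.coef_names == ["b0"]
    assert fit.sigma2["g"] == pytest.approx(best_fine, abs=1e-4)
    # the optimizer's criterion is at least as good as any probed point
    assert fit.criterion <= min(values) + 1e-8


def test_criterion_at_optimum_not_worse_than_random_probes():
    y, v, X, term = _toy_single_factor()
    fit = reml_fit(y, v, X, [term])
    rng = np.random.default_rng(0)
    for s2 in rng.uniform(0, 2, 50):
        assert fit.criterion <= reml_neg2_criterion(y, v, X, [term], [s2]) + 1e-8


def test_duplicating_observations_with_double_variance_keeps_beta():
    # fixed-effect model: duplicating every row at half weight leaves beta unchanged
    rng = np.random.default_rng(9)
    n = 12
    y = rng.normal(0.2, 0.3, n)
    v = rng.uniform(0.05, 0.2, n)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    fit = reml_fit(y, v, X)
    fit_dup = reml_fit(np.r_[y, y], np.r_[2 * v, 2 * v], np.vstack([X, X]))
    assert np.allclose(fit.coef.to_numpy(), fit_dup.coef.to_numpy(), atol=1e-10)


def test_row_order_and_level_labels_do_not_matter(small_sim):
    dataset, _ = small_sim
    frame = dataset_frame(dataset)
    X = build_design(frame)
    terms = [RandomTerm("species", tuple(frame["species"])),
             RandomTerm("obs", tuple(frame["effect_id"]))]
    fit = reml_fit(frame["z"].to_numpy(), frame["v"].to_numpy(), X, terms)

    perm = np.random.default_rng(1).permutation(len(frame))
    frame_p = frame.iloc[perm].reset_index(drop=True)
    relabel = {sp: f"taxon_{i}" for i, sp in enumerate(sorted(set(frame_p["species"])))}
    terms_p = [RandomTerm("species", tuple(relabel[s] for s in frame_p["species"])),
               RandomTerm("obs", tuple(frame_p["effect_id"]))]
    fit_p = reml_fit(frame_p["z"].to_numpy(), frame_p["v"].to_numpy(),
                     build_design(frame_p), terms_p)
    assert np.allclose(fit.coef.to_numpy(), fit_p.coef.to_numpy(), atol=1e-6)
    assert fit.sigma2["species"] == pytest.approx(fit_p.sigma2["species"], abs=1e-6)


def test_input_validation_errors():
    y = np.array([0.1, 0.2, 0.3])
    with pytest.raises(DataError, match="rank deficient"):
        reml_fit(y, np.full(3, 0.1), np.ones((3, 2)))
    with pytest.raises(DataError, match="positive"):
        reml_fit(y, np.array([0.1, -0.1, 0.2]), np.ones((3, 1)))
    with pytest.raises(DataError, match="shape mismatch"):
        reml_fit(y, np.full(4, 0.1), np.ones((3, 1)))


class TestWaldQM:
    def test_zero_coefficients_give_zero_statistic(self):
        # build a fit, then zero out the tested coefficients
        rng = np.random.default_rng(2)
        n = 20
        X = pd.DataFrame({"intercept": np.ones(n), "m": rng.normal(size=n)})
        fit = reml_fit(rng.normal(size=n), np.full(n, 0.1), X)
        fit.coef["m"] = 0.0
        qm = wald_qm(fit, ["m"])
        assert qm.statistic == pytest.approx(0.0, abs=1e-20)
        assert qm.p == pytest.approx(1.0)

    def test_single_coefficient_is_squared_z_score(self):
        n = 30
        rng = np.random.default_rng(3)
        X = pd.DataFrame({"intercept": np.ones(n), "m": rng.normal(size=n)})
        fit = reml_fit(rng.normal(size=n) + 2 * X["m"], np.full(n, 0.1), X)
        qm = wald_qm(fit, ["m"])
        z = fit.coef["m"] / fit.se["m"]
        assert qm.statistic == pytest.approx(z * z, rel=1e-10)
        assert qm.df == 1

    def test_intercept_excluded(self, small_sim):
        dataset, _ = small_sim
        fit = fit_dataset(dataset, random=("species", "obs"))
        with pytest.raises(DataError, match="intercept"):
            wald_qm(fit, ["intercept", "role[winner]"])
        assert wald_qm(fit).df == 3


class TestCellMeans:
    def test_intercept_only_model_single_cell(self):
        y = np.array([0.2, 0.6, 0.1])
        v = np.full(3, 0.04)
        fit = reml_fit(y, v, pd.DataFrame({"intercept": np.ones(3)}))
        (cell,) = cell_means(fit, [("loser", "high")])
        assert cell.mean_z == pytest.approx(fit.coef["intercept"])
        assert cell.ci_low == pytest.approx(cell.mean_z - 1.959963984540054 * cell.se)

    def test_mean_r_is_tanh_of_mean_z(self, small_sim):
        dataset, _ = small_sim
        fit = fit_dataset(dataset, random=("species", "obs"))
        for cell in cell_means(fit):
            assert cell.mean_r == pytest.approx(np.tanh(cell.mean_z))
            assert cell.ci_low <= cell.mean_z <= cell.ci_high

    def test_cells_reproduce_treatment_coding(self, small_sim):
        dataset, _ = small_sim
        fit = fit_dataset(dataset, random=("species", "obs"))
        means = {c.cell: c.mean_z for c in cell_means(fit, MODERATOR_CELLS)}
        b = fit.coef
        assert means[("loser", "high")] == pytest.approx(b["intercept"])
        assert means[("winner", "low")] == pytest.approx(
            b["intercept"] + b["role[winner]"] + b["cost[low]"] + b["role[winner]:cost[low]"]
        )


def test_design_reference_cell_is_loser_high():
    frame = pd.DataFrame(
        {"role": ["loser", "winner", "loser", "winner"],
         "cost_category": ["high", "high", "low", "low"]}
    )
    X = build_design(frame)
    assert list(X.columns) == ["intercept", "role[winner]", "cost[low]", "role[winner]:cost[low]"]
    assert X.to_numpy().tolist() == [
        [1, 0, 0, 0], [1, 1, 0, 0], [1, 0, 1, 0], [1, 1, 1, 1]]


def test_phylo_term_requires_tree(small_sim):
    dataset, _ = small_sim
    with pytest.raises(DataError, match="tree or a correlation"):
        fit_dataset(dataset, random=("species", "phylo", "obs"))
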