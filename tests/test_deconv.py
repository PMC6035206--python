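"""NNLS deconvolution, permutation significance, and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from ovimmune import (
    GeneSet,
    compare_fraction_groups,
    deconvolve,
    estimate_scores,
    filter_by_p,
)
from ovimmune.deconv import DeconvolutionResult, fractions_frame
from ovimmune.synthdata import SimulationConfig, simulate_signature

from conftest import make_matrix


@pytest.fixture(scope="module")
def signature():
    return simulate_signature(SimulationConfig(n_cell_types=4, n_markers_per_type=15))


def grid_oracle_two_types(S, m, resolution=2001):
    """Constrained least squares on a 2-type problem by brute-force grid.

    For each candidate fraction f the optimal non-negative scale has the
    closed form max(<v, m>/<v, v>, 0) with v = f*colA + (1-f)*colB.
    """
    best_f, best_loss = None, np.inf
    for f in np.linspace(0.0, 1.0, resolution):
        v = f * S[:, 0] + (1.0 - f) * S[:, 1]
        scale = max(float(v @ m) / float(v @ v), 0.0)
        loss = float(np.sum((scale * v - m) ** 2))
        if loss < best_loss:
            best_f, best_loss = f, loss
    return best_f


class TestDeconvolve:
    def test_pure_signature_column_recovered(self, signature):
        mixture = signature.iloc[:, 1].copy()
        result = deconvolve(mixture, signature, n_perm=20, seed=0)
        assert result.fractions.iloc[1] == pytest.approx(1.0, abs=1e-9)
        assert result.rmse == pytest.approx(0.0, abs=1e-8)

    def test_even_two_type_mixture(self, signature):
        mixture = 0.5 * signature.iloc[:, 0] + 0.5 * signature.iloc[:, 2]
        result = deconvolve(mixture, signature, n_perm=20, seed=0)
        assert result.fractions.iloc[0] == pytest.approx(0.5, abs=1e-6)
        assert result.fractions.iloc[2] == pytest.approx(0.5, abs=1e-6)

    def test_scale_invariance_of_fractions(self, signature):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(4))
        mixture = pd.Series(
            signature.to_numpy() @ f, index=signature.index
        )
        a = deconvolve(mixture, signature, n_perm=10, seed=1)
        b = deconvolve(17.0 * mixture, signature, n_perm=10, seed=1)
        assert np.allclose(a.fractions, b.fractions, atol=1e-9)

    def test_matches_two_type_grid_oracle(self):
        sig2 = simulate_signature(
            SimulationConfig(n_cell_types=2, n_markers_per_type=20)
        )
        S = sig2.to_numpy()
        true_f = 0.37
        mixture = pd.Series(
            S @ np.array([true_f, 1 - true_f]), index=sig2.index
        )
        result = deconvolve(mixture, sig2, n_perm=5, seed=0)
        oracle_f = grid_oracle_two_types(S, mixture.to_numpy())
        assert result.fractions.iloc[0] == pytest.approx(true_f, abs=1e-6)
        assert result.fractions.iloc[0] == pytest.approx(oracle_f, abs=1e-3)

    def test_fractions_sum_to_one_and_nonnegative(self, signature):
        rng = np.random.default_rng(2)
        mixture = pd.Series(
            np.abs(rng.normal(10, 5, size=signature.shape[0])),
            index=signature.index,
        )
        result = deconvolve(mixture, signature, n_perm=10, seed=0)
        assert result.fractions.sum() == pytest.approx(1.0, abs=1e-6)
        assert (result.fractions >= 0).all()

    def test_too_few_shared_markers_rejected(self, signature):
        mixture = pd.Series([1.0, 2.0], index=signature.index[:2])
        with pytest.raises(ValueError, match="shared marker"):
            deconvolve(mixture, signature)

    def test_structured_mixture_beats_noise_in_p(self, signature):
        rng = np.random.default_rng(3)
        f = rng.dirichlet(np.ones(4))
        structured = pd.Series(
            signature.to_numpy() @ f + rng.normal(0, 0.5, signature.shape[0]),
            index=signature.index,
        )
        noise = pd.Series(
            rng.permutation(structured.to_numpy()), index=signature.index
        )
        p_structured = deconvolve(structured, signature, n_perm=200, seed=4).p
        p_noise = deconvolve(noise, signature, n_perm=200, seed=4).p
        assert p_structured < 0.05
        assert p_noise > p_structured


def result_with_p(sample, p):
    return DeconvolutionResult(
        sample=sample,
        fractions=pd.Series([0.5, 0.5], index=["a", "b"]),
        p=p, rmse=0.0, corr=1.0,
    )


class TestFilterByP:
    def test_all_uninformative_removed(self):
        results = [result_with_p(f"s{i}", 1.0) for i in range(3)]
        assert filter_by_p(results) == []

    def test_permissive_threshold_keeps_all(self):
        results = [result_with_p(f"s{i}", 1.0) for i in range(3)]
        assert len(filter_by_p(results, p_max=1.01)) == 3

    def test_threshold_is_strict(self):
        results = [result_with_p("s0", 0.1), result_with_p("s1", 0.0999)]
        kept = filter_by_p(results, p_max=0.1)
        assert [r.sample for r in kept] == ["s1"]


def fraction_results(case_values, control_values, cell="T_CD8"):
    results = []
    for i, v in enumerate(case_values):
        results.append(DeconvolutionResult(
            f"case{i}", pd.Series([v, 1 - v], index=[cell, "Other"]),
            p=0.01, rmse=0.0, corr=1.0))
    for i, v in enumerate(control_values):
        results.append(DeconvolutionResult(
            f"ctrl{i}", pd.Series([v, 1 - v], index=[cell, "Other"]),
            p=0.01, rmse=0.0, corr=1.0))
    labels = pd.Series(
        ["case"] * len(case_values) + ["control"] * len(control_values),
        index=[r.sample for r in results],
    )
    return results, labels


class TestCompareFractionGroups:
    def test_identical_groups_yield_p_one(self):
        results, labels = fraction_results([0.1, 0.2, 0.3], [0.3, 0.1, 0.2])
        out = compare_fraction_groups(results, labels)
        assert out.loc["T_CD8", "p"] == pytest.approx(1.0)

    def test_fully_separated_triples_exact_p(self):
        results, labels = fraction_results([0.7, 0.8, 0.9], [0.1, 0.2, 0.3])
        out = compare_fraction_groups(results, labels)
        assert out.loc["T_CD8", "p"] == pytest.approx(0.1)
        assert out.loc["T_CD8", "case_mean_pct"] == pytest.approx(80.0)

    def test_planted_m2_contrast_is_significant(self):
        rng = np.random.default_rng(0)
        case = np.clip(rng.normal(0.0078, 0.03, size=12), 0, 1)
        control = np.clip(rng.normal(0.1899, 0.03, size=200), 0, 1)
        results, labels = fraction_results(case, control, cell="M2_macrophage")
        out = compare_fraction_groups(results, labels)
        assert out.loc["M2_macrophage", "p"] < 0.001
        assert out.loc["M2_macrophage", "control_mean_pct"] == pytest.approx(
            18.99, abs=1.0
        )

    def test_fisher_mode_on_presence_absence(self):
        results, labels = fraction_results(
            [0.4, 0.5, 0.6, 0.7], [0.0, 0.0, 0.0, 0.0]
        )
        out = compare_fraction_groups(results, labels, test="fisher")
        assert out.loc["T_CD8", "p"] == pytest.approx(1 / 35)

    def test_degenerate_group_rejected(self):
        results, labels = fraction_results([0.5], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="two samples"):
            compare_fraction_groups(results, labels)


class TestEstimateScores:
    def build(self, immune_boost):
        genes = [f"g{i}" for i in range(30)]
        rng = np.random.default_rng(1)
        base = rng.normal(5, 1, size=(30, 8))
        base[:8, :4] += immune_boost  # immune genes up in cases
        m = make_matrix(base, ["case"] * 4 + ["control"] * 4, genes=genes)
        immune = GeneSet.from_iterable("immune", genes[:8])
        stromal = GeneSet.from_iterable("stromal", genes[8:16])
        return m, immune, stromal

    def test_identical_groups_show_no_difference(self):
        genes = [f"g{i}" for i in range(20)]
        rng = np.random.default_rng(2)
        col = rng.normal(5, 1, size=20)
        values = np.column_stack([col] * 6)
        m = make_matrix(values, ["case"] * 3 + ["control"] * 3, genes=genes)
        scores, pvals = estimate_scores(
            m, GeneSet.from_iterable("i", genes[:5]),
            GeneSet.from_iterable("s", genes[5:10]),
        )
        assert pvals["immune"] == pytest.approx(1.0)
        assert np.allclose(scores["combined"], scores["combined"].iloc[0])

    def test_planted_immune_high_group_separates_perfectly(self):
        m, immune, stromal = self.build(immune_boost=5.0)
        scores, pvals = estimate_scores(m, immune, stromal)
        case_scores = scores["immune"].iloc[:4]
        control_scores = scores["immune"].iloc[4:]
        assert case_scores.min() > control_scores.max()  # AUC 1.0
        assert pvals["immune"] < 0.05
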