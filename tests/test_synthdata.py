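"""The generators must honour their recorded ground truth exactly."""

import numpy as np
import pandas as pd
import pytest

from ovimmune import deconvolve
from ovimmune.synthdata import (
    SimulationConfig,
    simulate_cohorts,
    simulate_genome,
    simulate_group_fractions,
    simulate_mixtures,
    simulate_signature,
    simulate_structure_map,
    simulate_survival,
)
from ovimmune.survmeta import fit_cox, fixed_effect_meta


def cfg(**kwargs) -> SimulationConfig:
    base = dict(n_genes=200, n_de_genes=20, n_ffpe_genes=20,
                samples_per_cohort=8, n_control_cohorts=3, seed=5)
    base.update(kwargs)
    return SimulationConfig(**base)


class TestSimulateCohorts:
    def test_study_design_sample_counts(self):
        config = cfg(n_case_samples=12,
                     control_cohort_sizes=(200, 150, 150, 133, 100))
        matrices, _ = simulate_cohorts(config)
        case = matrices[0]
        assert case.n_samples == 12
        assert (case.metadata["phenotype"] == "case").all()
        assert (case.metadata["preservation"] == "FFPE").all()
        controls = matrices[1:]
        assert sum(m.n_samples for m in controls) == 733
        assert all((m.metadata["preservation"] == "FF").all() for m in controls)

    def test_noiseless_group_mean_logfc_is_exact(self):
        config = cfg(noise_sd=0.0, ffpe_shift=0.0)
        matrices, truth = simulate_cohorts(config)
        case = matrices[0].values.mean(axis=1)
        control = pd.concat([m.values for m in matrices[1:]], axis=1).mean(axis=1)
        diff = case - control
        for gene, lfc in truth.de_genes.items():
            assert diff[gene] == pytest.approx(lfc, abs=1e-12)
        non_de = diff.drop(list(truth.de_genes))
        assert np.allclose(non_de, 0.0)

    def test_no_planted_effect_means_identical_profiles(self):
        config = cfg(noise_sd=0.0, n_de_genes=0, ffpe_shift=0.0)
        matrices, _ = simulate_cohorts(config)
        case = matrices[0].values.iloc[:, 0]
        control = matrices[1].values.iloc[:, 0]
        assert np.allclose(case, control)

    def test_ffpe_shift_hits_only_ffpe_samples(self):
        config = cfg(noise_sd=0.0, n_de_genes=0, ffpe_shift=2.0)
        matrices, truth = simulate_cohorts(config)
        case, control = matrices[0], matrices[1]
        gene = sorted(truth.ffpe_genes)[0]
        delta = case.values.loc[gene].mean() - control.values.loc[gene].mean()
        assert delta == pytest.approx(2.0, abs=1e-12)

    def test_determinism_and_seed_sensitivity(self):
        a, _ = simulate_cohorts(cfg(seed=3))
        b, _ = simulate_cohorts(cfg(seed=3))
        c, _ = simulate_cohorts(cfg(seed=4))
        assert a[0].values.equals(b[0].values)
        assert not a[0].values.equals(c[0].values)

    def test_overlap_forbidden_by_default(self):
        with pytest.raises(ValueError, match="exceeds n_genes"):
            SimulationConfig(n_genes=30, n_de_genes=20, n_ffpe_genes=20).validate()
        SimulationConfig(
            n_genes=30, n_de_genes=20, n_ffpe_genes=20, allow_de_ffpe_overlap=True
        ).validate()

    def test_fraction_vectors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(
                n_cell_types=2, case_fractions=(0.5, 0.4),
                control_fractions=(0.5, 0.5),
            ).validate()


class TestSimulateMixtures:
    def test_one_hot_fraction_reproduces_signature_column(self):
        config = cfg()
        sig = simulate_signature(config)
        one_hot = np.zeros(sig.shape[1])
        one_hot[2] = 1.0
        fractions = pd.DataFrame([one_hot], index=["s0"], columns=sig.columns)
        matrix, truth = simulate_mixtures(sig, fractions, noise_sd=0.0, seed=0)
        expected = np.log2(sig.iloc[:, 2].to_numpy())
        assert np.allclose(matrix.values["s0"].to_numpy(), expected)
        assert truth.true_fractions.equals(fractions)

    def test_noiseless_mixture_is_exactly_recoverable(self):
        config = cfg()
        sig = simulate_signature(config)
        rng = np.random.default_rng(1)
        f = rng.dirichlet(np.ones(sig.shape[1]), size=3)
        fractions = pd.DataFrame(f, index=["a", "b", "c"], columns=sig.columns)
        matrix, _ = simulate_mixtures(sig, fractions, noise_sd=0.0, seed=0)
        for sample in fractions.index:
            result = deconvolve(2.0 ** matrix.values[sample], sig, n_perm=5, seed=0)
            assert np.abs(result.fractions - fractions.loc[sample]).max() < 1e-6

    def test_negative_fractions_rejected(self):
        sig = simulate_signature(cfg())
        bad = pd.DataFrame(
            [[-0.1] + [1.1 / (sig.shape[1] - 1)] * (sig.shape[1] - 1)],
            index=["s0"], columns=sig.columns,
        )
        with pytest.raises(ValueError, match="non-negative"):
            simulate_mixtures(sig, bad)

    def test_group_fraction_means_near_configured(self):
        config = cfg()
        fractions, labels = simulate_group_fractions(
            config, n_case=400, n_control=400
        )
        case_mean = fractions[labels == "case"].mean()
        assert np.abs(
            case_mean.to_numpy() - np.asarray(config.case_fractions)
        ).max() < 0.02


class TestSimulateGenome:
    def test_planted_cluster_holds_requested_fraction(self):
        config = cfg(cluster_fraction=0.3, cluster_span=1_000_000)
        _, truth = simulate_cohorts(config)
        ann, hotspot = simulate_genome(config, list(truth.de_genes))
        chrom, start, end, anchor = hotspot
        de = ann.loc[list(truth.de_genes)]
        inside = (
            (de["chrom"] == chrom) & (de["start"] >= start) & (de["start"] < end)
        ).sum()
        assert inside >= 0.3 * len(truth.de_genes)
        assert anchor in truth.de_genes
        assert ann.loc[anchor, "chrom"] == chrom

    def test_no_cluster_when_fraction_zero(self):
        config = cfg(cluster_fraction=0.0)
        _, truth = simulate_cohorts(config)
        _, hotspot = simulate_genome(config, list(truth.de_genes))
        assert hotspot is None

    def test_determinism(self):
        config = cfg()
        _, truth = simulate_cohorts(config)
        a, _ = simulate_genome(config, list(truth.de_genes))
        b, _ = simulate_genome(config, list(truth.de_genes))
        assert a.equals(b)

    def test_intervals_are_valid(self):
        config = cfg()
        _, truth = simulate_cohorts(config)
        ann, _ = simulate_genome(config, list(truth.de_genes))
        assert (ann["end"] > ann["start"]).all()
        assert set(ann.index) == set(f"g{i:04d}" for i in range(200))


class TestSimulateSurvival:
    def test_null_effect_gives_null_pooled_estimate(self):
        config = cfg(true_log_hr=0.0, n_survival_studies=5,
                     patients_per_study=400, seed=7)
        survival = simulate_survival(config)
        fits = [fit_cox(g) for _, g in survival.groupby("study")]
        meta = fixed_effect_meta(fits)
        assert abs(meta.beta) < 2.5 * meta.se

    def test_censoring_rate_approximate(self):
        config = cfg(censoring_rate=0.4, n_survival_studies=4,
                     patients_per_study=500)
        survival = simulate_survival(config)
        censored = 1.0 - survival["event"].mean()
        assert censored == pytest.approx(0.4, abs=0.07)

    def test_large_sample_recovery_of_planted_hazard(self):
        config = cfg(n_survival_studies=10, patients_per_study=2000, seed=2)
        survival = simulate_survival(config)
        fits = [
            fit_cox(g, covariates=("expression", "debulking", "stage"))
            for _, g in survival.groupby("study")
        ]
        meta = fixed_effect_meta(fits)
        assert meta.beta == pytest.approx(config.true_log_hr, abs=0.02)


class TestStructureMap:
    def test_enriched_structure_contains_planted_genes(self):
        config = cfg()
        _, truth = simulate_cohorts(config)
        structures, enriched = simulate_structure_map(config, list(truth.de_genes))
        overlap = len(structures[enriched] & set(truth.de_genes))
        assert overlap >= 0.5 * len(truth.de_genes)
        assert all(len(v) > 0 for v in structures.values())

    def test_all_structure_genes_in_universe(self):
        config = cfg()
        _, truth = simulate_cohorts(config)
        structures, _ = simulate_structure_map(config, list(truth.de_genes))
        universe = set(f"g{i:04d}" for i in range(200))
        for genes in structures.values():
            assert genes <= universe
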