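"""Synthetic-data generators with recorded ground truth.

Every input the analysis consumes can be simulated here with the
statistical structure the downstream methods assume: case/control
expression cohorts with planted differentially expressed (DE) genes and
preservation (FFPE) artefact genes, bulk mixtures of a known cell-type
signature, a gene map with one planted DE-gene cluster, multi-study
survival tables with a known log-hazard effect of expression, and a toy
brain-structure -> gene map with one enriched ("cerebellum-like")
structure.  Ground truth is returned alongside the data so recovery and
calibration tests can score the pipeline.

All randomness flows from one root seed; each generator draws from its
own substream (fixed spawn key), so adding or re-running one generator
never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import ExpressionMatrix

# mean immune-cell fractions used as group-level defaults for the mixture
# generator: six cell types with distinct case/control means plus a
# remainder compartment so each vector sums to one.
DEFAULT_CELL_TYPES = (
    "B_naive",
    "T_CD8",
    "Treg",
    "Monocyte",
    "T_CD4_memory_resting",
    "M2_macrophage",
    "Other",
)
DEFAULT_CASE_FRACTIONS = (0.0631, 0.258, 0.1632, 0.1168, 0.0003, 0.0078, 0.3908)
DEFAULT_CONTROL_FRACTIONS = (0.003, 0.041, 0.018, 0.0186, 0.0807, 0.1899, 0.6488)

# substream spawn keys, one per generator
_STREAM_COHORTS = 0
_STREAM_GENOME = 1
_STREAM_MIXTURES = 2
_STREAM_SURVIVAL = 3
_STREAM_STRUCTURES = 4
_STREAM_SIGNATURE = 5


def substream(seed: int | None, key: int) -> np.random.Generator:
    """Independent generator derived from the root seed and a fixed key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults mirror the study design at
    a size small enough for routine test runs (12 FFPE cases against five
    fresh-frozen control cohorts)."""

    n_genes: int = 2000
    n_chromosomes: int = 5
    chromosome_length: int = 100_000_000
    n_control_cohorts: int = 5
    samples_per_cohort: int = 40
    n_case_samples: int = 12
    n_de_genes: int = 100
    de_logfc_mean: float = 1.5
    de_logfc_sd: float = 0.3
    n_ffpe_genes: int = 150
    ffpe_shift: float = 1.0
    noise_sd: float = 0.3
    cluster_fraction: float = 0.3
    cluster_span: int = 1_000_000
    n_cell_types: int = len(DEFAULT_CELL_TYPES)
    n_markers_per_type: int = 20
    case_fractions: tuple[float, ...] = DEFAULT_CASE_FRACTIONS
    control_fractions: tuple[float, ...] = DEFAULT_CONTROL_FRACTIONS
    n_survival_studies: int = 10
    patients_per_study: int = 200
    true_log_hr: float = float(np.log(1.07))
    censoring_rate: float = 0.3
    seed: int = 0
    allow_de_ffpe_overlap: bool = False
    # optional explicit control cohort sizes (overrides n_control_cohorts x
    # samples_per_cohort; lets the study's 12-vs-733 design be expressed
    # exactly even though 733 is not divisible into equal cohorts)
    control_cohort_sizes: tuple[int, ...] | None = None

    def validate(self) -> "SimulationConfig":
        counts = {
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
            "chromosome_length": self.chromosome_length,
            "n_control_cohorts": self.n_control_cohorts,
            "samples_per_cohort": self.samples_per_cohort,
            "n_case_samples": self.n_case_samples,
            "n_cell_types": self.n_cell_types,
            "n_markers_per_type": self.n_markers_per_type,
            "n_survival_studies": self.n_survival_studies,
            "patients_per_study": self.patients_per_study,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if not self.allow_de_ffpe_overlap and (
            self.n_de_genes + self.n_ffpe_genes > self.n_genes
        ):
            raise ValueError(
                "n_de_genes + n_ffpe_genes exceeds n_genes (set "
                "allow_de_ffpe_overlap to permit shared genes)"
            )
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.cluster_span >= self.chromosome_length:
            raise ValueError("cluster_span must be smaller than chromosome_length")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        for name, frac in (
            ("case_fractions", self.case_fractions),
            ("control_fractions", self.control_fractions),
        ):
            arr = np.asarray(frac, dtype=float)
            if arr.size != self.n_cell_types:
                raise ValueError(f"{name} must have n_cell_types entries")
            if (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 (got {arr.sum()})")
        if self.control_cohort_sizes is not None:
            if any(s <= 0 for s in self.control_cohort_sizes):
                raise ValueError("control cohort sizes must be positive")
        return self

    @property
    def cohort_sizes(self) -> tuple[int, ...]:
        if self.control_cohort_sizes is not None:
            return tuple(self.control_cohort_sizes)
        return (self.samples_per_cohort,) * self.n_control_cohorts

    @property
    def n_control_samples(self) -> int:
        return sum(self.cohort_sizes)


@dataclass
class GroundTruth:
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> true logFC
    ffpe_genes: set[str] = field(default_factory=set)
    hotspot: tuple[str, int, int, str] | None = None  # chrom, start, end, anchor
    true_fractions: pd.DataFrame | None = None  # samples x cell types
    true_log_hr: float | None = None
    structure_map: dict[str, set[str]] | None = None
    enriched_structure: str | None = None


def gene_ids(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(n_genes)]


def simulate_cohorts(
    config: SimulationConfig,
) -> tuple[list[ExpressionMatrix], GroundTruth]:
    """One FFPE case cohort plus FF control cohorts with planted effects.

    Planted DE genes are shifted in case samples by their true logFC
    (random sign, N(de_logfc_mean, de_logfc_sd) magnitude); FFPE-affected
    genes are shifted by ``ffpe_shift`` in FFPE samples only; i.i.d.
    Gaussian noise with sd ``noise_sd`` is added on the log2 scale.
    """
    config.validate()
    rng = substream(config.seed, _STREAM_COHORTS)
    genes = gene_ids(config.n_genes)
    baseline = rng.uniform(5.0, 10.0, size=config.n_genes)

    idx = rng.permutation(config.n_genes)
    de_idx = idx[: config.n_de_genes]
    if config.allow_de_ffpe_overlap:
        ffpe_idx = rng.permutation(config.n_genes)[: config.n_ffpe_genes]
    else:
        ffpe_idx = idx[config.n_de_genes : config.n_de_genes + config.n_ffpe_genes]
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    magnitudes = rng.normal(config.de_logfc_mean, config.de_logfc_sd,
                            size=config.n_de_genes)
    logfcs = signs * magnitudes

    truth = GroundTruth(
        de_genes={genes[i]: float(lfc) for i, lfc in zip(de_idx, logfcs)},
        ffpe_genes={genes[i] for i in ffpe_idx},
    )

    de_effect = np.zeros(config.n_genes)
    de_effect[de_idx] = logfcs
    ffpe_effect = np.zeros(config.n_genes)
    ffpe_effect[ffpe_idx] = config.ffpe_shift

    matrices: list[ExpressionMatrix] = []

    def build(cohort: str, n_samples: int, phenotype: str, preservation: str):
        mean = baseline.copy()
        if phenotype == "case":
            mean = mean + de_effect
        if preservation == "FFPE":
            mean = mean + ffpe_effect
        noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))
        values = mean[:, None] + noise
        sample_ids = [f"{cohort}_s{j:03d}" for j in range(n_samples)]
        meta = pd.DataFrame(
            {
                "cohort": cohort,
                "preservation": preservation,
                "phenotype": phenotype,
            },
            index=sample_ids,
        )
        matrices.append(
            ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids), meta)
        )

    build("case_cohort", config.n_case_samples, "case", "FFPE")
    for c, size in enumerate(config.cohort_sizes):
        build(f"control_{c}", size, "control", "FF")
    return matrices, truth


def simulate_signature(config: SimulationConfig) -> pd.DataFrame:
    """Well-conditioned marker-gene signature: each cell type expresses its
    own markers highly (linear scale ~100) and others weakly (~1)."""
    rng = substream(config.seed, _STREAM_SIGNATURE)
    cell_types = list(DEFAULT_CELL_TYPES[: config.n_cell_types])
    if config.n_cell_types > len(DEFAULT_CELL_TYPES):
        cell_types += [
            f"type_{i}" for i in range(len(DEFAULT_CELL_TYPES), config.n_cell_types)
        ]
    n_markers = config.n_cell_types * config.n_markers_per_type
    marker_ids = [f"m{i:04d}" for i in range(n_markers)]
    values = rng.uniform(0.5, 2.0, size=(n_markers, config.n_cell_types))
    for k in range(config.n_cell_types):
        rows = slice(k * config.n_markers_per_type, (k + 1) * config.n_markers_per_type)
        values[rows, k] = rng.uniform(80.0, 120.0, size=config.n_markers_per_type)
    return pd.DataFrame(values, index=marker_ids, columns=cell_types)


def simulate_group_fractions(
    config: SimulationConfig,
    n_case: int | None = None,
    n_control: int | None = None,
    concentration: float = 150.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample fraction vectors around the group means.

    Samples are drawn from Dirichlet distributions centred on the case and
    control mean fraction vectors; ``concentration`` sets the per-sample
    spread (150 gives a component sd of roughly 3 percentage points for a
    20% component).  Returns the fraction frame and phenotype labels.
    """
    rng = substream(config.seed, _STREAM_MIXTURES)
    n_case = config.n_case_samples if n_case is None else n_case
    n_control = config.n_control_samples if n_control is None else n_control
    cell_types = list(DEFAULT_CELL_TYPES[: config.n_cell_types])
    rows, labels, ids = [], [], []
    for group, mean, n in (
        ("case", np.asarray(config.case_fractions), n_case),
        ("control", np.asarray(config.control_fractions), n_control),
    ):
        alpha = np.maximum(mean * concentration, 1e-3)
        draws = rng.dirichlet(alpha, size=n)
        for j in range(n):
            rows.append(draws[j])
            labels.append(group)
            ids.append(f"{group}_mix_{j:03d}")
    fractions = pd.DataFrame(rows, index=ids, columns=cell_types)
    return fractions, pd.Series(labels, index=ids, name="phenotype")


def simulate_mixtures(
    signature: pd.DataFrame,
    fractions: pd.DataFrame,
    noise_sd: float = 0.0,
    seed: int | None = None,
    phenotypes: pd.Series | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Bulk profiles as linear combinations of signature columns.

    Mixing happens on the linear scale (mixture = signature x fractions);
    the result is log2-transformed and Gaussian noise with sd ``noise_sd``
    is added on the log2 scale.  The true fractions are recorded.
    """
    if (fractions.to_numpy() < 0).any():
        raise ValueError("fractions must be non-negative")
    if not np.allclose(fractions.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each fraction vector must sum to 1")
    if set(fractions.columns) != set(signature.columns):
        raise ValueError("fraction labels must match signature cell types")
    rng = np.random.default_rng(seed)
    S = signature.to_numpy(dtype=float)
    F = fractions[signature.columns].to_numpy(dtype=float)
    linear = S @ F.T  # genes x samples
    log2 = np.log2(np.maximum(linear, 1e-12))
    log2 = log2 + rng.normal(0.0, noise_sd, size=log2.shape)
    if phenotypes is None:
        phenotypes = pd.Series("control", index=fractions.index)
    meta = pd.DataFrame(
        {
            "cohort": "mixture",
            "preservation": "FF",
            "phenotype": phenotypes.loc[fractions.index].to_numpy(),
        },
        index=fractions.index,
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(log2, index=signature.index, columns=fractions.index), meta
    )
    return matrix, GroundTruth(true_fractions=fractions.copy())


def simulate_genome(
    config: SimulationConfig, de_genes: Iterable[str]
) -> tuple[pd.DataFrame, tuple[str, int, int, str] | None]:
    """Gene map with a planted cluster of DE genes around an anchor.

    Genes are placed uniformly per chromosome except that
    ``cluster_fraction`` of the DE genes (including the anchor, the first
    DE gene) land inside one ``cluster_span`` window.  Returns the
    annotation (0-based half-open BED-like frame) and the recorded hotspot
    (chrom, start, end, anchor gene), or None when no cluster is planted.
    """
    config.validate()
    rng = substream(config.seed, _STREAM_GENOME)
    genes = gene_ids(config.n_genes)
    universe = set(genes)
    de_list = [g for g in de_genes]
    if not set(de_list) <= universe:
        raise ValueError("de_genes must be a subset of the gene universe")

    chroms = np.array([f"chr{i + 1}" for i in range(config.n_chromosomes)])
    chrom_assign = rng.integers(0, config.n_chromosomes, size=config.n_genes)
    starts = rng.integers(0, config.chromosome_length - 200_000, size=config.n_genes)
    lengths = rng.integers(1_000, 100_000, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)

    hotspot = None
    n_cluster = int(round(config.cluster_fraction * len(de_list)))
    if n_cluster >= 1 and de_list:
        if n_cluster > len(de_list):
            raise ValueError("cluster cannot hold more genes than the DE set")
        anchor = de_list[0]
        clustered = [anchor] + list(
            rng.choice(
                [g for g in de_list if g != anchor],
                size=max(n_cluster - 1, 0),
                replace=False,
            )
        )
        chrom_idx = int(rng.integers(0, config.n_chromosomes))
        wstart = int(
            rng.integers(0, config.chromosome_length - config.cluster_span)
        )
        wend = wstart + config.cluster_span
        pos = {g: i for i, g in enumerate(genes)}
        for g in clustered:
            i = pos[g]
            chrom_assign[i] = chrom_idx
            starts[i] = rng.integers(wstart, wend)
        hotspot = (str(chroms[chrom_idx]), wstart, wend, anchor)

    annotation = pd.DataFrame(
        {
            "chrom": chroms[chrom_assign],
            "start": starts,
            "end": starts + lengths,
            "strand": strands,
        },
        index=genes,
    )
    return annotation, hotspot


# covariate log-hazards used by the survival generator: suboptimal
# debulking and advanced stage both raise the hazard
DEBULKING_LOG_HR = 0.5
STAGE_LOG_HR = {"I": 0.0, "II": 0.3, "III/IV": 0.6}
BASELINE_HAZARD = 0.01  # events per month at the covariate reference


def simulate_survival(config: SimulationConfig) -> pd.DataFrame:
    """Multi-study survival tables with a planted expression effect.

    Expression is standard normal; event times are exponential with hazard
    h0*exp(true_log_hr*x + covariate effects); independent exponential
    censoring is tuned to the configured censoring rate.  Returns a
    stacked frame with columns study, time, event, expression, debulking,
    stage.
    """
    config.validate()
    rng = substream(config.seed, _STREAM_SURVIVAL)
    frames = []
    for s in range(config.n_survival_studies):
        n = config.patients_per_study
        x = rng.standard_normal(n)
        debulking = rng.choice(DEBULKING_LEVELS_ARR, size=n)
        stage = rng.choice(STAGE_LEVELS_ARR, size=n, p=[0.2, 0.2, 0.6])
        lp = (
            config.true_log_hr * x
            + DEBULKING_LOG_HR * (debulking == "suboptimal")
            + np.vectorize(STAGE_LOG_HR.get)(stage)
        )
        hazard = BASELINE_HAZARD * np.exp(lp)
        event_time = rng.exponential(1.0 / hazard)
        if config.censoring_rate > 0:
            cens_rate = (
                hazard.mean() * config.censoring_rate / (1.0 - config.censoring_rate)
            )
            censor_time = rng.exponential(1.0 / cens_rate, size=n)
        else:
            censor_time = np.full(n, np.inf)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        frames.append(
            pd.DataFrame(
                {
                    "study": f"study_{s:02d}",
                    "time": np.maximum(time, 1e-6),
                    "event": event,
                    "expression": x,
                    "debulking": debulking,
                    "stage": stage,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


DEBULKING_LEVELS_ARR = np.array(["optimal", "suboptimal"])
STAGE_LEVELS_ARR = np.array(["I", "II", "III/IV"])


def simulate_structure_map(
    config: SimulationConfig,
    de_genes: Iterable[str],
    n_structures: int = 20,
    genes_per_structure: int = 50,
    enriched_fraction: float = 0.5,
) -> tuple[dict[str, set[str]], str]:
    """Toy structure -> gene-set map with one DE-enriched structure.

    One designated structure (the "cerebellum-like" one) contains
    ``enriched_fraction`` of the planted DE genes topped up with random
    genes; all others are random draws from the universe.
    """
    rng = substream(config.seed, _STREAM_STRUCTURES)
    genes = np.array(gene_ids(config.n_genes))
    de_list = list(de_genes)
    structures: dict[str, set[str]] = {}
    enriched = "structure_00"
    n_planted = int(round(enriched_fraction * len(de_list)))
    planted = set(rng.choice(de_list, size=n_planted, replace=False)) if n_planted else set()
    fill = rng.choice(
        genes, size=max(genes_per_structure - len(planted), 0), replace=False
    )
    structures[enriched] = planted | set(fill)
    for s in range(1, n_structures):
        structures[f"structure_{s:02d}"] = set(
            rng.choice(genes, size=genes_per_structure, replace=False)
        )
    return structures, enriched


@dataclass
class SyntheticStudy:
    """Bundle of every simulated input plus the combined ground truth."""

    config: SimulationConfig
    cohorts: list[ExpressionMatrix]
    annotation: pd.DataFrame
    signature: pd.DataFrame
    mixtures: ExpressionMatrix
    survival: pd.DataFrame
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator off one root seed and merge the ground truth."""
    config.validate()
    cohorts, truth = simulate_cohorts(config)
    annotation, hotspot = simulate_genome(config, list(truth.de_genes))
    truth.hotspot = hotspot
    signature = simulate_signature(config)
    fractions, phenotypes = simulate_group_fractions(config)
    mixtures, mix_truth = simulate_mixtures(
        signature,
        fractions,
        noise_sd=config.noise_sd,
        seed=int(np.random.SeedSequence(entropy=config.seed,
                                        spawn_key=(_STREAM_MIXTURES, 1)).generate_state(1)[0]),
        phenotypes=phenotypes,
    )
    truth.true_fractions = mix_truth.true_fractions
    survival = simulate_survival(config)
    truth.true_log_hr = config.true_log_hr
    structures, enriched = simulate_structure_map(config, list(truth.de_genes))
    truth.structure_map = structures
    truth.enriched_structure = enriched
    return SyntheticStudy(
        config=config,
        cohorts=cohorts,
        annotation=annotation,
        signature=signature,
        mixtures=mixtures,
        survival=survival,
        truth=truth,
    )
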