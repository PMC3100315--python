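"""Synthetic cohorts with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes,
on the log2 scale with Gaussian noise (RMA-style summarized data):

* a four-subtype "human" cohort in which 723 classifier genes carry a
  class signal (between-class centroid SD 1.5 in units of the
  within-class noise SD) and the remaining genes are pure noise;
* a homogeneous "mouse" cohort drawn tightly around one subtype's
  centroid, with its own gene namespace, a one-to-one ortholog map that
  retains only part of the genes (default 723/840), and optional probe
  expansion to exercise probe collapsing;
* five disjoint 80-gene lineage sets, each shifted up by log2(1.5) in
  samples of its matching cell type;
* a patient cohort whose expression leans toward one of two genotype
  archetypes differing on planted differentially expressed genes, with
  exponential survival whose hazard grows with the lean toward the
  aggressive archetype, independent censoring, and four pseudo-dataset
  labels.

Everything is deterministic given ``SimConfig.seed``; each generator
draws from its own child stream so the four simulations do not perturb
one another.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneSetCollection, OrthologMap, SurvivalRecord

__all__ = [
    "SimConfig",
    "SubtypedCohort",
    "MouseCohort",
    "LineageSim",
    "GenotypeSurvivalSim",
    "simulate_subtyped_cohort",
    "simulate_mouse_cohort",
    "simulate_lineage_sets",
    "simulate_genotype_survival_cohort",
]

DEFAULT_CLASSES = ("Proneural", "Neural", "Classical", "Mesenchymal")
CELL_TYPES = ("OPC", "Oligodendrocyte", "Neuron", "Astrocyte", "CulturedAstroglia")


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs in one place; ``seed`` is mandatory.

    The defaults are the study conditions the rest of the package is
    validated under: 723 classifier genes over 4 subtypes with a
    between-class effect of 1.5 within-class SDs, ~86% ortholog
    retention (723/840), five disjoint 80-gene lineage sets at 1.5-fold
    enrichment, 200 planted DE genes at 1.5 SD, and exponential survival
    with hazard ratio 2.5 around a 553-day baseline median.
    """

    seed: int
    # subtype cohort
    n_genes: int = 1000
    n_classifier_genes: int = 723
    classes: tuple[str, ...] = DEFAULT_CLASSES
    samples_per_class: int = 20  # split into equal train/validation halves
    subtype_effect: float = 1.5  # between-class centroid SD / within-class SD
    within_class_sd: float = 1.0
    baseline_mean: float = 8.0  # log2-scale platform baseline
    baseline_sd: float = 1.0
    # mouse cohort
    n_mouse_samples: int = 20
    mouse_within_sd: float = 0.5
    ortholog_retention: float = 723.0 / 840.0
    probe_sd: float = 0.2
    # lineage sets
    n_lineage_sets: int = 5
    lineage_set_size: int = 80
    fold_enrichment: float = 1.5
    samples_per_type: int = 10
    replicate_sd: float = 0.5
    # genotype / DE / survival cohort
    n_de_genes: int = 200
    de_effect: float = 1.5
    n_patients: int = 80
    n_datasets: int = 4
    aggressive_fraction: float = 1.0 / 3.0
    lean_sd: float = 0.15
    baseline_hazard: float = math.log(2.0) / 553.0  # per day
    hazard_ratio: float = 2.5
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        counts = (self.n_genes, self.n_classifier_genes, self.samples_per_class,
                  self.n_mouse_samples, self.n_lineage_sets, self.lineage_set_size,
                  self.samples_per_type, self.n_de_genes, self.n_patients, self.n_datasets)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not 0.0 < self.ortholog_retention <= 1.0:
            raise ValueError("ortholog_retention must be in (0, 1]")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")
        if self.n_classifier_genes > self.n_genes:
            raise ValueError("n_classifier_genes cannot exceed n_genes")
        if not 0.0 < self.aggressive_fraction < 1.0:
            raise ValueError("aggressive_fraction must be in (0, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        """A child generator for one simulation stream."""
        return np.random.default_rng([self.seed, stream])


def _gene_names(n: int) -> list[str]:
    return [f"GENE{i:05d}" for i in range(1, n + 1)]


def _mouse_name(human: str) -> str:
    return "m" + human.capitalize()


@dataclass(frozen=True)
class SubtypedCohort:
    train: ExpressionMatrix
    validation: ExpressionMatrix
    labels: Mapping[str, str]  # every sample, train and validation
    centroids: pd.DataFrame  # ground-truth gene x class means (classifier genes only)
    classifier_genes: tuple[str, ...]


def simulate_subtyped_cohort(config: SimConfig) -> SubtypedCohort:
    """A labeled multi-subtype cohort split into train/validation halves."""
    if config.samples_per_class < 2:
        raise ValueError("samples_per_class must be >=2 to split into train and validation")
    rng = config.rng(1)
    genes = _gene_names(config.n_genes)
    classifier = genes[: config.n_classifier_genes]
    k = len(config.classes)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    centroids = np.zeros((config.n_genes, k))
    centroids[: config.n_classifier_genes] = rng.normal(
        0.0, config.subtype_effect, size=(config.n_classifier_genes, k)
    )

    sample_ids, labels, columns = [], {}, []
    for ci, cls in enumerate(config.classes):
        for j in range(config.samples_per_class):
            sid = f"HS_{cls[:4].upper()}_{j:03d}"
            sample_ids.append(sid)
            labels[sid] = cls
            noise = rng.normal(0.0, config.within_class_sd, size=config.n_genes)
            columns.append(baseline + centroids[:, ci] + noise)

    data = pd.DataFrame(np.column_stack(columns), index=genes, columns=sample_ids)
    half = config.samples_per_class // 2
    train_cols, val_cols = [], []
    for cls in config.classes:
        members = [s for s in sample_ids if labels[s] == cls]
        train_cols.extend(members[:half])
        val_cols.extend(members[half:])
    truth = pd.DataFrame(centroids[: config.n_classifier_genes], index=classifier,
                         columns=list(config.classes))
    return SubtypedCohort(
        train=ExpressionMatrix(data[train_cols], species="synthetic", state="summarized"),
        validation=ExpressionMatrix(data[val_cols], species="synthetic", state="summarized"),
        labels=labels,
        centroids=truth,
        classifier_genes=tuple(classifier),
    )


@dataclass(frozen=True)
class MouseCohort:
    matrix: ExpressionMatrix  # gene-level, mouse namespace
    ortholog_map: OrthologMap  # human symbol -> mouse symbol
    target_class: str
    probe_matrix: ExpressionMatrix | None = None
    probe_map: Mapping[str, str] | None = None  # probe id -> mouse gene


def simulate_mouse_cohort(
    config: SimConfig,
    centroids: pd.DataFrame,
    target_class: str = "Proneural",
    with_probes: bool = False,
) -> MouseCohort:
    """A homogeneous cohort around one subtype centroid, own namespace.

    All samples share the ``target_class`` expression program with
    reduced between-sample variance (``mouse_within_sd``).  The ortholog
    map covers a random ``ortholog_retention`` fraction of the genes;
    with ``with_probes`` each gene is additionally expanded into 2-3
    probes with small probe-level perturbations.
    """
    if target_class not in centroids.columns:
        raise ValueError(f"target_class {target_class!r} not among centroid classes")
    rng = config.rng(2)
    genes = _gene_names(config.n_genes)
    signal = np.zeros(config.n_genes)
    idx = {g: i for i, g in enumerate(genes)}
    for g in centroids.index:
        if g in idx:
            signal[idx[g]] = centroids.loc[g, target_class]

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    cols = []
    sample_ids = [f"MUS_{j:03d}" for j in range(config.n_mouse_samples)]
    for _ in sample_ids:
        cols.append(baseline + signal + rng.normal(0.0, config.mouse_within_sd,
                                                   size=config.n_genes))
    mouse_genes = [_mouse_name(g) for g in genes]
    data = pd.DataFrame(np.column_stack(cols), index=mouse_genes, columns=sample_ids)

    n_keep = int(round(config.ortholog_retention * config.n_genes))
    keep = sorted(rng.choice(config.n_genes, size=n_keep, replace=False))
    omap = OrthologMap({genes[i]: mouse_genes[i] for i in keep})

    probe_matrix = probe_map = None
    if with_probes:
        probe_rows, probe_ids, pmap = [], [], {}
        for gi, mg in enumerate(mouse_genes):
            for p in range(int(rng.integers(2, 4))):
                pid = f"{mg}_at{p}"
                probe_ids.append(pid)
                pmap[pid] = mg
                probe_rows.append(data.iloc[gi].to_numpy()
                                  + rng.normal(0.0, config.probe_sd, size=len(sample_ids)))
        probe_matrix = ExpressionMatrix(
            pd.DataFrame(np.vstack(probe_rows), index=probe_ids, columns=sample_ids),
            species="mouse", state="summarized",
        )
        probe_map = pmap

    return MouseCohort(
        matrix=ExpressionMatrix(data, species="mouse", state="summarized"),
        ortholog_map=omap,
        target_class=target_class,
        probe_matrix=probe_matrix,
        probe_map=probe_map,
    )


@dataclass(frozen=True)
class LineageSim:
    matrix: ExpressionMatrix
    sets: GeneSetCollection
    cell_types: Mapping[str, str]  # sample -> cell type (== matching set name)


def simulate_lineage_sets(config: SimConfig) -> LineageSim:
    """Cell-type samples with disjoint lineage sets planted at a fold change.

    For a sample of cell type k, the genes of set k are shifted up by
    log2(fold_enrichment); all other genes stay at their baseline.
    """
    needed = config.n_lineage_sets * config.lineage_set_size
    if needed > config.n_genes:
        raise ValueError(
            f"{config.n_lineage_sets} disjoint sets of {config.lineage_set_size} genes need "
            f"{needed} genes but only {config.n_genes} are simulated"
        )
    rng = config.rng(3)
    genes = _gene_names(config.n_genes)
    type_names = [CELL_TYPES[i % len(CELL_TYPES)] if config.n_lineage_sets <= len(CELL_TYPES)
                  else f"TYPE{i}" for i in range(config.n_lineage_sets)]
    sets = {
        type_names[i]: set(genes[i * config.lineage_set_size:(i + 1) * config.lineage_set_size])
        for i in range(config.n_lineage_sets)
    }
    shift = math.log2(config.fold_enrichment)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    cols, sample_ids, cell_types = [], [], {}
    for ti, tname in enumerate(type_names):
        member = np.zeros(config.n_genes)
        lo = ti * config.lineage_set_size
        member[lo:lo + config.lineage_set_size] = shift
        for j in range(config.samples_per_type):
            sid = f"{tname.upper()}_{j:03d}"
            sample_ids.append(sid)
            cell_types[sid] = tname
            cols.append(baseline + member + rng.normal(0.0, config.replicate_sd,
                                                       size=config.n_genes))
    data = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)
    return LineageSim(
        matrix=ExpressionMatrix(data, species="synthetic", state="summarized"),
        sets=GeneSetCollection(sets),
        cell_types=cell_types,
    )


@dataclass(frozen=True)
class GenotypeSurvivalSim:
    matrix: ExpressionMatrix
    genotype: Mapping[str, str]  # sample -> "PtenP53" (aggressive) | "Pten"
    up_in_aggressive: frozenset  # planted genes higher in the PtenP53 archetype
    up_in_indolent: frozenset
    survival: tuple[SurvivalRecord, ...]
    lean: Mapping[str, float]  # latent lean toward the aggressive archetype
    datasets: Mapping[str, str]

    AGGRESSIVE: str = field(default="PtenP53", init=False)
    INDOLENT: str = field(default="Pten", init=False)


def simulate_genotype_survival_cohort(config: SimConfig) -> GenotypeSurvivalSim:
    """Patients leaning toward one of two genotype archetypes, with survival.

    Half the planted DE genes are higher in the aggressive archetype,
    half in the indolent one, separated by ``de_effect`` within-group
    SDs between pure archetypes.  Each sample's latent lean toward the
    aggressive archetype is +-0.5 (by genotype) plus Gaussian jitter;
    its hazard is ``baseline_hazard * hazard_ratio**lean01`` with lean01
    the lean mapped to [0, 1].  Censoring is an independent competing
    exponential tuned so that about ``censoring_rate`` of follow-ups end
    censored.  Samples are assigned round-robin to pseudo-datasets.
    """
    rng = config.rng(4)
    n = config.n_patients
    genes = _gene_names(config.n_genes)
    half_de = config.n_de_genes // 2
    up_a = genes[:half_de]
    up_b = genes[half_de: 2 * half_de]
    d = np.zeros(config.n_genes)
    d[:half_de] = config.de_effect
    d[half_de: 2 * half_de] = -config.de_effect

    n_aggr = int(round(n * config.aggressive_fraction))
    genotype_arr = np.array(["PtenP53"] * n_aggr + ["Pten"] * (n - n_aggr))
    rng.shuffle(genotype_arr)
    lean_arr = np.where(genotype_arr == "PtenP53", 0.5, -0.5) + rng.normal(
        0.0, config.lean_sd, size=n
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    sample_ids = [f"PT_{j:03d}" for j in range(n)]
    cols = [baseline + lean_arr[j] * d + rng.normal(0.0, 1.0, size=config.n_genes)
            for j in range(n)]
    data = pd.DataFrame(np.column_stack(cols), index=genes, columns=sample_ids)

    lean01 = np.clip(lean_arr + 0.5, 0.0, 1.0)
    hazards = config.baseline_hazard * config.hazard_ratio ** lean01
    event_times = rng.exponential(1.0 / hazards)
    records = []
    datasets = {}
    for j, sid in enumerate(sample_ids):
        ds = f"D{(j % config.n_datasets) + 1}"
        datasets[sid] = ds
        if config.censoring_rate >= 1.0:
            time, event = event_times[j], 0
        elif config.censoring_rate <= 0.0:
            time, event = event_times[j], 1
        else:
            c_rate = hazards[j] * config.censoring_rate / (1.0 - config.censoring_rate)
            censor_time = rng.exponential(1.0 / c_rate)
            time = min(event_times[j], censor_time)
            event = int(event_times[j] <= censor_time)
        records.append(SurvivalRecord(sample_id=sid, time=float(max(time, 1e-9)),
                                      event=event, dataset=ds))

    return GenotypeSurvivalSim(
        matrix=ExpressionMatrix(data, species="synthetic", state="summarized"),
        genotype=dict(zip(sample_ids, genotype_arr)),
        up_in_aggressive=frozenset(up_a),
        up_in_indolent=frozenset(up_b),
        survival=tuple(records),
        lean=dict(zip(sample_ids, lean_arr)),
        datasets=datasets,
    )
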