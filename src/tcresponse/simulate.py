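"""Synthetic data emulating the study design, for testing every stage.

The generator produces the three-condition treatment time course
(untreated, 30 min, 3 h) as a gene x sample negative-binomial count
matrix with kinetic classes planted per gene, plus a toy ``is_a``
ontology with gene annotations, BGC membership tables and a
confrontation-assay gradient grid. It stands in for the deposited raw
sequencing data so the whole pipeline is testable offline.

Counts are NB with variance ``m + phi*m^2`` (``phi = 0`` degenerates to
Poisson). Planted log2 effects act cumulatively: condition means are
``b, b*2^e1, b*2^(e1+e2)`` for baseline ``b`` and per-window effects
``e1, e2`` whose signs follow the planted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from tcresponse.containers import TIME_POINTS, CountExperiment
from tcresponse.enrichment import OntologyGraph, propagate_annotations
from tcresponse.kinetics import CLASS_LABELS
from tcresponse.spatial import ABSORBANCE, SpatialGrid

#: Planted sign pattern (window 1, window 2) per kinetic class.
CLASS_SIGNS: dict[str, tuple[int, int]] = {
    "A1": (1, 0), "A2": (-1, 0),
    "B1": (1, 1), "B2": (-1, -1),
    "C1": (0, 1), "C2": (0, -1),
    "D1": (1, -1), "D2": (-1, 1),
    "none": (0, 0),
}


def _default_proportions() -> dict[str, float]:
    # roughly the regulated fraction observed in the study (~1.8k of ~10k
    # genes), spread evenly over the eight classes
    props = {label: 0.02 for label in CLASS_LABELS if label != "none"}
    props["none"] = 1.0 - sum(props.values())
    return props


@dataclass
class SimulationConfig:
    """Study-condition parameters for the count simulator.

    ``effect_size`` is the planted |log2FC| of each significant step
    (default 2, comfortably above the >1 regulation gate);
    ``dispersion`` is the NB dispersion phi (variance ``m + phi*m^2``);
    ``library_size_range`` optionally rescales each sample to a target
    column sum (``None`` leaves the drawn per-gene means untouched).
    """

    n_genes: int = 2000
    n_replicates: int = 3          # per condition; not stated by the study
    time_points: tuple[str, str, str] = TIME_POINTS
    class_proportions: dict[str, float] = field(default_factory=_default_proportions)
    effect_size: float = 2.0
    baseline_log2_mean_range: tuple[float, float] = (3.0, 10.0)
    dispersion: float = 0.05
    library_size_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        if len(self.time_points) != 3:
            raise ValueError("exactly three time points expected")
        unknown = set(self.class_proportions) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown kinetic classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9 or min(self.class_proportions.values()) < 0:
            raise ValueError("class proportions must be non-negative and sum to 1")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class PlantedTruth:
    """Ground truth of the simulation: class and per-window effects per gene."""

    table: pd.DataFrame  # index gene_id; true_class, effect_w1, effect_w2

    def classes(self) -> pd.Series:
        return self.table["true_class"]


def _rng(seed: int, stage: int) -> np.random.Generator:
    # one global seed; per-stage child streams derived deterministically
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    if phi == 0:
        return rng.poisson(mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimulationConfig) -> tuple[CountExperiment, PlantedTruth]:
    """NB count matrix with planted kinetic classes.

    Returns the experiment (counts + design) and the planted truth.
    Reproducible for a fixed ``config.seed``.
    """
    rng = _rng(config.seed, stage=0)
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]

    labels = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in labels])
    classes = rng.choice(labels, size=config.n_genes, p=probs)
    signs = np.array([CLASS_SIGNS[c] for c in classes], dtype=float)
    effects = signs * config.effect_size          # genes x 2, log2 units

    lo, hi = config.baseline_log2_mean_range
    baseline = 2.0 ** rng.uniform(lo, hi, size=config.n_genes)
    cond_means = np.column_stack([
        baseline,
        baseline * 2.0 ** effects[:, 0],
        baseline * 2.0 ** (effects[:, 0] + effects[:, 1]),
    ])

    sample_ids, times, reps = [], [], []
    cols = []
    for t_idx, tp in enumerate(config.time_points):
        for r in range(1, config.n_replicates + 1):
            sample_ids.append(f"t{t_idx}_r{r}")
            times.append(tp)
            reps.append(r)
            m = cond_means[:, t_idx].copy()
            if config.library_size_range is not None:
                target = rng.uniform(*config.library_size_range)
                m *= target / m.sum()
            cols.append(_nb_draw(rng, m, config.dispersion))

    counts = pd.DataFrame(
        np.column_stack(cols), index=pd.Index(genes, name="gene_id"), columns=sample_ids
    )
    design = pd.DataFrame(
        {"time": times, "replicate": reps}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = pd.DataFrame(
        {"true_class": classes, "effect_w1": effects[:, 0], "effect_w2": effects[:, 1]},
        index=counts.index,
    )
    return CountExperiment(counts, design), PlantedTruth(truth)


# ---------------------------------------------------------------------------
# ontology + annotations
# ---------------------------------------------------------------------------

def simulate_ontology(
    n_terms: int,
    max_children: int = 3,
    annotation_density: float = 0.15,
    gene_ids=(),
    seed: int = 0,
) -> tuple[OntologyGraph, dict[str, frozenset[str]]]:
    """Random single-root is_a DAG plus ancestor-closed gene annotations.

    Every non-root term gets one tree parent (respecting
    ``max_children`` per node) and, occasionally, a second parent so the
    graph is a genuine DAG rather than a tree. Each gene is directly
    annotated to each term with probability ``annotation_density``
    (at least one term per gene), then closed under ancestors.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = _rng(seed, stage=1)
    terms = [f"T:{i:07d}" for i in range(n_terms)]
    g = nx.DiGraph()
    g.add_node(terms[0])
    n_children = {terms[0]: 0}
    for i in range(1, n_terms):
        open_slots = [t for t in terms[:i] if n_children[t] < max_children]
        parent = open_slots[rng.integers(len(open_slots))] if open_slots else terms[
            rng.integers(i)
        ]
        g.add_edge(terms[i], parent)
        n_children[parent] = n_children.get(parent, 0) + 1
        n_children[terms[i]] = 0
        # second parent with low probability, only among earlier terms
        if i >= 2 and rng.random() < 0.15:
            extra = terms[rng.integers(i)]
            if extra != parent:
                g.add_edge(terms[i], extra)
    names = {t: f"synthetic term {idx}" for idx, t in enumerate(terms)}
    graph = OntologyGraph(g, names)

    annot: dict[str, set[str]] = {}
    for gene in gene_ids:
        hits = [t for t in terms[1:] if rng.random() < annotation_density]
        if not hits:
            hits = [terms[1 + rng.integers(n_terms - 1)]]
        annot[str(gene)] = set(hits)
    return graph, propagate_annotations(annot, graph)


def simulate_bgc_membership(
    gene_ids, n_clusters: int = 5, genes_per_cluster: tuple[int, int] = (3, 19),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Disjoint random gene clusters standing in for BGC membership."""
    rng = _rng(seed, stage=2)
    pool = list(gene_ids)
    rng.shuffle(pool)
    out: dict[str, list[str]] = {}
    cursor = 0
    for i in range(n_clusters):
        size = int(rng.integers(genes_per_cluster[0], genes_per_cluster[1] + 1))
        members = pool[cursor:cursor + size]
        if not members:
            break
        out[f"cluster{i + 1:02d}"] = members
        cursor += size
    return out


# ---------------------------------------------------------------------------
# spatial grid
# ---------------------------------------------------------------------------

def simulate_grid(
    n_rows: int = 4,
    n_cols: int = 9,
    analytes: tuple[str, ...] = ("orsellinic_acid", "lecanoric_acid"),
    pigment_analyte: str | None = None,
    gradient_direction: str = "columns",
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpatialGrid:
    """Block lattice with monotone analyte gradients plus Gaussian noise.

    The default 4 x 9 lattice matches the study's 36-block excision
    grid. Each analyte increases monotonically along
    ``gradient_direction`` ("columns" = toward the inducing colony, or
    "rows") with additive noise. The 400 nm absorbance channel is a
    monotone (concave saturating) map of the TRUE pigment-analyte
    gradient plus its own noise, so at ``noise_sd = 0`` pigment and
    absorbance are perfectly rank-correlated while large noise
    attenuates the association.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    if gradient_direction not in ("columns", "rows"):
        raise ValueError("gradient_direction must be 'columns' or 'rows'")
    pigment = pigment_analyte or analytes[0]
    if pigment not in analytes:
        raise ValueError("pigment analyte must be among the analytes")
    rng = _rng(seed, stage=3)

    rows = np.repeat(np.arange(1, n_rows + 1), n_cols)
    cols = np.tile(np.arange(1, n_cols + 1), n_rows)
    axis = cols if gradient_direction == "columns" else rows
    axis_max = n_cols if gradient_direction == "columns" else n_rows
    base = axis / axis_max  # in (0, 1]

    records = []
    pigment_gradient = None
    for analyte in analytes:
        scale = rng.uniform(5.0, 15.0)
        gradient = scale * base
        values = np.clip(gradient + rng.normal(0.0, noise_sd, size=gradient.size), 0, None)
        if analyte == pigment:
            pigment_gradient = gradient
        records.append(pd.DataFrame(
            {"row": rows, "col": cols, "analyte": analyte, "value": values}
        ))
    # saturating monotone response of absorbance to the pigment gradient
    absorb = 2.0 * pigment_gradient / (pigment_gradient.max() + pigment_gradient)
    absorb = np.clip(absorb + rng.normal(0.0, 0.1 * noise_sd, size=absorb.size), 0, None)
    records.append(pd.DataFrame(
        {"row": rows, "col": cols, "analyte": ABSORBANCE, "value": absorb}
    ))
    return SpatialGrid(pd.concat(records, ignore_index=True))
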