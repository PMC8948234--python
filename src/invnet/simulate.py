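"""Seeded synthetic multi-omics cohorts and regulatory-DAG datasets.

The cohort generator emulates the statistical structure the pipeline
assumes in real early-stage lung adenocarcinoma data: two expression
classes with planted up-/down-regulated signature genes, a latent
proliferation factor loading on a confounded gene block (orthogonal to
class), cis copy-number and promoter-methylation drivers of expression,
class-skewed histology and nodal-stage annotations, and exponential
survival with a class-dependent hazard under administrative censoring.

The DAG generator emits discretized multinomial data from a known random
DAG (optionally with cis root anchors) for the network-recovery tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import OmicsDataset
from .network import DiscreteMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CohortParams",
    "SyntheticTruth",
    "generate_cohort",
    "generate_dag_data",
]

#: Class-conditional histology probabilities over the seven subtypes.
#: Invasive tumors concentrate in the aggressive subtypes (AC/PAP/MP/SOL),
#: non-invasive tumors in the lepidic-type subtypes (AIS/MIA/LPA).
HISTOLOGY_PROBS = {
    1: {"AC": 0.35, "PAP": 0.20, "MP": 0.15, "SOL": 0.12,
        "LPA": 0.08, "MIA": 0.06, "AIS": 0.04},
    0: {"AIS": 0.30, "MIA": 0.28, "LPA": 0.28,
        "AC": 0.06, "PAP": 0.04, "MP": 0.02, "SOL": 0.02},
}


@dataclass
class CohortParams:
    """Generative settings for a two-class synthetic cohort.

    Defaults mirror the scale at which the pipeline is exercised: a
    53-sample-like two-class cohort (25 + 25), 500 genes with 60 planted
    signature genes (half up, half down in the invasive class) at a log2
    effect of 1.5, per-gene biological noise around sd 0.8 (so variable
    genes clear the variance > 1 selection filter), a 30-gene proliferation
    block loading 0.8 on a latent factor independent of class, cis-CNV /
    cis-methylation effects with slope 0.8 on a quarter / tenth of genes,
    a true survival log hazard ratio of 1.0 for the invasive class, and
    ~20% random censoring.
    """

    n_invasive: int = 25
    n_indolent: int = 25
    n_genes: int = 500
    n_signature: int = 60  # split evenly up/down
    effect_log2: float = 1.5
    noise_sd: float = 0.5  # extra white noise on top of per-gene sd
    gene_sd_range: tuple[float, float] = (0.6, 1.1)
    baseline_range: tuple[float, float] = (2.0, 9.0)
    n_proliferation: int = 30
    proliferation_loading: float = 0.8
    cis_cnv_fraction: float = 0.25
    cis_methyl_fraction: float = 0.10
    cis_slope: float = 0.8
    nodal_positive_rate: tuple[float, float] = (0.03, 0.45)  # (indolent, invasive)
    survival_log_hr: float = 1.0
    baseline_hazard: float = 0.02  # events per month for the indolent class
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_invasive, self.n_indolent, self.n_genes) <= 0:
            raise ValueError("sample and gene counts must be positive")
        if self.n_signature > self.n_genes:
            raise ValueError("n_signature exceeds n_genes")
        if self.n_signature + self.n_proliferation > self.n_genes:
            raise ValueError("signature + proliferation blocks exceed n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth planted by a generator, for recovery tests."""

    class_labels: pd.Series | None = None  # 1 = invasive
    signature_up: list[str] = field(default_factory=list)
    signature_down: list[str] = field(default_factory=list)
    proliferation_genes: list[str] = field(default_factory=list)
    cis_cnv_genes: list[str] = field(default_factory=list)
    cis_methyl_genes: list[str] = field(default_factory=list)
    survival_log_hr: float | None = None
    dag: nx.DiGraph | None = None
    cis_nodes: dict[str, str] = field(default_factory=dict)

    @property
    def signature_genes(self) -> list[str]:
        return self.signature_up + self.signature_down


def generate_cohort(params: CohortParams | None = None,
                    **overrides) -> tuple[OmicsDataset, SyntheticTruth]:
    """Generate a seeded synthetic multi-omics cohort with known truth."""
    if params is None:
        params = CohortParams(**overrides)
    elif overrides:
        raise ValueError("pass either params or keyword overrides, not both")
    p = params
    rng = np.random.default_rng(p.seed)

    n = p.n_invasive + p.n_indolent
    samples = [f"S{i:03d}" for i in range(n)]
    genes = [f"G{i:04d}" for i in range(p.n_genes)]
    labels = np.array([1] * p.n_invasive + [0] * p.n_indolent)

    n_up = p.n_signature // 2
    sig_up = genes[:n_up]
    sig_down = genes[n_up:p.n_signature]
    prolif = genes[p.n_signature:p.n_signature + p.n_proliferation]

    baseline = rng.uniform(*p.baseline_range, size=p.n_genes)
    gene_sd = rng.uniform(*p.gene_sd_range, size=p.n_genes)
    expr = (baseline[:, None]
            + gene_sd[:, None] * rng.standard_normal((p.n_genes, n))
            + p.noise_sd * rng.standard_normal((p.n_genes, n)))

    half = p.effect_log2 / 2.0
    idx = {g: i for i, g in enumerate(genes)}
    for g in sig_up:
        expr[idx[g]] += np.where(labels == 1, half, -half)
    for g in sig_down:
        expr[idx[g]] += np.where(labels == 1, -half, half)

    # latent proliferation factor, independent of class
    prolif_factor = rng.standard_normal(n)
    for g in prolif:
        expr[idx[g]] += p.proliferation_loading * prolif_factor

    # cis features: values drawn per sample; flagged genes get a slope into
    # expression
    n_cis_cnv = int(round(p.cis_cnv_fraction * p.n_genes))
    n_cis_meth = int(round(p.cis_methyl_fraction * p.n_genes))
    cis_cnv_genes = list(rng.choice(genes, size=n_cis_cnv, replace=False))
    remaining = [g for g in genes if g not in set(cis_cnv_genes)]
    cis_meth_genes = list(rng.choice(remaining, size=min(n_cis_meth,
                                                         len(remaining)),
                                     replace=False))
    cnv = 0.5 * rng.standard_normal((p.n_genes, n))  # segment-mean-like
    methyl = np.clip(rng.normal(0.5, 0.15, size=(p.n_genes, n)), 0, 1)
    for g in cis_cnv_genes:
        expr[idx[g]] += p.cis_slope * cnv[idx[g]]
    for g in cis_meth_genes:
        expr[idx[g]] -= p.cis_slope * (methyl[idx[g]] - 0.5) / 0.15

    # annotations
    hist = np.empty(n, dtype=object)
    for cls in (0, 1):
        probs = HISTOLOGY_PROBS[cls]
        cats = list(probs)
        mask = labels == cls
        hist[mask] = rng.choice(cats, size=int(mask.sum()),
                                p=[probs[c] for c in cats])
    nodal_p = np.where(labels == 1, p.nodal_positive_rate[1],
                       p.nodal_positive_rate[0])
    nodal = np.where(rng.random(n) < nodal_p, "N1", "N0")

    hazard = p.baseline_hazard * np.exp(p.survival_log_hr * labels)
    event_time = rng.exponential(1.0 / hazard)
    cens_scale = np.quantile(event_time, 1 - p.censoring_rate) \
        if p.censoring_rate > 0 else np.inf
    cens_time = rng.uniform(0, 2 * cens_scale, size=n) \
        if np.isfinite(cens_scale) else np.full(n, np.inf)
    time = np.minimum(event_time, cens_time)
    event = (event_time <= cens_time).astype(int)
    time = np.maximum(time, 0.01)

    ann = pd.DataFrame({
        "histology": hist,
        "nodal_stage": nodal,
        "time": time,
        "event": event,
        "age": rng.normal(67, 9, size=n).round(1),
        "sex": rng.choice(["F", "M"], size=n, p=[0.62, 0.38]),
        "stage": rng.choice(["I", "II"], size=n, p=[0.8, 0.2]),
    }, index=pd.Index(samples, name="sample"))

    dataset = OmicsDataset(
        expression=pd.DataFrame(expr, index=pd.Index(genes, name="gene"),
                                columns=samples),
        annotations=ann,
        cnv=pd.DataFrame(cnv, index=pd.Index(genes, name="gene"),
                         columns=samples),
        methylation=pd.DataFrame(methyl, index=pd.Index(genes, name="gene"),
                                 columns=samples),
    )
    truth = SyntheticTruth(
        class_labels=pd.Series(labels, index=samples, name="invasive"),
        signature_up=sig_up, signature_down=sig_down,
        proliferation_genes=prolif,
        cis_cnv_genes=cis_cnv_genes, cis_methyl_genes=cis_meth_genes,
        survival_log_hr=p.survival_log_hr,
    )
    return dataset, truth


def generate_dag_data(n_nodes: int, n_samples: int,
                      cis_fraction: float = 0.0, edge_prob: float = 0.3,
                      seed: int = 0, strength: float = 0.85,
                      n_states: int = 3,
                      dag: nx.DiGraph | None = None
                      ) -> tuple[DiscreteMatrix, dict, SyntheticTruth]:
    """Sample discretized multinomial data from a (random or given) DAG.

    Nodes are added in a random topological order and each ordered pair is
    an edge with probability ``edge_prob``. Root nodes draw states from a
    random categorical; a child copies a deterministic summary of its
    parents' states (the rounded mean) with probability ``strength`` and is
    uniform otherwise. A ``cis_fraction`` of nodes receive a parentless cis
    anchor variable that influences their state the same way.

    Returns the discrete matrix, a dict of cis-node state vectors keyed
    ``"cnv:<node>"``, and the ground truth (DAG + cis map).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    nodes = [f"V{i:02d}" for i in range(n_nodes)]

    if dag is None:
        order = list(rng.permutation(n_nodes))
        dag = nx.DiGraph()
        dag.add_nodes_from(nodes)
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < edge_prob:
                    dag.add_edge(nodes[order[i]], nodes[order[j]])
    assert nx.is_directed_acyclic_graph(dag)

    n_cis = int(round(cis_fraction * n_nodes))
    cis_targets = list(rng.choice(nodes, size=n_cis, replace=False)) \
        if n_cis else []
    cis_states: dict[str, np.ndarray] = {}
    cis_nodes = {}
    for v in cis_targets:
        cis_states[f"cnv:{v}"] = rng.integers(0, n_states, size=n_samples)
        cis_nodes[v] = f"cnv:{v}"

    states = {v: np.zeros(n_samples, dtype=np.int64) for v in nodes}
    for v in nx.topological_sort(dag):
        parents = sorted(dag.predecessors(v))
        influences = [states[u] for u in parents]
        if v in cis_nodes:
            influences.append(cis_states[cis_nodes[v]])
        if influences:
            det = np.rint(np.mean(influences, axis=0)).astype(np.int64)
            noise = rng.integers(0, n_states, size=n_samples)
            use_det = rng.random(n_samples) < strength
            states[v] = np.where(use_det, det, noise)
        else:
            base = rng.dirichlet(np.full(n_states, 2.0))
            states[v] = rng.choice(n_states, size=n_samples, p=base)

    samples = [f"S{i:03d}" for i in range(n_samples)]
    df = pd.DataFrame({v: states[v] for v in nodes}, index=samples).T
    df.columns = samples
    disc = DiscreteMatrix(states=df.astype(np.int8),
                          cutpoints={v: np.array([0.5, 1.5]) for v in nodes},
                          n_states={v: n_states for v in nodes})
    truth = SyntheticTruth(dag=dag, cis_nodes=cis_nodes)
    return disc, cis_states, truth
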