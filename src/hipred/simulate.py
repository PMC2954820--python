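"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the pipeline's inputs:

* a toy genome with multi-transcript gene models plus deletions engineered
  to satisfy exactly one named LOF criterion each (verified against the
  caller at construction time, so the truth table is exact);
* two-class multivariate-Gaussian feature vectors with shared covariance —
  the generative twin of the discriminant model — calibrated so the
  analytically optimal AUC, Phi(Delta/sqrt(2)) for Mahalanobis separation
  Delta, takes a requested value;
* a weighted random network with planted extra seed-adjacent edges for
  class-1 genes.

Each generator draws from its own RNG stream derived from the master seed
by a fixed sub-stream index, so adding a generator never perturbs existing
fixtures; identical configs produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .intervals import CNVCall, GenomeInterval, GeneModelSet, Transcript
from .lof import CRITERIA, transcript_lof


class SimulationSpecError(ValueError):
    """An infeasible planting request (e.g. a criterion the transcript's
    geometry cannot realise without an earlier criterion firing first)."""


@dataclass
class SimulationConfig:
    """Study conditions for all three generators. ``seed`` is mandatory.

    Genome/CNV: ``n_genes`` toy genes on one chromosome among
    ``n_individuals`` samples; ``n_recurrent`` genes receive gene-level LOF
    in >= 2 distinct individuals (the HS catalog truth), ``n_singleton`` in
    exactly one; ``criterion_mix`` cycles over the planted criteria;
    ``n_benign`` genes receive non-LOF deletions.

    Features: two Gaussian classes with shared covariance, class sizes
    defaulting to the real training set (234 HI vs 326 HS), separation
    calibrated so the optimal AUC is 0.81 (the model's real-data operating
    point), optional MCAR missingness.

    Network: ``network_nodes`` genes, ``network_edges`` background links
    with Gamma-distributed log-likelihood weights, ``n_seeds`` seed genes,
    and ``planted_excess`` extra seed edges per class-1 gene.
    """

    seed: int
    # genome / CNVs
    n_genes: int = 200
    n_individuals: int = 50
    n_recurrent: int = 60
    n_singleton: int = 30
    n_benign: int = 40
    criterion_mix: tuple[str, ...] = CRITERIA
    # feature classes
    n_hi: int = 234
    n_hs: int = 326
    n_features: int = 4
    optimal_auc: float = 0.81
    covariance: np.ndarray | None = None
    missingness_rate: float = 0.0
    # network
    network_nodes: int = 500
    network_edges: int = 2000
    n_seeds: int = 40
    n_class1: int = 50
    planted_excess: int = 4
    weight_shape: float = 2.0
    weight_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.missingness_rate <= 1.0:
            raise ValueError("missingness_rate must be in [0, 1]")
        if self.covariance is not None:
            cov = np.asarray(self.covariance, dtype=float)
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("covariance must be positive-definite")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ------------------------------------------------------------ toy gene models

# fixed per-gene layout (offsets from the gene origin); 3 exons, CDS split
# over two of them with the 5'-most exon untranslated, so every criterion
# is plantable on the full-length transcript
_EXONS = ((0, 60), (160, 280), (380, 470))
_CDS_PLUS = ((170, 280), (380, 426))    # 156 bp, starts in exon 2
_CDS_MINUS = ((14, 60), (160, 270))     # 156 bp, 5' end in exon 2 (minus)
GENE_SPACING = 2000
GENE_ORIGIN = 1000


def make_toy_gene(
    gene_id: str, origin: int, strand: str, n_transcripts: int = 1,
    chrom: str = "chr1",
) -> list[Transcript]:
    """Build 1-2 transcripts of a toy gene at ``origin``.

    The second transcript drops the 5'-untranslated exon, so its first
    exon contains the start codon (a geometry on which a pure first-exon
    deletion cannot be planted).
    """
    exons = [
        GenomeInterval(chrom, origin + a, origin + b, strand) for a, b in _EXONS
    ]
    cds_spec = _CDS_PLUS if strand == "+" else _CDS_MINUS
    cds = [GenomeInterval(chrom, origin + a, origin + b, strand) for a, b in cds_spec]
    txs = [
        Transcript(
            id=f"{gene_id}.t1",
            gene_id=gene_id,
            interval=GenomeInterval(chrom, exons[0].start, exons[-1].end, strand),
            exons=exons,
            cds=cds,
        )
    ]
    if n_transcripts >= 2:
        sub = exons[1:] if strand == "+" else exons[:-1]
        txs.append(
            Transcript(
                id=f"{gene_id}.t2",
                gene_id=gene_id,
                interval=GenomeInterval(chrom, sub[0].start, sub[-1].end, strand),
                exons=list(sub),
                cds=list(cds),
            )
        )
    return txs


def plant_deletion(transcript: Transcript, criterion: str) -> GenomeInterval:
    """Construct a deletion whose *reported* LOF criterion is ``criterion``.

    The candidate is built from the transcript's own geometry and verified
    against the caller; an infeasible request (the ordered rules report
    something else) raises :class:`SimulationSpecError` naming the
    conflict. ``criterion`` may also be "none" for a benign deletion.
    """
    chrom = transcript.chrom
    if criterion == "over_half_cds":
        cand = GenomeInterval(
            chrom, min(c.start for c in transcript.cds),
            max(c.end for c in transcript.cds),
        )
    elif criterion == "start_codon":
        pos = transcript.start_codon_positions()
        cand = GenomeInterval(chrom, min(pos), max(pos) + 1)
    elif criterion == "first_exon":
        fe = transcript.first_exon
        cand = GenomeInterval(chrom, max(fe.start - 2, 0), fe.end + 2)
    elif criterion == "splice_signal":
        introns = transcript.introns()
        if not introns:
            raise SimulationSpecError(
                f"{transcript.id}: no intron to plant a splice-signal deletion"
            )
        i = introns[0]
        cand = GenomeInterval(chrom, i.start, min(i.start + 2, i.end))
    elif criterion == "frameshift":
        seg = max(transcript.cds, key=len)
        if len(seg) < 20:
            raise SimulationSpecError(
                f"{transcript.id}: CDS segment too short for an interior "
                "frameshift deletion"
            )
        mid = (seg.start + seg.end) // 2
        cand = GenomeInterval(chrom, mid - 3, mid + 4)  # 7 bp, 7 % 3 != 0
    elif criterion == "none":
        introns = transcript.introns()
        feasible = [i for i in introns if len(i) >= 20]
        if not feasible:
            raise SimulationSpecError(
                f"{transcript.id}: no intron interior for a benign deletion"
            )
        i = feasible[0]
        cand = GenomeInterval(chrom, i.start + 8, i.start + 16)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    call = transcript_lof(transcript, cand)
    if call.criterion != criterion:
        raise SimulationSpecError(
            f"{transcript.id}: requested {criterion!r} but the ordered rules "
            f"report {call.criterion!r} for the constructed deletion"
        )
    return cand


def simulate_genome_and_cnvs(
    config: SimulationConfig,
) -> tuple[GeneModelSet, list[CNVCall], pd.DataFrame]:
    """Toy genome, engineered deletions and the planting truth table.

    The truth table has one row per planted deletion: gene_id,
    transcript_id, sample_id, criterion, gene_lof (whether the deletion
    set of that sample renders the whole gene LOF). Genes are assigned
    roles in order: recurrent (LOF in 2 individuals), singleton (1), benign
    (non-LOF deletions only), untouched.
    """
    if config.n_recurrent + config.n_singleton + config.n_benign > config.n_genes:
        raise SimulationSpecError("gene roles exceed n_genes")
    rng = config.rng(0)
    samples = [f"S{i:04d}" for i in range(config.n_individuals)]
    if config.n_individuals < 2:
        raise SimulationSpecError("need >= 2 individuals for recurrent planting")

    models = GeneModelSet()
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    for i, gid in enumerate(gene_ids):
        origin = GENE_ORIGIN + i * GENE_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = 1 + int(rng.random() < 0.5)
        for tx in make_toy_gene(gid, origin, strand, n_tx):
            models.add(tx)

    cnvs: list[CNVCall] = []
    rows = []
    mix = list(config.criterion_mix)
    mix_i = 0

    def lof_sample(gid: str, sample: str) -> None:
        nonlocal mix_i
        coding = models.coding_transcripts(gid)
        for k, tx in enumerate(coding):
            if k == 0:
                crit = mix[mix_i % len(mix)]
                mix_i += 1
                try:
                    d = plant_deletion(tx, crit)
                except SimulationSpecError:
                    crit = "frameshift"
                    d = plant_deletion(tx, crit)
            else:
                # secondary transcripts: a criterion feasible on any geometry
                crit = "frameshift"
                d = plant_deletion(tx, crit)
            cnvs.append(CNVCall(sample_id=sample, interval=d))
            rows.append(
                {"gene_id": gid, "transcript_id": tx.id, "sample_id": sample,
                 "criterion": crit, "gene_lof": True}
            )

    idx = 0
    for gid in gene_ids[idx : idx + config.n_recurrent]:
        for sample in rng.choice(samples, size=2, replace=False):
            lof_sample(gid, str(sample))
    idx += config.n_recurrent
    for gid in gene_ids[idx : idx + config.n_singleton]:
        lof_sample(gid, str(rng.choice(samples)))
    idx += config.n_singleton
    for gid in gene_ids[idx : idx + config.n_benign]:
        tx = models.coding_transcripts(gid)[0]
        d = plant_deletion(tx, "none")
        sample = str(rng.choice(samples))
        cnvs.append(CNVCall(sample_id=sample, interval=d))
        rows.append(
            {"gene_id": gid, "transcript_id": tx.id, "sample_id": sample,
             "criterion": "none", "gene_lof": False}
        )

    truth = pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "sample_id", "criterion",
                       "gene_lof"],
    )
    return models, cnvs, truth


def truth_hs_genes(truth: pd.DataFrame, min_individuals: int = 2) -> set[str]:
    """Genes planted as gene-level LOF in >= ``min_individuals`` samples."""
    lof = truth[truth["gene_lof"]]
    counts = lof.groupby("gene_id")["sample_id"].nunique()
    return set(counts[counts >= min_individuals].index)


# ----------------------------------------------------------- feature classes

def mahalanobis_for_auc(optimal_auc: float) -> float:
    """Invert Phi(Delta/sqrt(2)) = AUC for the class separation Delta."""
    if not 0.5 <= optimal_auc < 1.0:
        raise ValueError("optimal AUC must be in [0.5, 1)")
    return math.sqrt(2.0) * stats.norm.ppf(optimal_auc)


def simulate_feature_classes(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Two-class Gaussian feature table, labels, and the analytic optimum.

    Class-conditional draws share one covariance; the mean difference lies
    along the all-ones direction scaled so the Mahalanobis separation
    Delta satisfies Phi(Delta/sqrt(2)) = ``config.optimal_auc``. The info
    dict records the class means, covariance, the analytic discriminant
    Sigma^-1 delta and the optimal AUC; optional MCAR missingness is
    applied after the draw.
    """
    rng = config.rng(1)
    p = config.n_features
    cov = (
        np.asarray(config.covariance, dtype=float)
        if config.covariance is not None
        else np.eye(p)
    )
    delta_target = mahalanobis_for_auc(config.optimal_auc)
    direction = np.ones(p)
    raw = math.sqrt(direction @ np.linalg.solve(cov, direction))
    delta_vec = direction * (delta_target / raw)

    mu_hs = np.zeros(p)
    mu_hi = delta_vec
    x_hi = rng.multivariate_normal(mu_hi, cov, size=config.n_hi)
    x_hs = rng.multivariate_normal(mu_hs, cov, size=config.n_hs)
    x = np.vstack([x_hi, x_hs])
    y = np.concatenate([np.ones(config.n_hi, int), np.zeros(config.n_hs, int)])

    if config.missingness_rate > 0:
        mask = rng.random(x.shape) < config.missingness_rate
        x = np.where(mask, np.nan, x)

    names = [f"feature_{i}" for i in range(p)]
    gene_ids = [f"G{i:05d}" for i in range(len(y))]
    features = pd.DataFrame(x, columns=names, index=pd.Index(gene_ids, name="gene_id"))
    labels = pd.Series(y, index=features.index, name="is_hi")
    info = {
        "mean_hi": mu_hi,
        "mean_hs": mu_hs,
        "covariance": cov,
        "mahalanobis": delta_target,
        "optimal_discriminant": np.linalg.solve(cov, delta_vec),
        "optimal_auc": float(stats.norm.cdf(delta_target / math.sqrt(2.0))),
    }
    return features, labels, info


# ----------------------------------------------------------------- networks

def simulate_network(
    config: SimulationConfig,
) -> tuple[nx.Graph, list[str], pd.DataFrame]:
    """Weighted background graph with planted seed-adjacency for class 1.

    Nodes are genes N00000...; the first ``n_seeds`` are the seed set, the
    next ``n_class1`` the class-1 genes receiving ``planted_excess`` extra
    seed edges each; an equal-sized slice of untouched genes serves as
    class 0. Edge weights are Gamma(shape, scale) draws. The truth table
    records class and the planted expected seed-weight excess.
    """
    rng = config.rng(2)
    n = config.network_nodes
    nodes = [f"N{i:05d}" for i in range(n)]
    seeds = nodes[: config.n_seeds]
    class1 = nodes[config.n_seeds : config.n_seeds + config.n_class1]
    class0 = nodes[
        config.n_seeds + config.n_class1 : config.n_seeds + 2 * config.n_class1
    ]

    g = nx.Graph()
    g.add_nodes_from(nodes)
    n_bg = 0
    while n_bg < config.network_edges:
        i, j = rng.integers(n, size=2)
        if i == j or g.has_edge(nodes[i], nodes[j]):
            continue
        w = rng.gamma(config.weight_shape, config.weight_scale)
        g.add_edge(nodes[i], nodes[j], weight=float(w))
        n_bg += 1

    mean_w = config.weight_shape * config.weight_scale
    for gene in class1:
        targets = rng.choice(config.n_seeds, size=config.planted_excess, replace=False)
        for t in targets:
            w = rng.gamma(config.weight_shape, config.weight_scale)
            if g.has_edge(gene, seeds[t]):
                g[gene][seeds[t]]["weight"] += float(w)
            else:
                g.add_edge(gene, seeds[t], weight=float(w))

    truth = pd.DataFrame(
        {
            "gene_id": class1 + class0,
            "label": [1] * len(class1) + [0] * len(class0),
            "planted_excess_weight": [config.planted_excess * mean_w] * len(class1)
            + [0.0] * len(class0),
        }
    ).set_index("gene_id")
    return g, seeds, truth


# ------------------------------------------------------- control distribution

def simulate_control_lods(
    config: SimulationConfig, n_controls: int = 500,
    loc: float = -0.4, scale: float = 0.8,
) -> pd.Series:
    """Per-individual maximal LOD values for a synthetic control cohort.

    Gumbel-distributed (a maximum of many deletion scores), located near
    the real control medians (about -0.4 at the 50th percentile).
    """
    rng = config.rng(3)
    vals = rng.gumbel(loc=loc, scale=scale, size=n_controls)
    return pd.Series(np.sort(vals), name="max_lod")
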