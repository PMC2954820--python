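"""Deletion-level haploinsufficiency LOD scores.

A deletion covering genes with haploinsufficiency probabilities p_i is
scored by the log10 odds that at least one covered gene is
haploinsufficient versus none, assuming no statistical interaction between
genes:

    q = prod_i (1 - p_i),   LOD = log10((1 - q) / q)

Probabilities are clamped into [eps, 1-eps] (default eps = 1e-6) so genes
with saturated p(HI) cannot produce infinite scores. A patient deletion is
judged against the empirical distribution of per-individual *maximal* LOD
scores in healthy controls: the empirical pathogenicity probability is the
fraction of controls whose maximal LOD is at least the query LOD.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import CNVCall, GenomeInterval, GeneModelSet
from .lof import transcript_lof

DEFAULT_CLAMP_EPS = 1e-6


@dataclass
class LODResult:
    interval: GenomeInterval | None
    gene_ids: list[str]
    n_genes_scored: int
    n_genes_skipped_missing_phi: int
    lod: float | None  # None when no gene could be scored


def lod_score(p_list, clamp_eps: float = DEFAULT_CLAMP_EPS) -> float:
    """LOD = log10((1-q)/q) with q = prod(1-p_i) after clamping each p.

    An empty probability list has no defined score and raises; callers that
    tolerate unscorable deletions use :func:`score_deletion`.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size == 0:
        raise ValueError("lod_score of an empty gene set is undefined")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    p = np.clip(p, clamp_eps, 1.0 - clamp_eps)
    log_q = np.log10(1.0 - p).sum()
    q = 10.0 ** log_q
    return float(np.log10(1.0 - q) - log_q)


def deletion_genes(
    deletion: GenomeInterval,
    gene_models: GeneModelSet,
    mode: str = "lof",
) -> list[str]:
    """Genes a deletion contributes to its score.

    ``lof`` mode (default): genes whose every coding transcript is rendered
    LOF by this single deletion. ``overlap`` mode: any gene with an
    overlapped transcript.
    """
    out = []
    for gid, txs in gene_models.genes.items():
        if mode == "overlap":
            if any(deletion.overlaps(t.interval) for t in txs):
                out.append(gid)
            continue
        coding = [t for t in txs if t.is_coding]
        if not coding:
            continue
        if all(transcript_lof(t, deletion).is_lof for t in coding):
            out.append(gid)
    return out


def score_deletion(
    deletion: GenomeInterval,
    phi: pd.Series,
    gene_models: GeneModelSet,
    mode: str = "lof",
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> LODResult:
    """Score one deletion; genes without p(HI) are skipped and counted."""
    genes = deletion_genes(deletion, gene_models, mode=mode)
    scored = [g for g in genes if g in phi.index and not math.isnan(phi[g])]
    skipped = len(genes) - len(scored)
    if not scored:
        return LODResult(deletion, genes, 0, skipped, None)
    lod = lod_score(phi[scored].values, clamp_eps=clamp_eps)
    return LODResult(deletion, genes, len(scored), skipped, lod)


def max_lod_per_individual(
    cnvs: list[CNVCall],
    phi: pd.Series,
    gene_models: GeneModelSet,
    mode: str = "lof",
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> tuple[pd.Series, int]:
    """Per-sample maximum deletion LOD.

    Returns (series sample_id -> maximal LOD, number of samples excluded
    because none of their deletions could be scored).
    """
    by_sample: dict[str, list[GenomeInterval]] = defaultdict(list)
    for c in cnvs:
        by_sample[c.sample_id].append(c.interval)
    maxima = {}
    n_excluded = 0
    for sample, dels in by_sample.items():
        lods = [
            r.lod
            for r in (score_deletion(d, phi, gene_models, mode, clamp_eps) for d in dels)
            if r.lod is not None
        ]
        if lods:
            maxima[sample] = max(lods)
        else:
            n_excluded += 1
    return pd.Series(maxima, dtype=float).sort_index(), n_excluded


def genome_burden_lod(
    deletions: list[GenomeInterval],
    phi: pd.Series,
    gene_models: GeneModelSet,
    mode: str = "lof",
    clamp_eps: float = DEFAULT_CLAMP_EPS,
) -> LODResult:
    """Genome-wide haploinsufficiency burden: pooled unique LOF genes.

    A gene hit by several deletions of the genome contributes once.
    """
    genes: set[str] = set()
    for d in deletions:
        genes.update(deletion_genes(d, gene_models, mode=mode))
    genes = sorted(genes)
    scored = [g for g in genes if g in phi.index and not math.isnan(phi[g])]
    skipped = len(genes) - len(scored)
    if not scored:
        return LODResult(None, list(genes), 0, skipped, None)
    lod = lod_score(phi[scored].values, clamp_eps=clamp_eps)
    return LODResult(None, list(genes), len(scored), skipped, lod)


# ----------------------------------------------------------- empirical lookup

class ControlDistribution:
    """Empirical null of per-individual maximal LOD scores in controls.

    Built either from raw per-individual values or from a percentile table
    (percentile -> LOD); in table mode the survival fraction is linearly
    interpolated between tabulated percentiles and clamped to the table's
    resolution.
    """

    def __init__(
        self,
        values: pd.Series | None = None,
        percentiles: dict[float, float] | None = None,
        population: str = "",
    ) -> None:
        if (values is None) == (percentiles is None):
            raise ValueError("provide exactly one of values or percentiles")
        self.population = population
        if values is not None:
            v = np.sort(np.asarray(values, dtype=float))
            if v.size == 0:
                raise ValueError("control distribution must be non-empty")
            self.values: np.ndarray | None = v
            self.percentile_lods = None
            self.percentile_levels = None
        else:
            items = sorted(percentiles.items())
            levels = np.array([k for k, _ in items], dtype=float)
            lods = np.array([v for _, v in items], dtype=float)
            if (np.diff(lods) < 0).any():
                raise ValueError("percentile table must be non-decreasing")
            self.values = None
            self.percentile_levels = levels
            self.percentile_lods = lods

    @classmethod
    def from_percentile_row(cls, row: pd.Series, population: str = "") -> "ControlDistribution":
        pct = {
            float(c[1:]): float(row[c])
            for c in row.index
            if isinstance(c, str) and c.startswith("p") and c[1:].isdigit()
        }
        return cls(percentiles=pct, population=population or str(row.get("population", "")))

    def empirical_p(self, lod: float) -> float:
        """Fraction of controls with maximal LOD >= ``lod``."""
        if self.values is not None:
            return float((self.values >= lod).mean())
        # survival from interpolated percentile level, clamped to the table
        level = np.interp(lod, self.percentile_lods, self.percentile_levels)
        return float(np.clip(1.0 - level / 100.0, 0.0, 1.0))

    @property
    def resolution(self) -> float:
        """Smallest non-zero probability the distribution can resolve."""
        if self.values is not None:
            return 1.0 / self.values.size
        return 1.0 - self.percentile_levels.max() / 100.0


def empirical_p(lod: float, control: ControlDistribution) -> float:
    return control.empirical_p(lod)


# ------------------------------------------------------------- ROC comparison

def roc_compare(
    case_metrics: pd.DataFrame,
    control_metrics: pd.DataFrame,
    metrics: tuple[str, ...] = ("lod", "length_bp", "n_genes"),
) -> pd.DataFrame:
    """Compare pathogenicity metrics by ROC AUC, cases vs controls.

    ``case_metrics`` has one row per pathogenic deletion; in
    ``control_metrics`` each row is one control individual's most extreme
    deletion under the respective metric (maximum). Returns per-metric AUC.
    """
    from .classifier import auc as _auc

    rows = []
    for m in metrics:
        cases = case_metrics[m].dropna().values
        controls = control_metrics[m].dropna().values
        if cases.size == 0 or controls.size == 0:
            raise ValueError(f"metric {m!r}: both groups must be non-empty")
        scores = np.concatenate([cases, controls])
        labels = np.concatenate([np.ones(cases.size), np.zeros(controls.size)])
        rows.append({"metric": m, "auc": _auc(scores, labels),
                     "n_cases": cases.size, "n_controls": controls.size})
    return pd.DataFrame(rows)
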