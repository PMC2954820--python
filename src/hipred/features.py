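"""Per-gene predictor variables and the HI-vs-HS property comparisons.

The shipped classifier uses four predictors: human-macaque dN/dS, summed
promoter conservation, a binary embryonic-expression flag and proximity to
known-HI seed genes in the functional network. This module computes those
predictors from their raw inputs, the Fig-2-style group comparisons
(Mann-Whitney / Fisher with z-scores against the genome average), and the
constrained feature selection (coverage >= 50%, pairwise |Spearman| < 0.3,
category diversity, then cross-validated AUC).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomeInterval, Transcript

PROMOTER_FLANK = 100  # bp either side of the TSS: [-100, 100) window


def promoter_interval(transcript: Transcript, flank: int = PROMOTER_FLANK) -> GenomeInterval:
    """The promoter window: ``2*flank`` bp centred on the TSS, half-open.

    For "+" transcripts this is [TSS-flank, TSS+flank); for "-" the window
    is reflected about the 5' end so offset -flank is upstream in the
    direction of transcription. Windows running off the chromosome origin
    are clipped at 0 with a warning.
    """
    tss = transcript.tss
    start, end = tss - flank, tss + flank
    if start < 0:
        warnings.warn(
            f"promoter window of {transcript.id} clipped at chromosome start",
            stacklevel=2,
        )
        start = 0
    return GenomeInterval(transcript.chrom, start, end, transcript.strand)


def summed_conservation(
    interval: GenomeInterval, track: pd.DataFrame
) -> float:
    """Sum a per-base conservation score over an interval.

    ``track`` is a chrom/pos/score table (0-based positions); bases absent
    from the track contribute 0.
    """
    sel = track[
        (track["chrom"] == interval.chrom)
        & (track["pos"] >= interval.start)
        & (track["pos"] < interval.end)
    ]
    return float(sel["score"].sum())


def read_conservation_track(path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t", names=["chrom", "pos", "score"],
                        dtype={"chrom": str}, comment="#")
    return track


def summarize_by_gene(per_transcript_values: dict[str, list[float]]) -> pd.Series:
    """Reduce per-transcript values to one per gene using the median."""
    return pd.Series(
        {g: float(np.median(v)) for g, v in per_transcript_values.items()},
        dtype=float,
    )


def tissue_specificity(expression: pd.DataFrame) -> pd.Series:
    """Tissue specificity: per-gene SD of expression across tissues.

    Each gene's total expression is first normalised (row scaled to sum 1)
    so the SD measures the shape of the profile, not its magnitude. SD uses
    the n-1 denominator. Genes with zero total expression are missing.
    """
    if expression.shape[1] < 2:
        raise ValueError("tissue specificity needs >= 2 tissues")
    if (expression.values < 0).any():
        raise ValueError("expression levels must be non-negative")
    totals = expression.sum(axis=1)
    normed = expression.div(totals, axis=0)
    sd = normed.std(axis=1, ddof=1)
    sd[totals == 0] = np.nan
    return sd


def embryonic_flag(
    expression_pairs: list[tuple[float, float]], fold: float = 8.0
) -> int:
    """1 iff the gene is over-expressed >= ``fold`` in any embryonic dataset.

    Each pair is (embryonic_level, reference_level); datasets are combined
    by union. A zero reference with positive embryonic expression counts as
    satisfying the fold; both zero does not.
    """
    for emb, ref in expression_pairs:
        if emb < 0 or ref < 0:
            raise ValueError("expression levels must be >= 0")
        if ref == 0:
            if emb > 0:
                return 1
        elif emb / ref >= fold:
            return 1
    return 0


def zscore_vs_genome(table: pd.DataFrame) -> pd.DataFrame:
    """Transform each numeric column to z-scores against the genome average.

    Missing values stay missing; a constant column has no scale and raises.
    """
    out = table.copy()
    for col in out.columns:
        if not pd.api.types.is_numeric_dtype(out[col]):
            continue
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} is constant; z-score undefined")
        out[col] = (x - x.mean()) / sd
    return out


@dataclass
class PropertyComparison:
    """One Fig-2-style property comparison between HI and HS genes."""

    property_name: str
    test: str  # mann_whitney_two_tailed | fisher_exact
    p_value: float
    z_hi: float
    z_hs: float
    sem_hi: float
    sem_hs: float
    mean_hi: float
    mean_hs: float


def compare_property(
    values_hi,
    values_hs,
    kind: str = "continuous",
    name: str = "",
    values_genome=None,
) -> PropertyComparison:
    """Compare a property between HI and HS genes.

    Continuous properties use the two-tailed Mann-Whitney U test (exact
    null for small untied samples, normal approximation with tie correction
    otherwise); binary properties use a two-sided Fisher's exact test.
    Group means are reported as z-scores relative to the genome average
    (the pooled groups when no genome-wide values are given), with the SEM
    on the same scale; Fig-2-style error bars are 2x SEM.
    """
    hi = np.asarray(values_hi, dtype=float)
    hs = np.asarray(values_hs, dtype=float)
    hi, hs = hi[~np.isnan(hi)], hs[~np.isnan(hs)]
    if hi.size == 0 or hs.size == 0:
        raise ValueError("both groups must be non-empty")

    if kind == "continuous":
        test = "mann_whitney_two_tailed"
        pooled = np.concatenate([hi, hs])
        if np.ptp(pooled) == 0:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(hi, hs, alternative="two-sided", method="auto")
    elif kind == "binary":
        test = "fisher_exact"
        table = [
            [int(hi.sum()), int(hi.size - hi.sum())],
            [int(hs.sum()), int(hs.size - hs.sum())],
        ]
        _, p = stats.fisher_exact(table, alternative="two-sided")
    else:
        raise ValueError(f"unknown comparison kind {kind!r}")

    genome = (
        np.asarray(values_genome, dtype=float)
        if values_genome is not None
        else np.concatenate([hi, hs])
    )
    genome = genome[~np.isnan(genome)]
    g_mean, g_sd = genome.mean(), genome.std(ddof=1)
    if g_sd == 0:
        z_hi = z_hs = 0.0
        sem_hi = sem_hs = 0.0
    else:
        z_hi = (hi.mean() - g_mean) / g_sd
        z_hs = (hs.mean() - g_mean) / g_sd
        sem_hi = hi.std(ddof=1) / g_sd / np.sqrt(hi.size) if hi.size > 1 else 0.0
        sem_hs = hs.std(ddof=1) / g_sd / np.sqrt(hs.size) if hs.size > 1 else 0.0
    return PropertyComparison(
        property_name=name,
        test=test,
        p_value=float(p),
        z_hi=float(z_hi),
        z_hs=float(z_hs),
        sem_hi=float(sem_hi),
        sem_hs=float(sem_hs),
        mean_hi=float(hi.mean()),
        mean_hs=float(hs.mean()),
    )


def select_features(
    feature_table: pd.DataFrame,
    labels: pd.Series,
    candidates: list[str] | None = None,
    categories: dict[str, str] | None = None,
    max_subset_size: int = 4,
    min_coverage: float = 0.5,
    max_spearman: float = 0.3,
    cv_folds: int = 10,
    cv_repeats: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Enumerate predictor subsets under the selection constraints.

    A subset survives when (i) its joint non-missing coverage is at least
    ``min_coverage`` of all genes and (ii) every feature pair has
    |Spearman rho| < ``max_spearman`` on jointly non-missing genes.
    Survivors are ranked by mean repeated-CV AUC of an LDA fit on the
    labelled genes; ties prefer subsets spanning more of the broad
    categories (genomic / evolutionary / functional / network). Returns a
    report sorted best-first with columns features, coverage, n_categories,
    cv_auc, cv_mcc, selected. The report is empty when nothing survives.
    """
    from .classifier import cross_validate

    if candidates is None:
        candidates = [
            c for c in feature_table.columns
            if pd.api.types.is_numeric_dtype(feature_table[c])
        ]
    candidates = sorted(candidates)
    categories = categories or {}
    n_genes = len(feature_table)

    rows = []
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(candidates, size):
            cols = list(subset)
            joint = feature_table[cols].dropna()
            coverage = len(joint) / n_genes
            if coverage < min_coverage:
                continue
            ok = True
            for a, b in itertools.combinations(cols, 2):
                pair = feature_table[[a, b]].dropna()
                if len(pair) < 3:
                    ok = False
                    break
                rho, _ = stats.spearmanr(pair[a], pair[b])
                if abs(rho) >= max_spearman:
                    ok = False
                    break
            if not ok:
                continue
            labelled = joint.index.intersection(labels.index)
            x = joint.loc[labelled]
            y = labels.loc[labelled]
            if y.nunique() < 2 or min(np.bincount(y.astype(int))) < cv_folds:
                continue
            cv = cross_validate(
                x.values, y.values.astype(int),
                folds=cv_folds, repeats=cv_repeats, seed=seed,
            )
            n_cat = len({categories.get(c, c) for c in cols})
            rows.append(
                {
                    "features": ",".join(cols),
                    "n_features": size,
                    "coverage": coverage,
                    "n_categories": n_cat,
                    "cv_auc": cv.mean_auc,
                    "cv_mcc": cv.mean_mcc,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=["features", "n_features", "coverage", "n_categories",
                 "cv_auc", "cv_mcc"],
    )
    if report.empty:
        report["selected"] = pd.Series(dtype=bool)
        return report
    report = report.sort_values(
        ["cv_auc", "n_categories", "coverage"], ascending=False
    ).reset_index(drop=True)
    report["selected"] = False
    report.loc[0, "selected"] = True
    return report
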