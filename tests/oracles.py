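"""Independent brute-force oracles used to cross-check the implementation.

Everything here works by literal enumeration over explicit base sets,
permutations or densities, deliberately sharing no code path with the
package modules it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats


# --------------------------------------------------------------- LOF calling

def _cds_bases_5to3(tx) -> list[int]:
    bases = []
    for c in tx.cds:
        bases.extend(range(c.start, c.end))
    if tx.strand == "-":
        bases = bases[::-1]
    return bases


def brute_transcript_criterion(tx, deletion) -> str:
    """Literal base-set evaluation of the five ordered LOF rules."""
    if deletion.chrom != tx.chrom:
        return "none"
    d = set(range(deletion.start, deletion.end))
    cds = _cds_bases_5to3(tx)
    deleted = len(set(cds) & d)
    if deleted * 2 > len(cds):
        return "over_half_cds"
    if set(cds[:3]) & d:
        return "start_codon"
    first = tx.exons[0] if tx.strand == "+" else tx.exons[-1]
    if set(range(first.start, first.end)) <= d:
        return "first_exon"
    exon_bases = set()
    for e in tx.exons:
        exon_bases |= set(range(e.start, e.end))
    for a, b in zip(tx.exons, tx.exons[1:]):
        intron = set(range(a.end, b.start))
        windows = {a.end, a.end + 1, b.start - 2, b.start - 1} & intron
        if windows & d:
            return "splice_signal"
    if 0 < deleted < len(cds) and deleted % 3 != 0:
        return "frameshift"
    return "none"


def brute_hs_genes(cnvs, gene_models, min_individuals=2) -> dict[str, int]:
    """Enumerate every (transcript, deletion) pair; count LOF individuals."""
    counts: dict[str, set] = {}
    by_sample: dict[str, list] = {}
    for c in cnvs:
        by_sample.setdefault(c.sample_id, []).append(c.interval)
    for gid, txs in gene_models.genes.items():
        coding = [t for t in txs if t.cds]
        if not coding:
            continue
        for sample, dels in by_sample.items():
            if all(
                any(brute_transcript_criterion(t, d) != "none" for d in dels)
                for t in coding
            ):
                counts.setdefault(gid, set()).add(sample)
    return {g: len(s) for g, s in counts.items() if len(s) >= min_individuals}


# ----------------------------------------------------------------- statistics

def permutation_mannwhitney_p(a, b) -> float:
    """Two-tailed permutation p: P(|U - mean| >= observed) by enumeration."""
    pooled = list(a) + list(b)
    n1 = len(a)
    ranks = stats.rankdata(pooled)
    mu = n1 * len(b) / 2

    def u_of(idx):
        return sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2

    obs = abs(u_of(range(n1)) - mu)
    cnt = tot = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        tot += 1
        if abs(u_of(idx) - mu) >= obs - 1e-9:
            cnt += 1
    return cnt / tot


def hypergeom_fisher_p(a, b, c, d) -> float:
    """Two-sided Fisher p by summing hypergeometric outcomes as extreme
    or less probable than the observed table."""
    m, n, big_n = a + b + c + d, a + b, a + c
    rv = stats.hypergeom(m, n, big_n)
    p_obs = rv.pmf(a)
    lo, hi = max(0, big_n - (c + d)), min(n, big_n)
    return float(
        sum(rv.pmf(k) for k in range(lo, hi + 1) if rv.pmf(k) <= p_obs * (1 + 1e-7))
    )


def pairwise_auc(scores, labels) -> float:
    """AUC by enumerating all (positive, negative) pairs, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def gaussian_bayes_posterior(x, mu1, mu0, cov, prior1) -> float:
    """Posterior P(class 1 | x) from the two Gaussian densities directly."""
    f1 = stats.multivariate_normal(mean=mu1, cov=cov).pdf(x)
    f0 = stats.multivariate_normal(mean=mu0, cov=cov).pdf(x)
    return prior1 * f1 / (prior1 * f1 + (1 - prior1) * f0)


# ------------------------------------------------------------------ LOD score

def product_form_lod(p_list, eps=1e-6) -> float:
    """LOD by direct probability products (no log-space accumulation)."""
    q = 1.0
    for p in p_list:
        q *= 1.0 - min(max(p, eps), 1.0 - eps)
    return math.log10((1.0 - q) / q)


def survival_fraction(values, lod) -> float:
    return sum(1 for v in values if v >= lod) / len(values)
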