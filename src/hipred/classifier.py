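"""Linear discriminant model for haploinsufficiency probability.

Training contrasts known haploinsufficient (HI, label 1) genes against the
CNV-derived haplosufficient (HS, label 0) catalog. Each predictor is first
scaled to unit training variance so discriminant coefficients are
comparable; under the shared-covariance Gaussian model the discriminant is
w = S_pooled^-1 (mu_HI - mu_HS) and the posterior probability of HI is the
logistic of w'x + b, with the intercept set by the class means and priors.

Model assessment follows repeated stratified 10-fold cross-validation; the
area under the ROC curve (rank statistic, ties counted one half) and the
Matthews correlation coefficient at a posterior threshold of 0.5 are
pooled over the held-out folds of each repeat and averaged over repeats.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LDAModel:
    """Fitted linear discriminant with unit-variance feature scaling."""

    feature_names: list[str]
    scale: np.ndarray          # per-feature divisor (training SD)
    mean_hi: np.ndarray        # class means in scaled space
    mean_hs: np.ndarray
    pooled_cov: np.ndarray     # pooled within-class covariance (scaled space)
    coef: np.ndarray           # w = pooled_cov^-1 (mean_hi - mean_hs)
    intercept: float
    prior_hi: float
    prior_hs: float
    n_dropped_incomplete: int = 0

    def coefficient_report(self) -> pd.DataFrame:
        """|w| per feature — the Fig-3-style relative-contribution chart."""
        return pd.DataFrame(
            {"feature": self.feature_names, "abs_coefficient": np.abs(self.coef)}
        ).sort_values("abs_coefficient", ascending=False, ignore_index=True)

    def to_json(self) -> str:
        d = {
            "feature_names": self.feature_names,
            "scale": self.scale.tolist(),
            "mean_hi": self.mean_hi.tolist(),
            "mean_hs": self.mean_hs.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "prior_hi": self.prior_hi,
            "prior_hs": self.prior_hs,
            "n_dropped_incomplete": self.n_dropped_incomplete,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LDAModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            scale=np.array(d["scale"]),
            mean_hi=np.array(d["mean_hi"]),
            mean_hs=np.array(d["mean_hs"]),
            pooled_cov=np.array(d["pooled_cov"]),
            coef=np.array(d["coef"]),
            intercept=d["intercept"],
            prior_hi=d["prior_hi"],
            prior_hs=d["prior_hs"],
            n_dropped_incomplete=d.get("n_dropped_incomplete", 0),
        )


def fit_lda(
    features,
    labels,
    feature_names: list[str] | None = None,
    priors: tuple[float, float] | None = None,
) -> LDAModel:
    """Fit the discriminant on complete cases.

    ``labels``: 1 = HI, 0 = HS. Rows with any missing feature are dropped
    and counted. ``priors`` overrides the default empirical class
    frequencies as (prior_hi, prior_hs).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=int)
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(x.shape[1])]

    complete = ~np.isnan(x).any(axis=1)
    n_dropped = int((~complete).sum())
    x, y = x[complete], y[complete]
    n_hi, n_hs = int((y == 1).sum()), int((y == 0).sum())
    if n_hi < 2 or n_hs < 2:
        raise ValueError("need >= 2 complete-case genes per class")

    scale = x.std(axis=0, ddof=1)
    if (scale == 0).any():
        bad = [feature_names[i] for i in np.where(scale == 0)[0]]
        raise ValueError(f"constant feature(s) {bad}; cannot scale to unit variance")
    xs = x / scale

    xi, xh = xs[y == 1], xs[y == 0]
    mu_hi, mu_hs = xi.mean(axis=0), xh.mean(axis=0)
    s_hi = np.cov(xi, rowvar=False, ddof=1).reshape(xs.shape[1], xs.shape[1])
    s_hs = np.cov(xh, rowvar=False, ddof=1).reshape(xs.shape[1], xs.shape[1])
    pooled = ((n_hi - 1) * s_hi + (n_hs - 1) * s_hs) / (n_hi + n_hs - 2)

    try:
        coef = np.linalg.solve(pooled, mu_hi - mu_hs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; check features for collinearity"
        ) from exc

    if priors is None:
        prior_hi = n_hi / (n_hi + n_hs)
    else:
        prior_hi = priors[0] / (priors[0] + priors[1])
    prior_hs = 1.0 - prior_hi
    intercept = float(
        -0.5 * coef @ (mu_hi + mu_hs) + math.log(prior_hi / prior_hs)
    )
    if np.allclose(mu_hi, mu_hs):
        import warnings

        warnings.warn("identical class means: degenerate (zero) discriminant",
                      stacklevel=2)
    return LDAModel(
        feature_names=list(feature_names),
        scale=scale,
        mean_hi=mu_hi,
        mean_hs=mu_hs,
        pooled_cov=pooled,
        coef=coef,
        intercept=intercept,
        prior_hi=prior_hi,
        prior_hs=prior_hs,
        n_dropped_incomplete=n_dropped,
    )


def predict_phi(model: LDAModel, features, gene_ids=None) -> pd.DataFrame:
    """Posterior probability of haploinsufficiency, p(HI), per gene.

    Rows with a missing feature are excluded and reported via the
    ``predictable`` flag; non-finite observed values are an error.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(x.shape[0])]
    complete = ~np.isnan(x).any(axis=1)
    if np.isinf(x[complete]).any():
        raise ValueError("non-finite feature value")
    phi = np.full(x.shape[0], np.nan)
    if complete.any():
        xs = x[complete] / model.scale
        logit = xs @ model.coef + model.intercept
        phi[complete] = 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(
        {"phi": phi, "predictable": complete},
        index=pd.Index(gene_ids, name="gene_id"),
    )


# -------------------------------------------------------------------- metrics

def auc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) identity.

    Equals U/(n1*n0) with tied score pairs counted one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def mcc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / math.sqrt(denom))


# ----------------------------------------------------------- cross-validation

@dataclass
class CVResult:
    auc_per_repeat: list[float]
    mcc_per_repeat: list[float]
    folds: int
    repeats: int
    seed: int
    mean_auc: float = field(init=False)
    mean_mcc: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_auc = float(np.mean(self.auc_per_repeat))
        self.mean_mcc = float(np.mean(self.mcc_per_repeat))


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator):
    """Random stratified partition: per-class shuffled round-robin chunks."""
    fold_of = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(idx.size) % folds
    return fold_of


def cross_validate(
    features,
    labels,
    folds: int = 10,
    repeats: int = 30,
    seed: int = 0,
    threshold: float = 0.5,
    max_retries: int = 10,
) -> CVResult:
    """Repeated stratified k-fold CV of the discriminant model.

    Per repeat, held-out posteriors are pooled across folds; AUC and the
    MCC at posterior ``threshold`` are computed on the pooled predictions,
    then averaged over repeats. A partition leaving a class absent from
    some training split is re-randomised (bounded retries).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=int)
    if min((y == 1).sum(), (y == 0).sum()) < folds:
        raise ValueError("need >= `folds` genes per class")
    rng = np.random.default_rng(seed)

    aucs, mccs = [], []
    for _ in range(repeats):
        for _attempt in range(max_retries):
            fold_of = _stratified_folds(y, folds, rng)
            ok = all(
                len(np.unique(y[fold_of != k])) == 2 for k in range(folds)
            )
            if ok:
                break
        else:
            raise RuntimeError("could not build a valid stratified partition")
        pooled_phi = np.empty_like(y, dtype=float)
        for k in range(folds):
            test = fold_of == k
            model = fit_lda(x[~test], y[~test])
            pooled_phi[test] = predict_phi(model, x[test])["phi"].values
        aucs.append(auc(pooled_phi, y))
        pred = (pooled_phi >= threshold).astype(int)
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        mccs.append(mcc(tp, tn, fp, fn))
    return CVResult(aucs, mccs, folds, repeats, seed)


# ----------------------------------------------------------------- imputation

def impute_pmm(
    table: pd.DataFrame, seed: int = 0, donors: int = 5
) -> tuple[pd.DataFrame, pd.Series]:
    """Predictive mean matching imputation of missing predictor values.

    For each feature with missing values, a linear regression on the other
    features is fit over complete cases; each missing cell receives the
    observed value of one of the ``donors`` complete cases whose predicted
    value is nearest to the cell's prediction (drawn at random among them).
    Returns the completed table and a boolean per-gene "imputed" flag.
    """
    rng = np.random.default_rng(seed)
    num_cols = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    x = table[num_cols].astype(float)
    complete_mask = x.notna().all(axis=1)
    if not complete_mask.any():
        raise ValueError("no complete cases to support imputation")
    if x.isna().all(axis=0).any():
        raise ValueError("a feature is missing in every row")
    complete = x[complete_mask]

    out = x.copy()
    imputed_flag = x.isna().any(axis=1)
    for col in num_cols:
        miss = x[col].isna()
        if not miss.any():
            continue
        others = [c for c in num_cols if c != col]
        a = np.column_stack(
            [np.ones(len(complete))] + [complete[c].values for c in others]
        )
        b = complete[col].values
        beta, *_ = np.linalg.lstsq(a, b, rcond=None)
        pred_complete = a @ beta
        # recipients predicted from their other (observed or already-imputed)
        # features; rows missing another feature use the complete-case mean
        rec = out.loc[miss, others].copy()
        rec = rec.fillna(complete[others].mean())
        a_rec = np.column_stack([np.ones(len(rec))] + [rec[c].values for c in others])
        pred_rec = a_rec @ beta
        k = min(donors, len(complete))
        for row_label, p in zip(rec.index, pred_rec):
            order = np.argsort(np.abs(pred_complete - p), kind="stable")[:k]
            donor = order[rng.integers(k)]
            out.loc[row_label, col] = b[donor]
    result = table.copy()
    result[num_cols] = out
    return result, imputed_flag


# ----------------------------------------------------------------- enrichment

@dataclass
class EnrichmentResult:
    """Top-decile enrichment of predicted-HI genes in a validation set.

    In odds-ratio mode both the sample odds ratio (``fold_enrichment``)
    and the conditional MLE reported by exact-test software
    (``conditional_odds_ratio``) are provided, since the two differ
    slightly for any finite table.
    """

    a: int  # set A, predicted HI
    b: int  # set A, not predicted
    c: int  # set B / baseline, predicted HI
    d: int  # set B / baseline, not predicted
    fold_enrichment: float
    p_value: float
    definition_used: str  # odds_ratio | proportion_ratio_vs_baseline
    top_fraction: float
    conditional_odds_ratio: float | None = None


def enrichment_test(
    phi: pd.Series,
    set_a: set[str] | list[str],
    set_b: set[str] | list[str] | None = None,
    top_fraction: float = 0.10,
    training_genes: set[str] | None = None,
) -> EnrichmentResult:
    """Enrichment of a gene set among top-p(HI) ("predicted HI") genes.

    Predicted-HI genes are the top ``top_fraction`` of all scored genes.
    With two sets, fold enrichment is the odds ratio of the 2x2 table with
    a two-sided Fisher's exact p. With ``set_b=None`` (baseline mode),
    fold enrichment is the predicted-HI fraction within the set divided by
    ``top_fraction``, with a two-sided binomial p. Sets should be disjoint
    from the training labels; overlap triggers a warning only.
    """
    import warnings

    phi = phi.dropna()
    set_a = set(set_a) & set(phi.index)
    if not set_a:
        raise ValueError("set A has no scored genes")
    if training_genes:
        overlap = (set_a | (set(set_b) if set_b else set())) & set(training_genes)
        if overlap:
            warnings.warn(
                f"{len(overlap)} validation genes overlap the training labels",
                stacklevel=2,
            )
    n_top = int(round(top_fraction * len(phi)))
    predicted = set(phi.sort_values(ascending=False).index[:n_top])

    a = len(set_a & predicted)
    b = len(set_a) - a
    if set_b is not None:
        set_b = set(set_b) & set(phi.index)
        if not set_b:
            raise ValueError("set B has no scored genes")
        c = len(set_b & predicted)
        d = len(set_b) - c
        if b * c == 0:
            fold = math.inf if a * d > 0 else math.nan
        else:
            fold = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        cond = float(stats.contingency.odds_ratio([[a, b], [c, d]]).statistic)
        return EnrichmentResult(a, b, c, d, float(fold), float(p),
                                "odds_ratio", top_fraction,
                                conditional_odds_ratio=cond)
    frac = a / len(set_a)
    fold = frac / top_fraction
    p = stats.binomtest(a, len(set_a), top_fraction, alternative="two-sided").pvalue
    return EnrichmentResult(a, b, 0, 0, float(fold), float(p),
                            "proportion_ratio_vs_baseline", top_fraction)


def enrichment_from_counts(
    a: int, b: int, c: int, d: int, definition: str = "odds_ratio",
    baseline: float = 0.10,
) -> EnrichmentResult:
    """Enrichment arithmetic from a printed 2x2 table or set counts.

    ``odds_ratio``: fold = (a*d)/(b*c), Fisher two-sided p on [[a,b],[c,d]].
    ``proportion_ratio_vs_baseline``: fold = (a/(a+b))/baseline with a
    two-sided binomial p (c, d ignored).
    """
    if definition == "odds_ratio":
        fold = (a * d) / (b * c)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        cond = float(stats.contingency.odds_ratio([[a, b], [c, d]]).statistic)
        return EnrichmentResult(a, b, c, d, float(fold), float(p),
                                definition, baseline,
                                conditional_odds_ratio=cond)
    if definition == "proportion_ratio_vs_baseline":
        fold = (a / (a + b)) / baseline
        p = stats.binomtest(a, a + b, baseline, alternative="two-sided").pvalue
        return EnrichmentResult(a, b, c, d, float(fold), float(p),
                                definition, baseline)
    raise ValueError(f"unknown definition {definition!r}")
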