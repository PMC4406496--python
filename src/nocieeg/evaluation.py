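"""Statistical screening, discriminant classification, Pk, and subset search.

Evaluation follows the sedation-monitoring convention: candidate measures
are screened per trial with the Mann-Whitney U test (Bonferroni-corrected
where a family of comparisons is run), significant measures feed uni- or
multivariable linear discriminant functions validated leave-one-out, and
performance is summarized by sensitivity (Sen, % of response windows
correct), specificity (Spe, % of no-response windows correct) and the
prediction probability

    Pk = (n_concordant + ½ n_tied) / n_between-class_pairs,

the probability that the indicator correctly orders a random response /
no-response pair (0.5 = chance, 1 = perfect).  SE(Pk) is the leave-one-case-
out jackknife estimate, and two indicators are compared through the normal
approximation to the difference of their Pk values.

The multivariable model is built by a randomized constrained search: each
iteration draws up to four mutually-uncorrelated measures (|Spearman ρ|
below a threshold), evaluates them leave-one-out, and keeps the subset if
both Sen and Spe exceed 60%; subsets are ranked by Pk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import EventAnnotation, logger

__all__ = [
    "TrialDefinition",
    "TRIALS",
    "LabeledDataset",
    "EvalResult",
    "DiscriminantModel",
    "mann_whitney",
    "bonferroni",
    "pk_statistic",
    "fit_discriminant",
    "loo_evaluate",
    "compare_pk",
    "screen_measures",
    "random_subset_search",
]


@dataclass(frozen=True)
class TrialDefinition:
    """Binary contrast on events: positive = response, negative = no-response."""

    name: str
    positive: Callable[[EventAnnotation], bool]
    negative: Callable[[EventAnnotation], bool]

    def label(self, event: EventAnnotation) -> Optional[int]:
        """1 for response, 0 for no-response, None if the event is not used."""
        if self.positive(event):
            return 1
        if self.negative(event):
            return 0
        return None


def _rss(pred: Callable[[int], bool]) -> Callable[[EventAnnotation], bool]:
    return lambda ev: ev.kind == "RSS" and pred(ev.value)


def _gag(value: int) -> Callable[[EventAnnotation], bool]:
    return lambda ev: ev.kind == "GAG" and ev.value == value


#: The five RSS contrasts plus the gag-reflex contrast.
TRIALS: dict[str, TrialDefinition] = {
    "trial1": TrialDefinition("trial1", _rss(lambda v: v == 5), _rss(lambda v: v == 6)),
    "trial2": TrialDefinition("trial2", _rss(lambda v: v < 6), _rss(lambda v: v == 6)),
    "trial3": TrialDefinition("trial3", _rss(lambda v: v < 5), _rss(lambda v: v == 5)),
    "trial4": TrialDefinition("trial4", _rss(lambda v: v < 5), _rss(lambda v: v == 6)),
    "trial5": TrialDefinition("trial5", _rss(lambda v: v < 5), _rss(lambda v: v >= 5)),
    "gag": TrialDefinition("gag", _gag(1), _gag(0)),
}


@dataclass
class LabeledDataset:
    """Measure table (windows × named measures) with binary labels
    (1 = response).  Undefined measure values may be NaN; they are excluded
    pairwise when a subset is evaluated."""

    measures: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.measures):
            raise ValueError("labels and measures must have the same length")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")

    @classmethod
    def from_feature_table(cls, table: pd.DataFrame,
                           trial: TrialDefinition) -> "LabeledDataset":
        """Label a feature table (with event metadata columns) for a trial."""
        labels, keep = [], []
        for idx, row in table.iterrows():
            ev = EventAnnotation(float(row["event_time"]),
                                 str(row["event_kind"]), int(row["event_value"]))
            lab = trial.label(ev)
            if lab is not None:
                labels.append(lab)
                keep.append(idx)
        meta = ["event_time", "event_kind", "event_value"]
        measures = table.loc[keep].drop(columns=[c for c in meta
                                                 if c in table.columns])
        return cls(measures.reset_index(drop=True), np.array(labels, dtype=int))


@dataclass
class EvalResult:
    """Pk ± SE plus Sen/Spe (%) for one measure subset."""

    pk: float
    se_pk: float
    sen: float
    spe: float
    subset: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (0 <= self.pk <= 1):
            raise ValueError("Pk must lie in [0, 1]")


@dataclass
class DiscriminantModel:
    """Linear discriminant: pooled within-class covariance, equal priors,
    decision threshold at the midpoint of the projected class means."""

    weights: np.ndarray
    threshold: float
    means: np.ndarray        # (2, d): class 0 and class 1 means
    pooled_cov: np.ndarray

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Signed score; > 0 classifies as response (class 1)."""
        return np.asarray(X, dtype=float) @ self.weights - self.threshold

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)


def mann_whitney(x: Sequence[float], y: Sequence[float]
                 ) -> tuple[float, float]:
    """Mann-Whitney U with two-sided p.

    Exact enumeration when both groups have ≤ 20 observations and there are
    no ties; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p·m)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p_values, dtype=float) * m)


def pk_statistic(scores: Sequence[float], labels: Sequence[int]
                 ) -> tuple[float, float]:
    """Prediction probability Pk and its jackknife standard error.

    Pk is computed over all between-class pairs with class 1 (response) as
    the high-score reference: a pair is concordant when the response window
    scores higher; score ties count one half.  SE is the leave-one-case-out
    jackknife over all windows.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    r = scores[labels == 1]
    s = scores[labels == 0]
    n1, n0 = len(r), len(s)
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    diff = r[:, None] - s[None, :]
    conc = (diff > 0).astype(float)
    tie = (diff == 0).astype(float)
    C, T = conc.sum(), tie.sum()
    n_pairs = n1 * n0
    pk = (C + 0.5 * T) / n_pairs

    # jackknife: delete one window at a time
    c_r = conc.sum(axis=1)    # contributions of each response window
    t_r = tie.sum(axis=1)
    c_s = conc.sum(axis=0)    # contributions of each no-response window
    t_s = tie.sum(axis=0)
    pk_del = np.concatenate([
        ((C - c_r) + 0.5 * (T - t_r)) / ((n1 - 1) * n0) if n1 > 1 else
        np.full(n1, pk),
        ((C - c_s) + 0.5 * (T - t_s)) / (n1 * (n0 - 1)) if n0 > 1 else
        np.full(n0, pk),
    ])
    n = n1 + n0
    se = float(np.sqrt((n - 1) / n * np.sum((pk_del - pk_del.mean()) ** 2)))
    return float(pk), se


def fit_discriminant(measures: np.ndarray, labels: Sequence[int],
                     kind: str = "linear") -> DiscriminantModel:
    """Fit a linear discriminant (pooled covariance, equal priors).

    w = Σ_pooled⁻¹ (μ₁ − μ₀), threshold at the midpoint of the projected
    class means.  Raises on singular pooled covariance (suggesting a smaller
    subset) or a constant measure.
    """
    if kind != "linear":
        raise NotImplementedError("only the linear discriminant is implemented")
    X = np.atleast_2d(np.asarray(measures, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(np.asarray(labels)) > 1:
        X = X.T
    y = np.asarray(labels, dtype=int)
    X0, X1 = X[y == 0], X[y == 1]
    if len(X0) < 2 or len(X1) < 2:
        raise ValueError("need at least 2 windows per class")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant measure in the design matrix")
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (len(X) - 2)
    S = np.atleast_2d(S)
    try:
        w = np.linalg.solve(S, mu1 - mu0)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular pooled covariance; try a smaller or less correlated "
            "measure subset"
        ) from exc
    threshold = float(w @ (mu0 + mu1) / 2)
    return DiscriminantModel(w, threshold, np.vstack([mu0, mu1]), S)


def loo_evaluate(dataset: LabeledDataset, subset: Sequence[str],
                 trial: TrialDefinition | None = None) -> EvalResult:
    """Leave-one-out evaluation of a discriminant on a measure subset.

    Each window is classified by a discriminant fit on all other windows;
    Sen/Spe come from the held-out predictions and Pk (with jackknife SE)
    from the held-out discriminant scores.  Rows with NaN in the subset are
    excluded (pairwise exclusion).
    """
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    X_full = dataset.measures.loc[:, list(subset)].to_numpy(dtype=float)
    mask = np.all(np.isfinite(X_full), axis=1)
    X = X_full[mask]
    y = dataset.labels[mask]
    n = len(y)
    if (y == 1).sum() == 0 or (y == 0).sum() == 0:
        raise ValueError("both classes must be present")
    scores = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        if len(np.unique(y[keep])) < 2:
            raise ValueError("degenerate fold: a training fold lost a class")
        model = fit_discriminant(X[keep], y[keep])
        scores[i] = model.decision_scores(X[i:i + 1])[0]
    pred = (scores > 0).astype(int)
    sen = 100.0 * np.mean(pred[y == 1] == 1)
    spe = 100.0 * np.mean(pred[y == 0] == 0)
    pk, se = pk_statistic(scores, y)
    return EvalResult(pk=pk, se_pk=se, sen=float(sen), spe=float(spe),
                      subset=subset)


def compare_pk(a: EvalResult, b: EvalResult) -> float:
    """Two-sided p for the difference of two Pk values (normal reference)."""
    se = np.hypot(a.se_pk, b.se_pk)
    if se == 0:
        raise ValueError("zero combined standard error")
    z = (a.pk - b.pk) / se
    return float(2 * stats.norm.sf(abs(z)))


def screen_measures(datasets: Sequence[LabeledDataset], alpha: float = 0.05,
                    correct: bool = False) -> list[str]:
    """Measures with Mann-Whitney p < alpha in at least one trial dataset.

    With ``correct=True`` each trial's p-value family is Bonferroni-adjusted
    by the number of measures tested in that trial.
    """
    if not datasets:
        raise ValueError("need at least one labeled dataset")
    cols = list(datasets[0].measures.columns)
    significant: set[str] = set()
    for ds in datasets:
        pvals = {}
        for col in cols:
            vals = ds.measures[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            x = vals[ok & (ds.labels == 1)]
            y = vals[ok & (ds.labels == 0)]
            if len(x) == 0 or len(y) == 0 or (np.std(vals[ok]) == 0):
                continue
            _, p = mann_whitney(x, y)
            pvals[col] = p
        m = max(len(pvals), 1)
        for col, p in pvals.items():
            if (min(1.0, p * m) if correct else p) < alpha:
                significant.add(col)
    logger.info("screening kept %d of %d measures", len(significant), len(cols))
    return [c for c in cols if c in significant]


def random_subset_search(dataset: LabeledDataset,
                         candidates: Sequence[str] | None = None,
                         max_size: int = 4, corr_threshold: float = 0.7,
                         n_iter: int = 1000, min_sen: float = 60.0,
                         min_spe: float = 60.0, seed: int = 0,
                         weight: str = "screening"
                         ) -> list[tuple[tuple[str, ...], EvalResult]]:
    """Randomized constrained search for the best ≤ ``max_size`` subset.

    Each iteration draws up to ``max_size`` measures whose pairwise
    |Spearman ρ| stays below ``corr_threshold``, evaluates them leave-one-out,
    and keeps the result when Sen > ``min_sen`` and Spe > ``min_spe``
    (strict).  Results are sorted by Pk descending, ties broken by higher
    Sen+Spe and then lexicographic subset name, so a given seed always yields
    the same ranked list.

    With ``weight='screening'`` (default) draw probabilities are proportional
    to each measure's univariate evidence (−log₁₀ Mann-Whitney p), which
    concentrates the random search on the informative part of the pool while
    remaining a randomized exploration; ``weight='uniform'`` draws uniformly.
    """
    if candidates is None:
        candidates = screen_measures([dataset])
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate pool (no measure passed screening)")
    rng = np.random.default_rng(seed)

    sub = dataset.measures.loc[:, candidates]
    corr = sub.corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(corr, 0.0)

    if weight == "screening":
        weights = np.empty(len(candidates))
        for k, col in enumerate(candidates):
            vals = sub[col].to_numpy(dtype=float)
            ok = np.isfinite(vals)
            x = vals[ok & (dataset.labels == 1)]
            y = vals[ok & (dataset.labels == 0)]
            _, p = mann_whitney(x, y)
            weights[k] = -np.log10(max(p, 1e-300)) + 0.05
    elif weight == "uniform":
        weights = np.ones(len(candidates))
    else:
        raise ValueError(f"unknown weight scheme {weight!r}")
    weights = weights / weights.sum()

    cache: dict[tuple[str, ...], EvalResult | None] = {}
    results: dict[tuple[str, ...], EvalResult] = {}
    for _ in range(n_iter):
        order = rng.choice(len(candidates), size=len(candidates),
                           replace=False, p=weights)
        chosen: list[int] = []
        for idx in order:
            if len(chosen) == max_size:
                break
            if all(corr[idx, j] < corr_threshold for j in chosen):
                chosen.append(int(idx))
        key = tuple(sorted(candidates[j] for j in chosen))
        if key in cache:
            continue
        try:
            res = loo_evaluate(dataset, key)
        except ValueError:
            cache[key] = None
            continue
        cache[key] = res
        if res.sen > min_sen and res.spe > min_spe:
            results[key] = res
    ranked = sorted(results.items(),
                    key=lambda kv: (-kv[1].pk, -(kv[1].sen + kv[1].spe), kv[0]))
    logger.info("subset search: %d unique subsets evaluated, %d passed "
                "constraints", len(cache), len(ranked))
    return ranked
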