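"""Confirmatory linear discriminant analysis of worker morphometrics.

The confirmatory stage runs Gaussian LDA on individual workers, pools
posteriors to nest-sample means, iteratively assigns wild-card nests
(those the clustering linkages disagreed on) to the class with the
highest nest-mean posterior, validates by leave-one-out
cross-validation at the individual or whole-nest level, and searches
for reduced discriminant functions — short linear combinations of raw
measurements (μm) whose score sign separates two taxa.

Class priors are equal by default: the sampling intensity per species
is a collection artefact, not a population frequency.  Proportional
priors are available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .core import TRAIT_NAMES, SpecimenRecord
from .cluster import WILDCARD, ClusterHypothesis

__all__ = [
    "LDAModel",
    "PosteriorTable",
    "ClassificationMatrix",
    "DiscriminantFunction",
    "fit_lda",
    "predict_posteriors",
    "wildcard_iterate",
    "loocv",
    "classification_matrix",
    "complex_scores",
    "reduce_discriminant",
]


def _design(records: Sequence[SpecimenRecord], traits: Sequence[str]) -> np.ndarray:
    return np.array([[rec.traits[t] for t in traits] for rec in records])


@dataclass
class LDAModel:
    """A fitted Gaussian LDA over raw traits (μm)."""

    classes: list[str]
    traits: list[str]
    estimator: LinearDiscriminantAnalysis
    priors: np.ndarray

    @property
    def n_axes(self) -> int:
        return min(len(self.classes) - 1, len(self.traits))

    @property
    def class_means(self) -> np.ndarray:
        return self.estimator.means_


def fit_lda(
    records: Sequence[SpecimenRecord],
    labels: Sequence[str],
    *,
    traits: Sequence[str] | None = None,
    proportional_priors: bool = False,
    regularize: bool = False,
) -> LDAModel:
    """Fit LDA on individual workers.

    Requires at least two classes with at least two specimens each.  A
    singular pooled within-class covariance raises with a hint to drop
    traits or pass ``regularize=True`` (small ridge on the covariance).
    """
    traits = list(traits) if traits is not None else list(TRAIT_NAMES)
    labels = list(labels)
    if len(labels) != len(records):
        raise ValueError("records and labels differ in length")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class(es) with fewer than 2 specimens: {list(small)}")

    X = _design(records, traits)
    y = np.asarray(labels)

    # explicit singularity check on the pooled within-class covariance
    pooled = np.zeros((len(traits), len(traits)))
    for c in classes:
        Xc = X[y == c]
        pooled += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
    pooled /= max(len(records) - len(classes), 1)
    if np.linalg.matrix_rank(pooled) < len(traits):
        if not regularize:
            raise np.linalg.LinAlgError(
                "pooled within-class covariance is singular; drop collinear "
                "traits or pass regularize=True"
            )

    priors = (
        counts / counts.sum()
        if proportional_priors
        else np.full(len(classes), 1.0 / len(classes))
    )
    if regularize:
        est = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage=1e-6, priors=priors
        )
    else:
        est = LinearDiscriminantAnalysis(solver="svd", priors=priors)
    est.fit(X, y)
    # fix axis signs: first nonzero coefficient of each axis positive
    if hasattr(est, "scalings_"):
        S = est.scalings_
        for j in range(S.shape[1]):
            nz = np.nonzero(S[:, j])[0]
            if nz.size and S[nz[0], j] < 0:
                S[:, j] = -S[:, j]
    return LDAModel(
        classes=[str(c) for c in est.classes_],
        traits=traits,
        estimator=est,
        priors=priors,
    )


@dataclass
class PosteriorTable:
    """Per-specimen class posteriors and their nest-sample means."""

    specimen: pd.DataFrame  # index: specimen_id, columns: classes
    nest: pd.DataFrame      # index: nest_id, columns: classes

    def nest_assignments(self) -> pd.Series:
        return self.nest.idxmax(axis=1)

    def specimen_assignments(self) -> pd.Series:
        return self.specimen.idxmax(axis=1)


def predict_posteriors(
    model: LDAModel, records: Sequence[SpecimenRecord]
) -> PosteriorTable:
    """Gaussian posteriors per worker, averaged arithmetically per nest."""
    for t in model.traits:
        for rec in records:
            if t not in rec.traits:
                raise KeyError(f"record {rec.specimen_id} lacks trait {t}")
    X = _design(records, model.traits)
    proba = model.estimator.predict_proba(X)
    spec = pd.DataFrame(
        proba,
        index=pd.Index([r.specimen_id for r in records], name="specimen_id"),
        columns=model.classes,
    )
    nest_ids = pd.Series([r.nest_id for r in records], index=spec.index)
    nest = spec.groupby(nest_ids).mean()
    nest.index.name = "nest_id"
    return PosteriorTable(specimen=spec, nest=nest)


@dataclass
class WildcardResult:
    labels: dict[str, str]            # nest_id -> final class
    converged: bool
    iterations: list[dict[str, str]]  # per-iteration wild-card assignments


def wildcard_iterate(
    records: Sequence[SpecimenRecord],
    hypothesis: ClusterHypothesis,
    max_iter: int = 25,
    **fit_kwargs,
) -> WildcardResult:
    """Iterative wild-card reclassification.

    Workers of hypothesis-labeled nests train the LDA; each wild-card
    nest is assigned to the class with the highest nest-mean posterior;
    the model is refit with those assignments until they stabilise.
    Non-convergence within ``max_iter`` returns the last state flagged.
    """
    nest_labels = dict(hypothesis.labels)
    seeds = {n: lab for n, lab in nest_labels.items() if lab != WILDCARD}
    wildcards = [n for n, lab in nest_labels.items() if lab == WILDCARD]
    if len(set(seeds.values())) < 2:
        raise ValueError("need at least 2 non-wildcard classes to seed the LDA")
    if not wildcards:
        model = _fit_on(records, seeds, fit_kwargs)
        return WildcardResult(labels=seeds, converged=True, iterations=[{}])

    assignment: dict[str, str] = {}
    trace: list[dict[str, str]] = []
    for _ in range(max_iter):
        current = {**seeds, **assignment}
        model = _fit_on(records, current, fit_kwargs)
        wc_records = [r for r in records if r.nest_id in wildcards]
        post = predict_posteriors(model, wc_records)
        new = {n: str(c) for n, c in post.nest_assignments().items()}
        trace.append(new)
        if new == assignment:
            return WildcardResult(
                labels={**seeds, **new}, converged=True, iterations=trace
            )
        assignment = new
    return WildcardResult(
        labels={**seeds, **assignment}, converged=False, iterations=trace
    )


def _fit_on(records, nest_to_label: Mapping[str, str], fit_kwargs) -> LDAModel:
    train = [r for r in records if r.nest_id in nest_to_label]
    y = [nest_to_label[r.nest_id] for r in train]
    return fit_lda(train, y, **fit_kwargs)


@dataclass
class ClassificationMatrix:
    """Confusion counts with per-class and overall success rates."""

    classes: list[str]
    counts: np.ndarray  # true x predicted
    mode: str           # resubstitution | LOOCV
    level: str          # individual | nest
    skipped: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def overall_rate(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def per_class_rate(self) -> dict[str, float]:
        out = {}
        for i, c in enumerate(self.classes):
            row = self.counts[i].sum()
            out[c] = float(self.counts[i, i]) / row if row else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def _matrix_from_pairs(pairs, classes, mode, level, skipped) -> ClassificationMatrix:
    classes = sorted(classes)
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for true, pred in pairs:
        counts[idx[true], idx[pred]] += 1
    return ClassificationMatrix(
        classes=classes, counts=counts, mode=mode, level=level, skipped=skipped
    )


def classification_matrix(
    model: LDAModel,
    records: Sequence[SpecimenRecord],
    labels: Sequence[str],
    level: str = "individual",
) -> ClassificationMatrix:
    """Resubstitution confusion matrix at individual or nest level."""
    post = predict_posteriors(model, records)
    if level == "individual":
        pred = post.specimen_assignments()
        pairs = list(zip(labels, (str(p) for p in pred)))
    elif level == "nest":
        nest_label = _nest_labels(records, labels)
        pred = post.nest_assignments()
        pairs = [(nest_label[n], str(pred[n])) for n in pred.index]
    else:
        raise ValueError("level must be 'individual' or 'nest'")
    return _matrix_from_pairs(
        pairs, set(t for t, _ in pairs) | set(p for _, p in pairs),
        "resubstitution", level, [],
    )


def _nest_labels(records, labels) -> dict[str, str]:
    out: dict[str, str] = {}
    for rec, lab in zip(records, labels):
        if out.setdefault(rec.nest_id, lab) != lab:
            raise ValueError(f"nest {rec.nest_id} has conflicting labels")
    return out


def loocv(
    records: Sequence[SpecimenRecord],
    labels: Sequence[str],
    level: str = "individual",
    **fit_kwargs,
) -> ClassificationMatrix:
    """Leave-one-out cross-validation.

    ``level="individual"`` holds out one worker per refit;
    ``level="nest"`` holds out all workers of one nest and predicts the
    nest from its mean posterior (no within-nest leakage).  A unit
    whose removal leaves its class with fewer than two members is
    skipped and reported.
    """
    labels = [str(l) for l in labels]
    pairs: list[tuple[str, str]] = []
    skipped: list[str] = []
    if level == "individual":
        counts = pd.Series(labels).value_counts()
        for i, rec in enumerate(records):
            if counts[labels[i]] - 1 < 2:
                skipped.append(rec.specimen_id)
                continue
            train = [r for j, r in enumerate(records) if j != i]
            y = [labels[j] for j in range(len(records)) if j != i]
            model = fit_lda(train, y, **fit_kwargs)
            post = predict_posteriors(model, [rec])
            pairs.append((labels[i], str(post.specimen_assignments().iloc[0])))
    elif level == "nest":
        nest_label = _nest_labels(records, labels)
        nest_counts = pd.Series(list(nest_label.values())).value_counts()
        for nest in sorted(nest_label):
            if nest_counts[nest_label[nest]] - 1 < 2:
                skipped.append(nest)
                continue
            train = [r for r in records if r.nest_id != nest]
            y = [nest_label[r.nest_id] for r in train]
            model = fit_lda(train, y, **fit_kwargs)
            held = [r for r in records if r.nest_id == nest]
            post = predict_posteriors(model, held)
            pairs.append((nest_label[nest], str(post.nest_assignments().iloc[0])))
    else:
        raise ValueError("level must be 'individual' or 'nest'")
    return _matrix_from_pairs(
        pairs, set(labels) | set(p for _, p in pairs), "LOOCV", level, skipped
    )


def complex_scores(
    model: LDAModel, records: Sequence[SpecimenRecord], n_axes: int = 3
) -> pd.DataFrame:
    """Discriminant scores on the first axes (eigenvalue order).

    Axes are centered so that the unweighted mean of the class score
    means is zero; for a two-class model the two class means are then
    exactly symmetric about the origin.
    """
    if len(model.classes) < 2:
        raise ValueError("a species complex with one species has no axes")
    X = _design(records, model.traits)
    scores = model.estimator.transform(X)[:, : min(n_axes, model.n_axes)]
    centers = model.estimator.transform(model.class_means)[:, : scores.shape[1]]
    scores = scores - centers.mean(axis=0)
    return pd.DataFrame(
        scores,
        index=pd.Index([r.specimen_id for r in records], name="specimen_id"),
        columns=[f"LD{i + 1}" for i in range(scores.shape[1])],
    )


@dataclass(frozen=True)
class DiscriminantFunction:
    """A linear score on raw measurements with a two-class sign rule.

    ``score = Σ coef·trait + intercept``; negative scores assign
    ``negative_class``, positive scores ``positive_class``; a score of
    exactly zero is a tie.  ``stats`` stores per-class reference score
    summaries (mean, min, max, 5–95% percentiles, n) used to flag
    atypical scores.
    """

    id: str
    terms: tuple[tuple[str, float], ...]
    intercept: float
    negative_class: str
    positive_class: str
    stats: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    source: str = ""
    kind: str = "linear"  # linear | ratio

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a discriminant function needs at least one term")
        if self.negative_class == self.positive_class:
            raise ValueError("classes must be distinct")

    def evaluate(self, traits: Mapping[str, float]) -> float:
        missing = [t for t, _ in self.terms if t not in traits]
        if missing:
            raise KeyError(f"{self.id}: missing trait(s) {missing}")
        return float(
            sum(c * float(traits[t]) for t, c in self.terms) + self.intercept
        )


def reduce_discriminant(
    records: Sequence[SpecimenRecord],
    labels: Sequence[str],
    max_terms: int = 4,
    *,
    positive_class: str | None = None,
    min_gain_pp: float = 0.5,
    function_id: str = "D",
) -> DiscriminantFunction:
    """Greedy forward search for the shortest reliable linear function.

    Traits are added one at a time, each step keeping the trait that
    maximises leave-one-out success of the two-group LDA restricted to
    the selected traits; the search stops at ``max_terms`` or when the
    best addition gains less than ``min_gain_pp`` percentage points.
    With more than two classes, ``positive_class`` is separated from
    the pooled remainder.  The intercept is centered so the two group
    score means are symmetric about zero.
    """
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if not 2 <= len(classes) <= 4:
        raise ValueError("reduce_discriminant handles 2-4 classes")
    if len(classes) > 2:
        if positive_class is None:
            raise ValueError("positive_class required when pooling >2 classes")
        pos_name = positive_class
        neg_name = "+".join(c for c in classes if c != positive_class)
        y01 = np.array([1 if l == positive_class else 0 for l in labels])
    else:
        neg_name, pos_name = classes
        y01 = np.array([1 if l == pos_name else 0 for l in labels])

    X_full = _design(records, TRAIT_NAMES)

    def loocv_success(cols: list[int]) -> float:
        Xs = X_full[:, cols]
        if np.allclose(Xs.var(axis=0), 0):  # degenerate candidate set
            return 0.0
        hits = 0
        for i in range(len(Xs)):
            mask = np.ones(len(Xs), dtype=bool)
            mask[i] = False
            est = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            try:
                est.fit(Xs[mask], y01[mask])
            except (IndexError, ValueError, np.linalg.LinAlgError):
                continue
            hits += int(est.predict(Xs[i : i + 1])[0] == y01[i])
        return hits / len(Xs)

    selected: list[int] = []
    best_rate = 0.0
    for _ in range(max_terms):
        candidates = [j for j in range(len(TRAIT_NAMES)) if j not in selected]
        rates = [(loocv_success(selected + [j]), j) for j in candidates]
        rate, j = max(rates)
        if rate - best_rate < min_gain_pp / 100.0 and selected:
            break
        selected.append(j)
        best_rate = rate
    if best_rate <= 0.5:
        raise ValueError(
            f"no function with >50% LOOCV success found (best {best_rate:.1%})"
        )

    Xs = X_full[:, selected]
    est = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    est.fit(Xs, y01)
    w = est.coef_[0].copy()
    b = float(est.intercept_[0])
    scores = Xs @ w + b
    m_neg, m_pos = scores[y01 == 0].mean(), scores[y01 == 1].mean()
    b -= (m_neg + m_pos) / 2.0
    if m_pos < m_neg:  # orient so positive_class scores positive
        w, b = -w, -b
    scores = Xs @ w + b

    stats = {}
    for name, mask in ((neg_name, y01 == 0), (pos_name, y01 == 1)):
        s = scores[mask]
        stats[name] = {
            "mean": float(s.mean()), "min": float(s.min()), "max": float(s.max()),
            "p5": float(np.percentile(s, 5)), "p95": float(np.percentile(s, 95)),
            "n": int(mask.sum()), "level": "individual",
        }
    return DiscriminantFunction(
        id=function_id,
        terms=tuple((TRAIT_NAMES[j], float(c)) for j, c in zip(selected, w)),
        intercept=float(b),
        negative_class=neg_name,
        positive_class=pos_name,
        stats=stats,
        source=f"forward selection, LOOCV success {best_rate:.3f}",
    )
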