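"""Split-half reliability and group-template accuracy procedures.

Given a cohort of subjects, each a (time x sources) matrix with a shared
source ordering, three per-edge connectivity metrics can be computed:

* ``precision`` — entries of the cross-validated L1-penalized precision
  matrix (undirected, conditional dependence);
* ``causal_raw`` — the raw pairwise direction criterion for every source
  pair;
* ``two_stage`` — the criterion masked by the precision skeleton (absent
  edges contribute 0).

Reliability is quantified as the Pearson (optionally Spearman)
correlation of vectorized upper-triangle metric values between two halves
of the data: the two temporal halves of one subject (intra-subject), or
two random halves of the cohort, each temporally concatenated
(inter-group).  A group-level network estimated from the full
concatenation serves as a direction template against which per-subject
orientations are scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr, spearmanr

from .core import UNDETERMINED
from .network import I_TO_J, J_TO_I, estimate_skeleton, orient_edges, two_stage
from .simulate import get_detector

METRICS = ("precision", "causal_raw", "two_stage")


@dataclass(frozen=True)
class SubjectData:
    """One subject's multivariate time series (time x sources)."""

    subject_id: str
    series: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2:
            raise ValueError("series must be 2-D (time x sources)")
        if not np.all(np.isfinite(s)):
            raise ValueError("series contains non-finite values")
        object.__setattr__(self, "series", s)

    @property
    def n_sources(self) -> int:
        return self.series.shape[1]


@dataclass(frozen=True)
class ConsistencyReport:
    """Per-unit split-half correlations with a mean +/- sd summary."""

    metric: str
    method: str
    values: np.ndarray
    unit: str = "subject"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(np.abs(v) > 1 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", v)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.values.size > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "method": self.method,
            "unit": self.unit,
            "mean": self.mean,
            "sd": self.sd,
            "values": self.values.tolist(),
        }


def _check_cohort(subjects: Sequence[SubjectData]) -> int:
    if not subjects:
        raise ValueError("empty subject list")
    p = subjects[0].n_sources
    if any(s.n_sources != p for s in subjects):
        raise ValueError("all subjects must share the same number of sources")
    return p


def _pairwise_criterion_matrix(
    X: np.ndarray, method: str, config: Optional[dict], seed: Optional[int]
) -> np.ndarray:
    """Antisymmetric p x p matrix of pairwise criterion values (i < j)."""
    p = X.shape[1]
    detector = get_detector(method, config)
    rng = np.random.default_rng(seed)
    M = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            c = detector(X[:, i], X[:, j], rng).criterion_C
            M[i, j] = c
            M[j, i] = -c
    return M


def _metric_values(
    X: np.ndarray,
    metric: str,
    method: str,
    config: Optional[dict],
    cv_folds: int,
    seed: Optional[int],
):
    """Upper-triangle metric vector; two_stage also returns its edge mask."""
    p = X.shape[1]
    iu = np.triu_indices(p, k=1)
    if metric == "precision":
        from sklearn.covariance import GraphicalLassoCV  # noqa: F401  (documented dep)

        import warnings

        from sklearn.exceptions import ConvergenceWarning
        from sklearn.model_selection import KFold

        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            prec = GraphicalLassoCV(cv=cv, max_iter=200).fit(Z).precision_
        return prec[iu], None
    if metric == "causal_raw":
        M = _pairwise_criterion_matrix(X, method, config, seed)
        return M[iu], None
    if metric == "two_stage":
        skeleton = estimate_skeleton(X, cv_folds=cv_folds, seed=seed)
        net = orient_edges(X, skeleton, method=method, config=config, seed=seed)
        vals = np.zeros(len(iu[0]))
        mask = np.zeros(len(iu[0]), dtype=bool)
        for k, (i, j) in enumerate(zip(*iu)):
            if skeleton[i, j]:
                mask[k] = True
                sign = {I_TO_J: -1.0, J_TO_I: 1.0, UNDETERMINED: 0.0}[
                    net.orientation[(i, j)]
                ]
                vals[k] = sign * net.edge_strength[(i, j)]
        return vals, mask
    raise ValueError(f"unknown metric: {metric!r} (expected one of {METRICS})")


def _half_correlation(
    Xa: np.ndarray,
    Xb: np.ndarray,
    metric: str,
    method: str,
    config: Optional[dict],
    cv_folds: int,
    seed: Optional[int],
    spearman: bool = False,
    mask_mode: str = "full",
) -> float:
    va, ma = _metric_values(Xa, metric, method, config, cv_folds, seed)
    vb, mb = _metric_values(Xb, metric, method, config, cv_folds, seed)
    if metric == "two_stage" and mask_mode == "union":
        # restrict to pairs present in at least one half's skeleton;
        # an edge absent in only one half contributes 0 on that half
        union = ma | mb
        va, vb = va[union], vb[union]
    elif metric == "two_stage" and mask_mode != "full":
        raise ValueError("mask_mode must be 'full' or 'union'")
    if va.size < 2:
        return np.nan
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        # degenerate: no variation in one half's metric values
        return 1.0 if np.allclose(va, vb) else 0.0
    if spearman:
        return float(spearmanr(va, vb).statistic)
    return float(pearsonr(va, vb).statistic)


def split_halves(X: np.ndarray):
    """Temporal split at the midpoint; an odd sample goes to the first half."""
    n = X.shape[0]
    first = (n + 1) // 2
    return X[:first], X[first:]


def intra_subject_split_half(
    subjects: Sequence[SubjectData],
    metric: str = "two_stage",
    method: str = "soc",
    config: Optional[dict] = None,
    cv_folds: int = 5,
    seed: Optional[int] = None,
    spearman: bool = False,
    mask_mode: str = "full",
) -> ConsistencyReport:
    """Per-subject correlation of the metric between the two temporal halves.

    For the two_stage metric, ``mask_mode='full'`` correlates the complete
    upper-triangle network vectors (edges absent from a half's skeleton
    contribute 0 there), i.e. the two half networks are correlated as
    matrices; ``'union'`` restricts to pairs present in at least one
    half's skeleton.
    """
    _check_cohort(subjects)
    values = []
    for subject in subjects:
        xa, xb = split_halves(subject.series)
        values.append(
            _half_correlation(
                xa, xb, metric, method, config, cv_folds, seed, spearman, mask_mode
            )
        )
    return ConsistencyReport(metric=metric, method=method, values=np.array(values))


def inter_group_split_half(
    subjects: Sequence[SubjectData],
    n_repeats: int = 100,
    metric: str = "two_stage",
    method: str = "soc",
    config: Optional[dict] = None,
    cv_folds: int = 5,
    seed: Optional[int] = None,
    spearman: bool = False,
    mask_mode: str = "full",
) -> ConsistencyReport:
    """Correlation of the metric between two random cohort halves.

    Each repeat randomly splits the subject list into disjoint halves,
    temporally concatenates the series within each half, and correlates
    the two halves' metric vectors.
    """
    _check_cohort(subjects)
    if len(subjects) < 4:
        raise ValueError("need at least 4 subjects for a group split")
    rng = np.random.default_rng(seed)
    half = len(subjects) // 2
    values = []
    for _ in range(n_repeats):
        order = rng.permutation(len(subjects))
        ga = np.vstack([subjects[k].series for k in order[:half]])
        gb = np.vstack([subjects[k].series for k in order[half : 2 * half]])
        values.append(
            _half_correlation(
                ga, gb, metric, method, config, cv_folds, seed, spearman, mask_mode
            )
        )
    return ConsistencyReport(
        metric=metric, method=method, values=np.array(values), unit="repeat"
    )


def template_accuracy(
    subjects: Sequence[SubjectData],
    template_method: str = "soc",
    config: Optional[dict] = None,
    cv_folds: int = 5,
    n_subjects_drawn: int = 20,
    n_repeats: int = 1,
    seed: Optional[int] = None,
    subject_method: Optional[str] = None,
):
    """Per-edge accuracy of subject-level directions against a group template.

    The template network is estimated by the two-stage procedure on the
    temporal concatenation of all subjects (a proxy for ground truth given
    its large sample size).  Repeatedly, ``n_subjects_drawn`` subjects are
    sampled without replacement; each sampled subject's data alone orients
    the template's edges, and per-edge accuracy is the fraction of
    subject-level directions matching the template.  An undetermined
    subject-level direction is scored as a seeded coin flip.

    Returns ``(edge_accuracy, global_accuracy, template)`` where
    ``edge_accuracy`` maps template edges (i, j) to accuracies.
    """
    _check_cohort(subjects)
    concat = np.vstack([s.series for s in subjects])
    template = two_stage(concat, method=template_method, config=config,
                         cv_folds=cv_folds, seed=seed)
    edges = [
        e for e in template.edges if template.orientation[e] != UNDETERMINED
    ]
    if not edges:
        raise ValueError("template skeleton has no oriented edges")
    rng = np.random.default_rng(seed)
    detector = get_detector(subject_method or template_method, config)
    hits = {e: 0 for e in edges}
    total = 0
    n_draw = min(n_subjects_drawn, len(subjects))
    for _ in range(n_repeats):
        chosen = rng.choice(len(subjects), size=n_draw, replace=False)
        for k in chosen:
            X = subjects[k].series
            for i, j in edges:
                res = detector(X[:, i], X[:, j], rng)
                if res.direction == UNDETERMINED:
                    match = rng.random() < 0.5
                else:
                    subj_dir = I_TO_J if res.direction == "x_to_y" else J_TO_I
                    match = subj_dir == template.orientation[(i, j)]
                hits[(i, j)] += int(match)
        total += n_draw
    edge_accuracy = {e: hits[e] / total for e in edges}
    global_accuracy = float(np.mean(list(edge_accuracy.values())))
    return edge_accuracy, global_accuracy, template
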