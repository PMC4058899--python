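"""Random-label null distributions, Z-tests, and feature-recurrence inference.

The null for classifier performance is built by randomly re-labeling the
subjects (an independent fair coin per subject by default, matching "randomly
classify each participant"; a label-permutation mode preserving the 21/21
split is also available) and re-running the entire LOOCV pipeline on the same
feature matrix.  Observed accuracy/precision are then compared with the null
by a one-sided Z-test and the "2 SD above the null mean" criterion.

Feature recurrence: under 90% elimination each fold retains exactly n_keep
features out of n_total; if selection were uniform, a given feature would
appear in a fold with probability q = n_keep / n_total, so its count over
n_folds folds is Binomial(n_folds, q).  The exact upper tail P(X >= k) is the
recurrence p-value.  A "literal" mode with q = 1 / n_total is retained for
comparison with the simpler back-of-envelope convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import CVReport, loocv_pipeline

__all__ = [
    "NullDistribution",
    "RecurrenceReport",
    "permutation_null",
    "z_test",
    "feature_recurrence",
    "recurrence_pvalue",
]

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    metric: str  # "accuracy" | "precision"
    values: np.ndarray
    n_permutations: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.n_permutations:
            raise ValueError("values length must equal n_permutations")
        if ((self.values < 0) | (self.values > 1)).any():
            raise ValueError("null metric values must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        return float(self.values.std())

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Inclusive central interval (e.g. 2.5th-97.5th percentile)."""
        lo = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.values, lo)),
            float(np.quantile(self.values, 1.0 - lo)),
        )


@dataclass
class RecurrenceReport:
    counts: dict[str, int]  # feature name -> folds in which selected
    n_folds: int
    n_keep: int
    n_total: int
    pvalues: dict[str, float]


def permutation_null(
    table,
    elim_frac: float = 0.0,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "bernoulli",
    n_rounds: int = 10,
    C: float = 1.0,
) -> tuple[NullDistribution, NullDistribution]:
    """Accuracy and precision distributions under random labels.

    Each repetition draws new labels (``mode="bernoulli"``: fair coin per
    subject; ``mode="permutation"``: shuffle the true labels), reruns the full
    LOOCV pipeline on the same feature matrix, and records both metrics.
    Repetitions producing a single-class labeling (or a class with fewer than
    2 members, which LOOCV cannot fold) are redrawn and logged.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if mode not in ("bernoulli", "permutation"):
        raise ValueError(f"unknown null mode {mode!r}")
    rng = np.random.default_rng(seed)
    n = len(table.labels)
    base = np.asarray(table.labels, dtype=int)
    accs = np.empty(n_perm)
    precs = np.empty(n_perm)
    n_redraws = 0
    for r in range(n_perm):
        while True:
            labels = (
                rng.integers(0, 2, size=n)
                if mode == "bernoulli"
                else rng.permutation(base)
            )
            counts = np.bincount(labels, minlength=2)
            if counts.min() >= 2:
                break
            n_redraws += 1
            logger.info("degenerate random labeling redrawn (repetition %d)", r)
        shuffled = _relabel(table, labels)
        report = loocv_pipeline(
            shuffled, elim_frac=elim_frac, n_rounds=n_rounds, C=C
        )
        accs[r] = report.accuracy
        precs[r] = report.precision
    if n_redraws:
        logger.info("%d degenerate labelings redrawn in total", n_redraws)
    return (
        NullDistribution(metric="accuracy", values=accs, n_permutations=n_perm),
        NullDistribution(metric="precision", values=precs, n_permutations=n_perm),
    )


def _relabel(table, labels: np.ndarray):
    from .features import FeatureTable

    return FeatureTable(
        kind=table.kind,
        names=list(table.names),
        values=np.asarray(table.values, dtype=float),
        labels=labels,
        subject_ids=list(table.subject_ids),
    )


def z_test(actual: float, null: NullDistribution) -> tuple[float, float, bool]:
    """One-sided upper-tail Z-test of an observed metric against its null.

    Returns (z, p, above_2sd) where ``above_2sd`` is the strict criterion
    actual > mean + 2 * sd.
    """
    sd = null.sd
    if sd == 0:
        raise ValueError("null distribution has zero standard deviation")
    z = (actual - null.mean) / sd
    p = float(stats.norm.sf(z))
    return float(z), p, bool(actual > null.mean + 2.0 * sd)


def recurrence_pvalue(
    k: int, n_folds: int, n_keep: int, n_total: int, mode: str = "subset"
) -> float:
    """Exact binomial upper tail P(X >= k), X ~ Binomial(n_folds, q).

    ``mode="subset"`` (default): q = n_keep / n_total, the appearance
    probability of a specific feature when n_keep of n_total are retained
    uniformly per fold.  ``mode="literal"``: q = 1 / n_total.
    """
    if not 0 <= k <= n_folds:
        raise ValueError("require 0 <= k <= n_folds")
    if not 1 <= n_keep <= n_total:
        raise ValueError("require 1 <= n_keep <= n_total")
    if mode == "subset":
        q = n_keep / n_total
    elif mode == "literal":
        q = 1.0 / n_total
    else:
        raise ValueError(f"unknown recurrence mode {mode!r}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n_folds, q))


def feature_recurrence(report: CVReport, mode: str = "subset") -> RecurrenceReport:
    """Count per-feature selections across LOOCV folds and attach exact
    binomial tail p-values under the uniform-selection null."""
    if not report.folds:
        raise ValueError("CV report has no folds")
    all_names: set[str] = set()
    for f in report.folds:
        all_names |= f.selected_features
    n_keep = max(len(f.selected_features) for f in report.folds)
    n_folds = len(report.folds)
    n_total = report.n_features if report.n_features else n_keep
    counts = {
        name: sum(1 for f in report.folds if name in f.selected_features)
        for name in sorted(all_names)
    }
    pvalues = {
        name: recurrence_pvalue(c, n_folds, n_keep, n_total, mode=mode)
        for name, c in counts.items()
    }
    return RecurrenceReport(
        counts=counts, n_folds=n_folds, n_keep=n_keep, n_total=n_total, pvalues=pvalues
    )
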