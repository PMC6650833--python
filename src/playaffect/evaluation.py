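"""Evaluation protocols and statistics.

Study-1 protocol: leave-one-session-out cross-validation (LOSOCV) over the
three calibration games — train on two games, test on the held-out one,
yielding fold accuracies L1..L3 whose mean is the subject accuracy A_i; the
pooled fold accuracies across subjects form the J sample compared between
feature-set tests with a Wilcoxon signed-rank test.

Study-2 protocol: train on all three calibration games, test on the
independent evaluation-game samples labeled from self-reports; the cohort
aggregate is the mean of A_i over evaluable subjects, reported against a
chance-level accuracy threshold derived from the binomial cumulative
distribution at the mean test-set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .dataset import FeatureSetSpec
from .exceptions import InvalidInputError, ProtocolError
from .model import ModelConfig, UserModel, predict_table, train_user_model

LABELS = ("boredom", "stress")


# ------------------------------------------------------------------ metrics

def classification_metrics(
    predictions: Sequence[str], labels: Sequence[str]
) -> dict[str, float]:
    """Accuracy plus per-class and macro precision/recall/F1.

    Zero-denominator conventions: a metric whose denominator is empty is 0.
    Macro values are unweighted means over the two classes.
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(labels)
    if len(y_pred) != len(y_true):
        raise InvalidInputError("predictions and labels must have equal length")
    if len(y_true) == 0:
        raise InvalidInputError("need at least one sample")
    cm = confusion_matrix(y_true, y_pred, labels=list(LABELS))
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(LABELS), zero_division=0
    )
    out: dict[str, float] = {"accuracy": float(np.trace(cm) / cm.sum())}
    for i, cls in enumerate(LABELS):
        out[f"precision_{cls}"] = float(prec[i])
        out[f"recall_{cls}"] = float(rec[i])
        out[f"f1_{cls}"] = float(f1[i])
    out["precision_macro"] = float(prec.mean())
    out["recall_macro"] = float(rec.mean())
    out["f1_macro"] = float(f1.mean())
    return out


@dataclass
class EvalResult:
    """Per-subject evaluation outcome (LOSOCV folds or one test set)."""

    subject_id: int
    fold_accuracies: list[float]
    accuracy: float  # A_i: mean of folds, or the single test accuracy
    metrics: dict[str, float]
    n_samples: int
    class_counts: dict[str, int] = field(default_factory=dict)


# ------------------------------------------------------------------ protocols

def losocv_evaluate(
    samples: pd.DataFrame,
    spec: FeatureSetSpec,
    cfg: ModelConfig | None = None,
    subject_id: int = 0,
) -> EvalResult:
    """Leave-one-session-out CV over a subject's three calibration games.

    ``samples`` is the labeled training table whose ``source`` column names
    the game of each sample; each of the three games is held out once.
    """
    cfg = cfg or ModelConfig()
    games = sorted(samples["source"].unique())
    if len(games) != 3:
        raise ProtocolError(f"LOSOCV needs exactly 3 games, got {games}")
    folds: list[float] = []
    pooled_metrics: list[dict[str, float]] = []
    for held_out in games:
        train = samples[samples["source"] != held_out]
        test = samples[samples["source"] == held_out]
        assert not set(train.index) & set(test.index)
        model = train_user_model(train, spec.features, cfg, subject_id=subject_id)
        pred = predict_table(model, test)
        m = classification_metrics(pred["label"], test["label"])
        folds.append(m["accuracy"])
        pooled_metrics.append(m)
    mean_metrics = {
        k: float(np.mean([m[k] for m in pooled_metrics])) for k in pooled_metrics[0]
    }
    return EvalResult(
        subject_id=subject_id,
        fold_accuracies=folds,
        accuracy=float(np.mean(folds)),
        metrics=mean_metrics,
        n_samples=len(samples),
        class_counts=samples["label"].value_counts().to_dict(),
    )


def cross_game_evaluate(
    train_samples: pd.DataFrame,
    test_samples: pd.DataFrame,
    spec: FeatureSetSpec,
    cfg: ModelConfig | None = None,
    subject_id: int = 0,
) -> EvalResult:
    """Study-2 protocol for one subject: calibration-trained model applied to
    the independent evaluation-game test set."""
    cfg = cfg or ModelConfig()
    if len(test_samples) == 0:
        raise ProtocolError("empty test set; subject is unevaluable")
    model = train_user_model(train_samples, spec.features, cfg, subject_id=subject_id)
    pred = predict_table(model, test_samples)
    m = classification_metrics(pred["label"], test_samples["label"])
    return EvalResult(
        subject_id=subject_id,
        fold_accuracies=[m["accuracy"]],
        accuracy=m["accuracy"],
        metrics=m,
        n_samples=len(test_samples),
        class_counts=test_samples["label"].value_counts().to_dict(),
    )


def cohort_summary(results: Sequence[EvalResult]) -> dict:
    """Mean of A_i over evaluable subjects plus distribution summaries."""
    if not results:
        raise InvalidInputError("no evaluable subjects")
    acc = np.asarray([r.accuracy for r in results])
    hist, edges = np.histogram(acc, bins=np.linspace(0.0, 1.0, 11))
    return {
        "n_subjects": len(results),
        "mean_accuracy": float(acc.mean()),
        "min_accuracy": float(acc.min()),
        "max_accuracy": float(acc.max()),
        "mean_test_set_size": float(np.mean([r.n_samples for r in results])),
        "accuracy_histogram": {"counts": hist.tolist(), "bin_edges": edges.tolist()},
        "per_subject": {r.subject_id: r.accuracy for r in results},
    }


# ------------------------------------------------------------- chance level

@dataclass
class ChanceLevelResult:
    """Minimal accuracy distinguishable from guessing at test-set size n."""

    n: int
    c: int
    alpha: float
    k_min: int
    threshold_exact: float      # 100 * k_min / n
    threshold_floor_pct: int
    convention: str


def chance_threshold(
    n: int, c: int = 2, alpha: float = 0.05, convention: str = "inverse_cdf"
) -> ChanceLevelResult:
    """Chance-level accuracy threshold from the binomial cumulative distribution.

    For X ~ Binomial(n, 1/c):

    * ``inverse_cdf`` (default): k_min is the smallest k with
      P(X <= k) >= 1 - alpha — the convention of the chance-level literature
      the method calibrates against (n=64, c=2, alpha=0.05 -> 60%).
    * ``strict_tail``: k_min is the smallest k with P(X >= k) <= alpha, i.e.
      the smallest count already individually significant.

    The floored integer percentage is the figure quoted alongside observed
    accuracies; the exact value 100*k_min/n is also reported.
    """
    if n < 1 or c < 2 or not 0 < alpha < 1:
        raise InvalidInputError(f"invalid chance-level parameters n={n}, c={c}, alpha={alpha}")
    if convention not in ("inverse_cdf", "strict_tail"):
        raise InvalidInputError(f"unknown convention {convention!r}")
    p = 1.0 / c
    ks = np.arange(n + 1)
    if convention == "inverse_cdf":
        cdf = stats.binom.cdf(ks, n, p)
        k_min = int(ks[np.argmax(cdf >= 1.0 - alpha)])
    else:
        sf = stats.binom.sf(ks - 1, n, p)  # P(X >= k)
        candidates = ks[sf <= alpha]
        if len(candidates) == 0:
            raise InvalidInputError(f"no k with tail <= alpha for n={n}, alpha={alpha}")
        k_min = int(candidates[0])
    exact = 100.0 * k_min / n
    return ChanceLevelResult(
        n=n, c=c, alpha=alpha, k_min=k_min,
        threshold_exact=exact, threshold_floor_pct=int(np.floor(exact)),
        convention=convention,
    )


# ---------------------------------------------------------------- Wilcoxon

@dataclass
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    z: float
    p: float
    r: float          # effect size |Z| / sqrt(N)
    n_used: int
    exact: bool


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p over all sign assignments of the given ranks.

    Uses the generating polynomial over doubled (hence integer) ranks; the
    null distribution of W+ is symmetric about mu even under ties, so the
    two-sided p is P(|W+ - mu| >= |w - mu|).
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = r2.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = 2.0 * w_plus
    mu = total / 2.0
    dev = abs(w2 - mu)
    support = np.arange(total + 1)
    return float(counts[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 15
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test with effect size.

    Zero differences are dropped.  For N <= ``exact_max_n`` the two-sided p
    comes from the exact sign-flip distribution (valid under ties); larger N
    uses the tie-corrected normal approximation with continuity correction.
    Z is always reported from the normal approximation, and the effect size
    is r = |Z| / sqrt(N).  All differences zero yields the degenerate
    result Z=0, p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 1.0, 0.0, 0, True)
    if n < 5:
        raise InvalidInputError(f"need >= 5 nonzero differences, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    tie_counts = np.unique(ranks, return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    if var <= 0:
        return WilcoxonResult(w_plus, 0.0, 1.0, 0.0, n, True)
    dev = w_plus - mu
    z = (dev - 0.5 * np.sign(dev)) / np.sqrt(var) if dev != 0 else 0.0
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        exact = True
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
        exact = False
    return WilcoxonResult(
        statistic=w_plus, z=float(z), p=min(float(p), 1.0),
        r=float(abs(z) / np.sqrt(n)), n_used=n, exact=exact,
    )
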