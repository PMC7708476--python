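"""Lineage decoding from event-response fingerprints.

Each cell's row of the responsiveness matrix Δ (its response to every
detected discharge) is its "fingerprint".  A regularized logistic
regression projects fingerprints onto a one-dimensional "mGC-ness" score;
the per-event weights identify pro-mGC (weight > +cutoff) and anti-mGC
(< −cutoff) events, and a two-way ANOVA (population × event class, with
interaction) verifies that the informative events differentially modulate
the two granule-cell populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
import statsmodels.api as sm
from statsmodels.formula.api import ols

from .session import ABGC, MGC
from .responsiveness import ResponseMatrix

__all__ = [
    "ClassifierResult",
    "InformativeEvents",
    "fit_lineage_classifier",
    "cross_validate",
    "informative_events",
    "event_class_anova",
]

_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class ClassifierResult:
    """Fitted lineage classifier: per-event weights and per-cell scores."""

    weights: np.ndarray          # one weight per event (A.U.)
    intercept: float
    penalty: str                 # "l1" or "l2"
    C: float
    scores: np.ndarray           # signed distance per cell; positive ↔ mGC
    accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))
    feat_mean: np.ndarray | None = None
    feat_sd: np.ndarray | None = None


@dataclass
class InformativeEvents:
    """Events most predictive of lineage under the sparse (L1) fit."""

    pro_mgc: np.ndarray
    anti_mgc: np.ndarray
    cutoff: float


def _features(delta: np.ndarray, mean=None, sd=None):
    """Cells × events features, z-scored per event column."""
    X = np.asarray(delta, dtype=float)
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray([1 if lab == MGC else 0 for lab in labels])
    if y.all() or not y.any():
        raise ValueError("both lineage classes must be present")
    return y


def _make_lr(penalty: str, C: float) -> LogisticRegression:
    if penalty == "l1":
        return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                  max_iter=5000)
    return LogisticRegression(l1_ratio=0.0, C=C, solver="lbfgs",
                              max_iter=5000)


def _choose_C(X, y, penalty: str, seed: int) -> float:
    """Nested 5-fold CV over a small C grid (balanced accuracy)."""
    n_min = min(np.bincount(y))
    n_splits = min(5, n_min)
    if n_splits < 2:
        return 1.0
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    gs = GridSearchCV(_make_lr(penalty, 1.0), {"C": list(_C_GRID)},
                      scoring="balanced_accuracy", cv=cv)
    gs.fit(X, y)
    return float(gs.best_params_["C"])


def fit_lineage_classifier(
    R: ResponseMatrix | np.ndarray,
    labels,
    penalty: str = "l2",
    C: float | None = None,
    seed: int = 0,
) -> ClassifierResult:
    """Fit logistic regression decoding lineage from response fingerprints.

    Features are each cell's Δ row, z-scored per event; positive scores map
    to mGC by convention.  When ``C`` is None the regularization strength
    is chosen by 5-fold cross-validation on the provided data.
    """
    delta = R.delta if isinstance(R, ResponseMatrix) else np.asarray(R)
    y = _binary_labels(labels)
    if delta.shape[0] != y.size:
        raise ValueError("one label per cell required")
    X, mean, sd = _features(delta)
    if C is None:
        C = _choose_C(X, y, penalty, seed)
    lr = _make_lr(penalty, C)
    lr.fit(X, y)
    scores = lr.decision_function(X)
    return ClassifierResult(
        weights=lr.coef_.ravel().copy(),
        intercept=float(lr.intercept_[0]),
        penalty=penalty,
        C=float(C),
        scores=scores,
        feat_mean=mean,
        feat_sd=sd,
    )


def cross_validate(
    R: ResponseMatrix | np.ndarray,
    labels,
    penalty: str = "l2",
    C: float | None = None,
    n_splits: int = 100,
    test_fraction: float = 0.2,
    balanced: bool = True,
    seed: int = 0,
) -> dict:
    """Repeated 80–20 split-by-cell cross-validation of the lineage decoder.

    Test sets are class-balanced by subsampling the majority class to the
    minority size, removing the effect of population size on accuracy.
    Returns mean, sd and the per-split accuracy distribution.
    """
    delta = R.delta if isinstance(R, ResponseMatrix) else np.asarray(R)
    y = _binary_labels(labels)
    rng = np.random.default_rng(seed)
    n = y.size
    n_test = max(int(round(test_fraction * n)), 2)
    accs = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        # both classes must appear on each side; resample if not
        guard = 0
        while (len(set(y[train])) < 2 or len(set(y[test])) < 2) and guard < 100:
            perm = rng.permutation(n)
            test, train = perm[:n_test], perm[n_test:]
            guard += 1
        if len(set(y[test])) < 2:
            raise ValueError("minority class too small to populate test splits")
        Xtr, mean, sd = _features(delta[train])
        Xte, _, _ = _features(delta[test], mean, sd)
        Cs = C if C is not None else _choose_C(Xtr, y[train], penalty,
                                               seed=int(rng.integers(2 ** 31)))
        lr = _make_lr(penalty, Cs)
        lr.fit(Xtr, y[train])
        te_idx = np.arange(len(test))
        if balanced:
            pos = te_idx[y[test] == 1]
            neg = te_idx[y[test] == 0]
            m = min(pos.size, neg.size)
            keep = np.concatenate([
                rng.choice(pos, size=m, replace=False),
                rng.choice(neg, size=m, replace=False),
            ])
        else:
            keep = te_idx
        accs[s] = (lr.predict(Xte[keep]) == y[test][keep]).mean()
    return {
        "mean": float(accs.mean()),
        "sd": float(accs.std(ddof=1)) if n_splits > 1 else 0.0,
        "accuracies": accs,
        "penalty": penalty,
    }


def informative_events(
    res: ClassifierResult,
    cutoff: float = 0.1,
) -> InformativeEvents:
    """Threshold the per-event weights into pro-/anti-mGC event sets."""
    w = res.weights
    return InformativeEvents(
        pro_mgc=np.flatnonzero(w > cutoff),
        anti_mgc=np.flatnonzero(w < -cutoff),
        cutoff=cutoff,
    )


def event_class_anova(
    R: ResponseMatrix | np.ndarray,
    labels,
    ie: InformativeEvents,
) -> dict:
    """Two-way ANOVA: responsiveness ~ population × event class.

    The response variable is each cell's mean Δ over the pro-mGC events and
    (separately) over the anti-mGC events; factors are lineage population
    and event class, with interaction.  Returns F and p for the two main
    effects and the interaction.
    """
    delta = R.delta if isinstance(R, ResponseMatrix) else np.asarray(R)
    if ie.pro_mgc.size == 0 or ie.anti_mgc.size == 0:
        raise ValueError("both informative event classes must be non-empty")
    y = _binary_labels(labels)
    rows = []
    for c in range(delta.shape[0]):
        pop = MGC if y[c] else ABGC
        rows.append({"resp": delta[c, ie.pro_mgc].mean(),
                     "population": pop, "event_class": "pro"})
        rows.append({"resp": delta[c, ie.anti_mgc].mean(),
                     "population": pop, "event_class": "anti"})
    df = pd.DataFrame(rows)
    model = ols("resp ~ C(population) * C(event_class)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    out = {}
    for key, row in (("population", "C(population)"),
                     ("event_class", "C(event_class)"),
                     ("interaction", "C(population):C(event_class)")):
        out[key] = {"F": float(table.loc[row, "F"]),
                    "p": float(table.loc[row, "PR(>F)"])}
    out["table"] = table
    return out
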