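"""Inverse decoding and population synchrony.

Two closing analyses: (1) decode the most active ensemble of each event
from the LFP power spectrum of the frame in which it occurred (random
forest, repeated 80–20 splits) — if decoding beats chance, distinct
ensembles leave distinct electrographic signatures; (2) quantify the
synchrony between adult-born and mature granule cells as the Kendall tau
between their median event-activation vectors, and compare session-level
synchrony between groups with a two-sided Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit

from .session import ABGC, MGC
from .ler import LERFit
from .lfp import SpectrumMatrix, one_over_f_correct
from .responsiveness import ActivationMatrix, ResponseMatrix

__all__ = [
    "DecodeResult",
    "SynchronyResult",
    "most_active_ensemble",
    "spectrum_features",
    "decode_from_spectrum",
    "population_synchrony",
    "compare_synchrony",
]


@dataclass
class DecodeResult:
    accuracies: np.ndarray       # per-split test accuracy
    chance_uniform: float        # 1/K
    chance_empirical: float      # majority-class frequency
    p_value: float               # exact binomial vs empirical chance, pooled
    confusion: np.ndarray
    classes: np.ndarray


@dataclass
class SynchronyResult:
    tau: float                   # NaN when undefined (constant median vector)
    p_value: float | None = None


def most_active_ensemble(fit: LERFit) -> np.ndarray:
    """Per-event index of the most recruited ensemble (argmax θ row).

    Ties resolve to the lowest index.
    """
    return np.argmax(fit.theta, axis=1)


def spectrum_features(spectra: SpectrumMatrix) -> np.ndarray:
    """Decoder features: 1/f-corrected power, standardized per bin."""
    power = SpectrumMatrix(values=spectra.values ** 2, freqs=spectra.freqs,
                           frame_indices=spectra.frame_indices)
    corrected = one_over_f_correct(power).values
    mean = corrected.mean(axis=0)
    sd = corrected.std(axis=0)
    return (corrected - mean) / np.where(sd > 0, sd, 1.0)


def decode_from_spectrum(
    spectra: SpectrumMatrix,
    targets: np.ndarray,
    n_estimators: int = 100,
    n_splits: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> DecodeResult:
    """Decode the most active ensemble from per-event LFP power spectra.

    ``spectra`` holds one row per event (the spectrum of the frame the
    event occupies); ``targets`` the ensemble indices.  Classes with fewer
    than 2 events are dropped with a warning; at least two classes must
    survive.  Significance is an exact binomial test of pooled test-set
    hits against the empirical majority-class chance level.
    """
    X = spectrum_features(spectra)
    y = np.asarray(targets)
    if X.shape[0] != y.size:
        raise ValueError("one target per spectrum row required")
    classes, counts = np.unique(y, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        import warnings
        warnings.warn(f"dropping classes with < 2 events: {small.tolist()}")
        keep = ~np.isin(y, small)
        X, y = X[keep], y[keep]
        classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("decoding requires at least two target classes")

    rng = np.random.default_rng(seed)
    n = y.size
    accs = np.empty(n_splits)
    hits = total = 0
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    # stratified splits keep class proportions equal across train and test,
    # so chance-level accuracy is binomial around the empirical frequency
    splitter = StratifiedShuffleSplit(n_splits=n_splits,
                                      test_size=test_fraction,
                                      random_state=int(rng.integers(2 ** 31)))
    for s, (train, test) in enumerate(splitter.split(X, y)):
        rf = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=int(rng.integers(2 ** 31)))
        rf.fit(X[train], y[train])
        pred = rf.predict(X[test])
        accs[s] = (pred == y[test]).mean()
        hits += int((pred == y[test]).sum())
        total += test.size
        for t, p in zip(y[test], pred):
            confusion[cls_index[t], cls_index[p]] += 1

    chance_emp = counts.max() / n
    p = stats.binomtest(hits, total, chance_emp, alternative="greater").pvalue
    return DecodeResult(
        accuracies=accs,
        chance_uniform=1.0 / classes.size,
        chance_empirical=float(chance_emp),
        p_value=float(p),
        confusion=confusion,
        classes=classes,
    )


def population_synchrony(A, labels) -> SynchronyResult:
    """Kendall tau between the two populations' median event-activation vectors.

    ``A`` is an ActivationMatrix (events × cells; the usual input) or a
    ResponseMatrix (cells × events).  For each event the median over each
    population's cells gives two length-M vectors; their Kendall tau is the
    synchrony.  Tau is NaN (reported, not an error) when either median
    vector is constant.
    """
    if isinstance(A, ActivationMatrix):
        mat = A.zprime.T.astype(float)      # cells × events
    elif isinstance(A, ResponseMatrix):
        mat = A.delta
    else:
        mat = np.atleast_2d(np.asarray(A, dtype=float))
    labels = np.asarray(labels, dtype=object)
    if labels.size != mat.shape[0]:
        raise ValueError("one label per cell required")
    abgc = np.asarray([lab == ABGC for lab in labels])
    if abgc.sum() < 2 or (~abgc).sum() < 2:
        raise ValueError("each population needs at least 2 cells")
    med_a = np.median(mat[abgc], axis=0)
    med_m = np.median(mat[~abgc], axis=0)
    if np.unique(med_a).size < 2 or np.unique(med_m).size < 2:
        return SynchronyResult(tau=float("nan"))
    res = stats.kendalltau(med_a, med_m)
    return SynchronyResult(tau=float(res.statistic), p_value=float(res.pvalue))


def compare_synchrony(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U on session-level synchrony values.

    Uses the exact null distribution when both groups are small and
    tie-free (scipy's automatic policy).  Returns (U, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 sessions")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
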