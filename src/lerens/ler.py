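"""Latent Ensemble Recruitment model fitting and ensemble statistics.

The LER model assumes the network consists of K fixed, unobserved cell
ensembles; each detected event recruits a sparse mixture of ensembles, and
each recruited ensemble activates a subset of its cells.  After the
responsiveness matrix is bootstrap-binarized (z′), inference reduces to
Latent Dirichlet Allocation with the analogies ensemble ~ topic,
event ~ document, cell ~ word: each event-document's word multiset is the
set of its active cells (each once, since z′ is binary).  Fitting uses
batch variational Bayes with multiple restarts, keeping the best evidence
lower bound.

Post-hoc ensemble statistics: membership (σ weight > 3/N), pairwise
ensemble overlap (Pearson between σ rows), ensemble-sorted cell–cell
Kendall-tau correlation, and a label-permutation dominance test that calls
an ensemble abGC- or mGC-dominated when its observed lineage count exceeds
the 95th percentile of a size-matched shuffle null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import LatentDirichletAllocation

from .session import ABGC, MGC
from .responsiveness import ActivationMatrix

__all__ = [
    "LERFit",
    "EnsembleSummary",
    "fit_ler",
    "membership",
    "ensemble_overlap",
    "sorted_correlation",
    "dominance_test",
    "dominance_curve",
    "match_ensembles",
]

logger = logging.getLogger(__name__)


@dataclass
class LERFit:
    """Inferred ensemble-over-cell (σ) and event-over-ensemble (θ) vectors."""

    sigma: np.ndarray      # (K, N), rows sum to 1
    theta: np.ndarray      # (M, K), rows sum to 1
    K: int
    elbo: float            # variational bound of the kept restart
    seed: int
    alpha: float
    beta: float
    event_index: np.ndarray | None = None  # rows of z kept (non-empty events)


@dataclass
class EnsembleSummary:
    """Thresholded memberships and dominance statistics of a fit."""

    members: list                 # per-ensemble arrays of cell indices
    dominance: np.ndarray | None = None   # per-ensemble label
    purity: np.ndarray | None = None      # per-ensemble abGC fraction
    overlap: np.ndarray | None = None     # K×K Pearson between σ rows
    shared_counts: np.ndarray | None = None


def _as_z(z) -> np.ndarray:
    zmat = z.zprime if isinstance(z, ActivationMatrix) else np.asarray(z)
    zmat = np.atleast_2d(zmat)
    if not np.isin(zmat, (0, 1)).all():
        raise ValueError("activation matrix must be binary")
    return zmat.astype(float)


def fit_ler(
    z,
    K: int,
    alpha: float | None = None,
    beta: float | None = None,
    seed: int = 0,
    restarts: int = 10,
    max_iter: int = 30,
) -> LERFit:
    """Fit the LER model on a binary activation matrix (events × cells).

    ``alpha`` and ``beta`` default to the symmetric sparse priors 1/K and
    1/N.  Events with no active cell are dropped (logged); ``restarts``
    independent variational fits are run and the best bound kept.  The fit
    never sees lineage labels or event order beyond row identity.
    """
    zmat = _as_z(z)
    M, N = zmat.shape
    if K < 1 or K > N:
        raise ValueError(f"K must lie in [1, N={N}]")
    active = zmat.sum(axis=1) > 0
    if not active.any():
        raise ValueError("activation matrix has no active cells in any event")
    if not active.all():
        logger.info("dropping %d empty events", int((~active).sum()))
    kept = np.flatnonzero(active)
    X = zmat[kept]
    alpha = 1.0 / K if alpha is None else alpha
    beta = 1.0 / N if beta is None else beta

    # events are exchangeable: fit on a canonical (content-sorted) row order
    # so the solver's per-document random initialization cannot leak event
    # order into the result; θ for the caller's order comes from the
    # deterministic E-step afterwards
    canon = np.lexsort(X.T[::-1])
    Xc = X[canon]

    best = None
    seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2 ** 31)
    for rs in seeds:
        lda = LatentDirichletAllocation(
            n_components=K,
            doc_topic_prior=alpha,
            topic_word_prior=beta,
            learning_method="batch",
            max_iter=max_iter,
            random_state=int(rs),
        )
        lda.fit(Xc)
        bound = lda.score(Xc)
        if best is None or bound > best[0]:
            best = (bound, lda)
    bound, lda = best
    theta = lda.transform(X)
    sigma = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    theta = theta / theta.sum(axis=1, keepdims=True)
    return LERFit(sigma=sigma, theta=theta, K=K, elbo=float(bound),
                  seed=seed, alpha=alpha, beta=beta, event_index=kept)


def membership(fit: LERFit, threshold_factor: float = 3.0) -> EnsembleSummary:
    """Cells participating in each ensemble: σ weight strictly > 3/N."""
    N = fit.sigma.shape[1]
    thr = threshold_factor / N
    members = [np.flatnonzero(fit.sigma[k] > thr) for k in range(fit.K)]
    return EnsembleSummary(members=members)


def ensemble_overlap(fit: LERFit, summary: EnsembleSummary | None = None):
    """Pearson correlations between σ rows and pairwise shared-member counts."""
    if fit.K < 2:
        raise ValueError("overlap requires K >= 2")
    overlap = np.corrcoef(fit.sigma)
    if summary is None:
        summary = membership(fit)
    K = fit.K
    shared = np.zeros((K, K), dtype=int)
    for a in range(K):
        for b in range(K):
            shared[a, b] = np.intersect1d(summary.members[a],
                                          summary.members[b]).size
    summary.overlap = overlap
    summary.shared_counts = shared
    return overlap, shared


def kendall_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Kendall tau-b between rows; NaN for constant rows."""
    n = X.shape[0]
    out = np.full((n, n), np.nan)
    const = np.asarray([np.unique(row).size < 2 for row in X])
    for a in range(n):
        if const[a]:
            continue
        out[a, a] = 1.0
        for b in range(a + 1, n):
            if const[b]:
                continue
            tau = stats.kendalltau(X[a], X[b]).statistic
            out[a, b] = out[b, a] = tau
    return out


def sorted_correlation(
    activity: np.ndarray,
    fit: LERFit,
    summary: EnsembleSummary | None = None,
) -> dict:
    """Ensemble-sorted cell–cell Kendall-tau correlation matrix.

    ``activity`` is cells × observations (z′ columns transposed, or ΔF/F).
    Cells are sorted by their strongest ensemble (argmax σ weight, members
    first); returns the sorted matrix, the order, and the within- vs
    between-ensemble mean correlations.
    """
    activity = np.atleast_2d(np.asarray(activity, dtype=float))
    if activity.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    if summary is None:
        summary = membership(fit)
    assign = np.argmax(fit.sigma, axis=0)
    order = np.argsort(assign, kind="stable")
    tau = kendall_matrix(activity)
    sorted_tau = tau[np.ix_(order, order)]

    same = assign[:, None] == assign[None, :]
    off = ~np.eye(activity.shape[0], dtype=bool)
    with np.errstate(invalid="ignore"):
        within = np.nanmean(tau[same & off]) if (same & off).any() else np.nan
        between = np.nanmean(tau[~same]) if (~same).any() else np.nan
    return {
        "matrix": sorted_tau,
        "order": order,
        "assignment": assign,
        "within_mean": float(within),
        "between_mean": float(between),
    }


def dominance_test(
    summary: EnsembleSummary,
    labels,
    n_shuffle: int = 10000,
    seed: int = 0,
    percentile: float = 95.0,
) -> EnsembleSummary:
    """Label-permutation test for lineage-dominated ensembles.

    Ensemble sizes are held fixed; lineage labels are permuted across the
    whole population (counts preserved) ``n_shuffle`` times, building a
    null for the abGC and mGC counts in each size-matched ensemble.  An
    ensemble is abGC-dominated (resp. mGC-dominated) when its observed
    count strictly exceeds the null's 95th percentile; otherwise mixed.
    Empty ensembles are mixed by definition.
    """
    labels = np.asarray(labels, dtype=object)
    N = labels.size
    is_abgc = np.asarray([lab == ABGC for lab in labels])
    rng = np.random.default_rng(seed)
    K = len(summary.members)
    member_mask = np.zeros((K, N), dtype=float)
    for k, mem in enumerate(summary.members):
        member_mask[k, np.asarray(mem, dtype=int)] = 1.0

    perms = np.empty((n_shuffle, N))
    base = is_abgc.astype(float)
    for s in range(n_shuffle):
        perms[s] = rng.permutation(base)
    null_abgc = perms @ member_mask.T               # shuffles × K
    sizes = member_mask.sum(axis=1)
    null_mgc = sizes[None, :] - null_abgc

    obs_abgc = member_mask @ base
    obs_mgc = sizes - obs_abgc
    dominance = np.empty(K, dtype=object)
    purity = np.full(K, np.nan)
    for k in range(K):
        if sizes[k] == 0:
            dominance[k] = "mixed"
            logger.info("ensemble %d empty; mixed by definition", k)
            continue
        purity[k] = obs_abgc[k] / sizes[k]
        q_a = np.percentile(null_abgc[:, k], percentile)
        q_m = np.percentile(null_mgc[:, k], percentile)
        if obs_abgc[k] > q_a:
            dominance[k] = "abGC-dominated"
        elif obs_mgc[k] > q_m:
            dominance[k] = "mGC-dominated"
        else:
            dominance[k] = "mixed"
    summary.dominance = dominance
    summary.purity = purity
    return summary


def match_ensembles(sigma_a: np.ndarray, sigma_b: np.ndarray):
    """Hungarian matching of two σ matrices on Pearson correlation.

    Returns (rows, cols, matched correlations); rows index ``sigma_a``.
    """
    ka, kb = sigma_a.shape[0], sigma_b.shape[0]
    corr = np.empty((ka, kb))
    for a in range(ka):
        for b in range(kb):
            corr[a, b] = np.corrcoef(sigma_a[a], sigma_b[b])[0, 1]
    rows, cols = linear_sum_assignment(-corr)
    return rows, cols, corr[rows, cols]


def dominance_curve(
    z,
    labels,
    K_range,
    fits_per_K: int = 10,
    n_shuffle: int = 2000,
    seed: int = 0,
    restarts: int = 1,
    max_iter: int = 30,
    n_boot: int = 1000,
) -> dict:
    """Dominated-ensemble fractions and max purity as a function of K.

    For each K, ``fits_per_K`` independent model realizations are fit; per
    realization the dominance test labels each ensemble, and the abGC- and
    mGC-dominated fractions and the max per-population purity are recorded.
    Returns per-K means with bootstrap 95% CIs over realizations.
    """
    K_range = list(K_range)
    zmat = _as_z(z)
    N = zmat.shape[1]
    if any(k < 2 or k > N for k in K_range):
        raise ValueError("K_range must lie within [2, N]")
    rng = np.random.default_rng(seed)
    out = {"K": K_range, "abgc_frac": [], "mgc_frac": [],
           "abgc_frac_ci": [], "mgc_frac_ci": [],
           "max_abgc_purity": [], "max_mgc_purity": []}
    for K in K_range:
        fa, fm, pa, pm = [], [], [], []
        for _ in range(fits_per_K):
            fit_seed = int(rng.integers(2 ** 31))
            fit = fit_ler(zmat, K=K, seed=fit_seed, restarts=restarts,
                          max_iter=max_iter)
            summ = membership(fit)
            summ = dominance_test(summ, labels, n_shuffle=n_shuffle,
                                  seed=int(rng.integers(2 ** 31)))
            dom = np.asarray(summ.dominance)
            fa.append(np.mean(dom == "abGC-dominated"))
            fm.append(np.mean(dom == "mGC-dominated"))
            pur = summ.purity[~np.isnan(summ.purity)]
            pa.append(pur.max() if pur.size else np.nan)
            pm.append((1 - pur).max() if pur.size else np.nan)
        out["abgc_frac"].append(float(np.mean(fa)))
        out["mgc_frac"].append(float(np.mean(fm)))
        out["abgc_frac_ci"].append(_boot_ci(fa, rng, n_boot))
        out["mgc_frac_ci"].append(_boot_ci(fm, rng, n_boot))
        out["max_abgc_purity"].append(float(np.nanmean(pa)))
        out["max_mgc_purity"].append(float(np.nanmean(pm)))
    return out


def _boot_ci(vals, rng, n_boot: int = 1000):
    vals = np.asarray(vals, dtype=float)
    if vals.size == 1:
        return (float(vals[0]), float(vals[0]))
    means = np.array([
        rng.choice(vals, size=vals.size, replace=True).mean()
        for _ in range(n_boot)
    ])
    lo, hi = np.percentile(means, [2.5, 97.5])
    return (float(lo), float(hi))
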