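"""Maximum-likelihood admixture model fitting by EM.

Model: individual i carries ancestry proportions ``Q[i]`` over K clusters;
cluster k has insertion frequency ``P[k, l]`` at locus l.  Each of the two
allele copies at a locus independently draws its cluster of origin from
``Q[i]`` and then its allele from that cluster's frequency, so the per-copy
insertion probability is ``sum_k Q[i,k] * P[k,l]``.  The EM updates are the
standard block updates of this likelihood (point estimation, not posterior
sampling); restarts with different seeds guard against local optima.

Model selection across K uses the second-difference statistic
``delta_K = mean(|L(K+1) - 2 L(K) + L(K-1)|) / sd(L(K))`` over restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateSeriesError
from .io_formats import MISSING, GenotypeTable

_P_CLIP = 1e-6  # keeps the log-likelihood finite


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                  # (n, K), rows on the simplex
    P: np.ndarray                  # (K, L) insertion frequencies
    log_likelihood: float
    iterations: int
    converged: bool
    seed: int
    loglik_trace: list[float] = field(default_factory=list)


def _loglik_terms(g: np.ndarray, obs: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    f = Q @ P                                    # (n, L) per-copy insertion prob
    f = np.clip(f, _P_CLIP, 1 - _P_CLIP)
    ll = g * np.log(f) + (2 - g) * np.log(1 - f)
    return float(ll[obs].sum())


def _em(dosage: np.ndarray, Q: np.ndarray, P: np.ndarray, max_iter: int, tol: float,
        update_p: bool) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    obs = dosage != MISSING
    g = np.where(obs, dosage, 0).astype(float)
    gm = np.where(obs, g, 0.0)
    cm = np.where(obs, 2 - g, 0.0)               # deletion-copy counts
    trace = [_loglik_terms(g, obs, Q, P)]
    converged = False
    for _ in range(max_iter):
        P = np.clip(P, _P_CLIP, 1 - _P_CLIP)
        f = np.clip(Q @ P, _P_CLIP, 1 - _P_CLIP)         # (n, L)
        # responsibilities: r1[i,k,l] = Q[i,k] P[k,l] / f[i,l] for insertion copies
        ins_w = gm / f                                   # (n, L)
        del_w = cm / (1 - f)
        # expected copies from cluster k: per individual
        e_ins = (ins_w @ P.T) * Q                        # (n, K)
        e_del = (del_w @ (1 - P).T) * Q
        Q_new = e_ins + e_del
        # renormalize explicitly: P clipping can push row sums off 1, which
        # otherwise compounds across iterations
        Q_new /= np.maximum(Q_new.sum(axis=1, keepdims=True), 1e-300)
        if update_p:
            # expected insertion copies attributed to cluster k at locus l:
            #   sum_i Q[i,k] P[k,l] * g[i,l] / f[i,l]
            num = (Q.T @ ins_w) * P
            den = num + (Q.T @ del_w) * (1 - P)
            with np.errstate(invalid="ignore", divide="ignore"):
                P_new = np.where(den > 0, num / den, P)
            P = np.clip(P_new, _P_CLIP, 1 - _P_CLIP)
        Q = Q_new
        ll = _loglik_terms(g, obs, Q, P)
        trace.append(ll)
        if abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return Q, P, trace, converged


def fit_admixture(table: GenotypeTable, K: int, seed: int = 0, max_iter: int = 1000,
                  tol: float = 1e-6, restarts: int = 10) -> AdmixtureFit:
    """Fit Q and P at fixed K by EM from seeded random restarts.

    The best-log-likelihood restart is returned.  ``K=1`` is allowed for
    delta-K series: Q is a column of ones and P the pooled frequencies.
    """
    n = table.n_samples
    if K < 1:
        raise ConfigError("K must be >= 1")
    if K > n:
        raise ConfigError(f"K={K} exceeds the number of individuals ({n})")
    dosage = table.dosage
    if K == 1:
        p = np.clip(table.insertion_frequencies(), _P_CLIP, 1 - _P_CLIP)[None, :]
        Q = np.ones((n, 1))
        obs = dosage != MISSING
        g = np.where(obs, dosage, 0).astype(float)
        ll = _loglik_terms(g, obs, Q, p)
        return AdmixtureFit(1, Q, p, ll, 0, True, seed, [ll])

    rng = np.random.default_rng(seed)
    best: AdmixtureFit | None = None
    for _ in range(restarts):
        Q0 = rng.dirichlet(np.ones(K), size=n)
        P0 = rng.uniform(0.05, 0.95, size=(K, table.n_loci))
        Q, P, trace, conv = _em(dosage, Q0, P0, max_iter, tol, update_p=True)
        fit = AdmixtureFit(K, Q, P, trace[-1], len(trace) - 1, conv, seed, trace)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


def fit_supervised_q(dosages: np.ndarray, reference_P: np.ndarray, seed: int = 0,
                     max_iter: int = 2000, tol: float = 1e-8) -> np.ndarray:
    """EM over a single individual's Q with cluster frequencies fixed.

    ``dosages``: (L,) insertion dosages (MISSING skipped); ``reference_P``:
    (K, L).  Returns the converged Q row on the simplex.
    """
    d = np.asarray(dosages, dtype=float)[None, :]
    P = np.clip(np.asarray(reference_P, dtype=float), _P_CLIP, 1 - _P_CLIP)
    K = P.shape[0]
    rng = np.random.default_rng(seed)
    Q0 = rng.dirichlet(np.ones(K), size=1)
    Q, _, _, _ = _em(d.astype(np.int16), Q0, P, max_iter, tol, update_p=False)
    return Q[0]


def supervised_components(table: GenotypeTable, reference_P: np.ndarray,
                          seed: int = 0) -> np.ndarray:
    """Supervised Q rows for every individual in ``table`` (n, K)."""
    return np.vstack([fit_supervised_q(table.dosage[i], reference_P, seed)
                      for i in range(table.n_samples)])


def fit_supervised_group_q(table: GenotypeTable, reference_P: np.ndarray,
                           seed: int = 0, max_iter: int = 5000,
                           tol: float = 1e-10) -> np.ndarray:
    """Population-level supervised ancestry: one shared Q for a whole group.

    Maximizes the joint likelihood of every individual's genotypes under a
    single ancestry vector.  Preferable to averaging per-individual ML
    estimates when the panel is small: individual estimates sit against the
    simplex boundary and their mean is biased toward the interior, while the
    pooled estimate concentrates with total allele-copy count.
    """
    flat = np.asarray(table.dosage).reshape(-1)
    tiled = np.tile(np.asarray(reference_P, dtype=float), (1, table.n_samples))
    return fit_supervised_q(flat, tiled, seed=seed, max_iter=max_iter, tol=tol)


def population_components(fit: AdmixtureFit, labels) -> pd.DataFrame:
    """Mean Q vector per population label (rows sum to 1)."""
    labels = list(labels)
    if len(labels) != fit.Q.shape[0]:
        raise ValueError("labels length mismatch with Q rows")
    df = pd.DataFrame(fit.Q, columns=[f"cluster_{k+1}" for k in range(fit.K)])
    df["population"] = labels
    return df.groupby("population", sort=False).mean()


def align_clusters(reference_P: np.ndarray, P: np.ndarray) -> list[int]:
    """Greedy cluster matching on P-vector correlation.

    Returns a permutation ``perm`` such that ``P[perm[k]]`` corresponds to
    ``reference_P[k]``; used to undo label switching across runs/K values.
    """
    K = reference_P.shape[0]
    corr = np.corrcoef(np.vstack([reference_P, P]))[:K, K:]
    perm = [-1] * K
    used: set[int] = set()
    for k in sorted(range(K), key=lambda k: -np.nanmax(corr[k])):
        order = np.argsort(-corr[k])
        for j in order:
            if j not in used:
                perm[k] = int(j)
                used.add(int(j))
                break
    return perm


@dataclass
class RunSeries:
    """Log-likelihoods of independent restarts across a range of K."""

    logliks: dict[int, list[float]]  # K -> one value per restart

    def delta_k(self) -> pd.Series:
        return evanno_delta_k(self)


def run_series(table: GenotypeTable, k_values, seed: int = 0, restarts: int = 5,
               max_iter: int = 500, tol: float = 1e-5) -> RunSeries:
    """Independent single-start fits per (K, restart) for delta-K selection."""
    rng = np.random.default_rng(seed)
    out: dict[int, list[float]] = {}
    for K in k_values:
        vals = []
        for _ in range(restarts):
            fit = fit_admixture(table, K, seed=int(rng.integers(2 ** 31)),
                                max_iter=max_iter, tol=tol, restarts=1)
            vals.append(fit.log_likelihood)
        out[K] = vals
    return RunSeries(out)


def evanno_delta_k(series: RunSeries) -> pd.Series:
    """Second-difference statistic per interior K.

    ``delta_K = mean_r |L_r(K+1) - 2 L_r(K) + L_r(K-1)| / sd(L(K))`` where the
    mean runs over restarts r and sd is the sample standard deviation of the
    restarts at K.  Requires both neighbors; sd = 0 raises.
    """
    ks = sorted(series.logliks)
    out = {}
    for K in ks:
        if K - 1 not in series.logliks or K + 1 not in series.logliks:
            continue
        lo = np.asarray(series.logliks[K - 1], dtype=float)
        mid = np.asarray(series.logliks[K], dtype=float)
        hi = np.asarray(series.logliks[K + 1], dtype=float)
        if not (len(lo) == len(mid) == len(hi)):
            raise ValueError("restart counts differ across K")
        sd = mid.std(ddof=1) if len(mid) > 1 else 0.0
        if sd == 0:
            raise DegenerateSeriesError(f"zero restart spread at K={K}")
        out[K] = float(np.abs(hi - 2 * mid + lo).mean() / sd)
    return pd.Series(out, name="delta_k")
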