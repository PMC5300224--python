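"""Maximum-likelihood admixture estimation.

Model: individual i's genotype at SNP j counts copies of allele 1 and is
Binomial(2, pi_ij) with pi_ij = sum_k q_ik f_kj, where Q = {q_ik} are
per-individual ancestry fractions (rows on the k-simplex) and F = {f_kj}
per-population allele frequencies.  The log-likelihood over unrelated
individuals and loci in linkage equilibrium is

    L(Q, F) = sum_ij { g_ij ln(pi_ij) + (2 - g_ij) ln(1 - pi_ij) }

maximized by monotone EM block updates over Q and F.  EM is a block
relaxation scheme: every iteration weakly increases L, which the test suite
exploits as an invariant.  Convergence is declared on an absolute
log-likelihood change below ``tol`` (default 1e-6).

Missing genotypes contribute nothing to the likelihood or to the update
sums; each individual's Q update normalizes by its own non-missing locus
count.  Model order k is chosen by masked-entry cross-validation: held-out
genotype entries are scored by binomial deviance against 2 * Q F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError
from .genotype_core import (
    MISSING,
    AlleleFrequencySet,
    GenotypeMatrix,
    allele1_frequency,
)
from .popgen_stats import pairwise_fst

EPS = 1e-6  # boundary clamp for f and q


@dataclass
class FitResult:
    q_hat: np.ndarray
    f_hat: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


def _as_dosage(g) -> np.ndarray:
    return g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g)


def _masked(g) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (G1, G2, obs): allele-1 copies, allele-2 copies, non-missing
    mask, with missing entries zeroed so they drop out of every sum."""
    d = _as_dosage(g)
    obs = d != MISSING
    g1 = np.where(obs, d, 0).astype(float)
    g2 = np.where(obs, 2 - d, 0).astype(float)
    return g1, g2, obs


def _check_dims(d: np.ndarray, q: np.ndarray, f: np.ndarray) -> None:
    if q.shape[0] != d.shape[0] or f.shape[1] != d.shape[1]:
        raise DimensionError("Q/F dimensions do not match the genotype matrix")
    if q.shape[1] != f.shape[0]:
        raise DimensionError("Q and F disagree on the number of populations k")


def admixture_loglik(g, q: np.ndarray, f: np.ndarray) -> float:
    """Exact binomial-mixture log-likelihood over non-missing entries.

    Boundary evaluations (mixture probability 0 with a positive count)
    return -inf rather than raising.
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    f = np.atleast_2d(np.asarray(f, dtype=float))
    g1, g2, _ = _masked(g)
    _check_dims(_as_dosage(g), q, f)
    pi = q @ f
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(g1 > 0, g1 * np.log(pi), 0.0)
        t2 = np.where(g2 > 0, g2 * np.log(1.0 - pi), 0.0)
    return float(np.sum(t1) + np.sum(t2))


def em_step(
    g, q: np.ndarray, f: np.ndarray, eps: float = EPS
) -> tuple[np.ndarray, np.ndarray]:
    """One EM block update of (Q, F); weakly increases the log-likelihood.

    Responsibilities attribute each allele-1 copy to population k with
    weight q_ik f_kj / pi_ij and each allele-2 copy with weight
    q_ik (1 - f_kj) / (1 - pi_ij).  Q rows average the responsibilities over
    the individual's non-missing copies; F entries take the allele-1 share
    of the copies attributed to population k.  An emptied population's
    frequency update is undefined and is clamped to [eps, 1 - eps].
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    f = np.atleast_2d(np.asarray(f, dtype=float))
    d = _as_dosage(g)
    _check_dims(d, q, f)
    g1, g2, obs = _masked(g)
    n_copies = 2.0 * obs.sum(axis=1, keepdims=True).astype(float)
    q_new, f_new, _ = _em_core(g1, g2, n_copies, q, f, eps)
    return q_new, f_new


def _em_core(
    g1: np.ndarray,
    g2: np.ndarray,
    n_copies: np.ndarray,
    q: np.ndarray,
    f: np.ndarray,
    eps: float = EPS,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fused EM update; returns (q', f', log-likelihood at the input state)."""
    pi = q @ f
    np.clip(pi, eps, 1.0 - eps, out=pi)
    one_m_pi = 1.0 - pi
    ll = float(
        np.einsum("ij,ij->", g1, np.log(pi))
        + np.einsum("ij,ij->", g2, np.log(one_m_pi))
    )

    w1 = g1 / pi          # I x J
    w2 = g2 / one_m_pi
    one_m_f = 1.0 - f

    # per-individual responsibility sums: sum_j (a_ijk + b_ijk)
    a_sum = q * (w1 @ f.T)
    b_sum = q * (w2 @ one_m_f.T)
    with np.errstate(invalid="ignore", divide="ignore"):
        q_new = (a_sum + b_sum) / n_copies
    q_new[np.isnan(q_new)] = 1.0 / q.shape[1]  # all-missing individual
    q_new = np.clip(q_new, eps, None)
    q_new /= q_new.sum(axis=1, keepdims=True)

    # per-population frequency updates: sum_i a_ijk / sum_i (a_ijk + b_ijk)
    a_num = f * (q.T @ w1)            # k x J
    b_num = one_m_f * (q.T @ w2)
    denom = a_num + b_num
    with np.errstate(invalid="ignore", divide="ignore"):
        f_new = a_num / denom
    f_new[~np.isfinite(f_new)] = 0.5  # empty population at this locus
    f_new = np.clip(f_new, eps, 1.0 - eps)
    return q_new, f_new, ll


def _init_state(
    d: np.ndarray, k: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n = d.shape[0]
    q = rng.dirichlet(np.ones(k), size=n)
    q = np.clip(q, EPS, None)
    q /= q.sum(axis=1, keepdims=True)
    base = allele1_frequency(d)
    base = np.where(np.isnan(base), 0.5, base)
    f = base[None, :] + rng.uniform(-0.05, 0.05, size=(k, d.shape[1]))
    f = np.clip(f, EPS, 1.0 - EPS)
    return q, f


def fit_admixture(
    g,
    k: int,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_starts: int = 5,
    seed: int = 0,
    supervised_labels=None,
) -> FitResult:
    """Fit the admixture model by EM; best of ``n_starts`` random starts.

    ``supervised_labels`` (optional) is a length-I array with a population
    index in 0..k-1 for reference purebreds and -1 (or None entries) for
    samples left free; fixed rows are pinned to near-unit ancestry vectors
    after every update.  Deterministic for fixed seed and data.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    d = _as_dosage(g)
    fixed_idx = fixed_q = None
    if supervised_labels is not None:
        lab = np.array(
            [-1 if v is None else int(v) for v in supervised_labels]
        )
        if lab.shape[0] != d.shape[0]:
            raise DimensionError("supervised_labels length != sample count")
        fixed_idx = (lab >= 0).nonzero()[0]
        fixed_q = np.full((len(fixed_idx), k), EPS)
        fixed_q[np.arange(len(fixed_idx)), lab[fixed_idx]] = 1.0 - (k - 1) * EPS

    g1, g2, obs = _masked(d)
    n_copies = 2.0 * obs.sum(axis=1, keepdims=True).astype(float)

    best: FitResult | None = None
    for s in range(n_starts):
        rng = np.random.default_rng([seed, s])
        q, f = _init_state(d, k, rng)
        if fixed_idx is not None:
            q[fixed_idx] = fixed_q
        trace: list[float] = []
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            q, f, ll = _em_core(g1, g2, n_copies, q, f)
            if fixed_idx is not None:
                q[fixed_idx] = fixed_q
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
                converged = True
                break
        trace.append(admixture_loglik(d, q, f))  # final-state likelihood
        res = FitResult(q, f, trace, converged, it)
        if best is None or res.loglik > best.loglik:
            best = res
    return best


def cross_validate_k(
    g,
    k_range=range(1, 6),
    folds: int = 5,
    tol: float = 1e-4,
    seed: int = 0,
    n_starts: int = 1,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Masked-entry cross-validation over model order k.

    Non-missing genotype entries are partitioned at random into ``folds``
    folds; each fold is masked in turn, the model refit, and the held-out
    entries scored by mean binomial deviance between g and the fitted
    2 * Q F.  Returns a DataFrame (k, fold, n_masked, deviance) plus the
    per-k mean accessible via ``groupby``.
    """
    d = _as_dosage(g).copy()
    obs_idx = np.argwhere(d != MISSING)
    if len(obs_idx) < folds:
        raise ParameterError("fewer non-missing entries than folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(obs_idx))
    rows = []
    for k in k_range:
        for fold in range(folds):
            held = obs_idx[perm[fold::folds]]
            masked = d.copy()
            masked[held[:, 0], held[:, 1]] = MISSING
            fit = fit_admixture(
                masked,
                k,
                tol=tol,
                max_iter=max_iter,
                n_starts=n_starts,
                seed=seed + 1000 * k + fold,
            )
            pi = np.clip(fit.q_hat @ fit.f_hat, EPS, 1.0 - EPS)
            gv = d[held[:, 0], held[:, 1]].astype(float)
            pv = pi[held[:, 0], held[:, 1]]
            dev = -(gv * np.log(pv) + (2.0 - gv) * np.log(1.0 - pv))
            rows.append(
                {
                    "k": int(k),
                    "fold": fold,
                    "n_masked": len(held),
                    "deviance": float(dev.mean()),
                }
            )
    return pd.DataFrame(rows)


def cv_error_by_k(cv_table: pd.DataFrame) -> pd.Series:
    """Per-k mean held-out deviance from a cross_validate_k table."""
    return cv_table.groupby("k")["deviance"].mean()


def inferred_pop_fst(f_hat) -> np.ndarray:
    """Pairwise Wright F_st between inferred population frequency vectors."""
    f = f_hat.freqs if isinstance(f_hat, AlleleFrequencySet) else np.atleast_2d(f_hat)
    k = f.shape[0]
    if k < 2:
        raise ParameterError("need k >= 2 populations")
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            out[a, b] = out[b, a] = pairwise_fst(f[a], f[b])
    return out
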