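"""Bayesian ancestry estimation by Gibbs sampling (admixture model).

The model augments the binomial admixture likelihood with latent origins
z_l^(i,a) in 1..k for each allele copy a of individual i at locus l:

    Pr(x_l^(i,a) = allele | z, P) given by the origin population's allele
    frequency p_{k l}, and Pr(z_l^(i,a) = k) = q_k^(i).

Priors are conjugate: p_{k l} ~ Beta(lambda, lambda) and q^(i) ~
Dirichlet(alpha, ..., alpha).  A Gibbs sweep cycles the full conditionals:

  * z: each allele-1 copy at (i, l) joins population k with probability
    proportional to q_ik p_kl (allele-2 copies use 1 - p_kl); copies of the
    same allele within a genotype are exchangeable, so their origins are
    drawn as a conditional multinomial count vector, which is identical in
    law to sampling each copy separately.
  * p: Beta(lambda + allele-1 copies assigned to k, lambda + allele-2
    copies assigned to k), per population and locus.
  * q: Dirichlet(alpha + per-population copy counts of individual i).

Assumptions match the likelihood model: Hardy-Weinberg equilibrium within
populations and linkage equilibrium between loci (uniform recombination, no
linkage model).  Posterior means over post-burn-in sweeps summarize Q and P.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .ancestry_ml import admixture_loglik
from .errors import DimensionError, ParameterError
from .genotype_core import MISSING, GenotypeMatrix, allele1_frequency

_FLOOR = 1e-12


@dataclass
class PosteriorSummary:
    q_mean: np.ndarray
    p_mean: np.ndarray
    n_sweeps: int
    burn_in: int
    loglik_trace: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.n_sweeps - self.burn_in


def _as_dosage(g) -> np.ndarray:
    return g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g)


def _sample_origin_counts(
    n: np.ndarray, w: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial counts over k populations for each (i, j) cell.

    ``n`` (I x J) copies to assign, ``w`` (I x J x k) unnormalized weights.
    Sequential conditional-binomial splitting, vectorized over cells.
    """
    k = w.shape[2]
    rem = n.astype(np.int64)
    wrem = np.maximum(w.sum(axis=2), _FLOOR)
    out = np.zeros(w.shape, dtype=np.int64)
    for kk in range(k - 1):
        pk = np.clip(w[:, :, kk] / wrem, 0.0, 1.0)
        draw = rng.binomial(rem, pk)
        out[:, :, kk] = draw
        rem = rem - draw
        wrem = np.maximum(wrem - w[:, :, kk], _FLOOR)
    out[:, :, k - 1] = rem
    return out


def gibbs_sweep(
    g,
    z: tuple[np.ndarray, np.ndarray] | None,
    p: np.ndarray,
    q: np.ndarray,
    alpha: float,
    lam: float,
    rng: np.random.Generator,
) -> tuple[tuple[np.ndarray, np.ndarray], np.ndarray, np.ndarray]:
    """One full conditional update cycle; returns (z, p, q).

    ``z`` is carried as a pair of count arrays ``(a, b)`` of shape
    (I, J, k): a[i, j, k] allele-1 copies of (i, j) assigned to population
    k, b likewise for allele-2 copies.  Missing genotypes have zero copies.
    """
    if alpha <= 0 or lam <= 0:
        raise ParameterError("alpha and lambda must be positive")
    d = _as_dosage(g)
    q = np.atleast_2d(np.asarray(q, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    k = q.shape[1]
    if p.shape[0] != k or p.shape[1] != d.shape[1] or q.shape[0] != d.shape[0]:
        raise DimensionError("state dimensions inconsistent with genotypes")

    obs = d != MISSING
    g1 = np.where(obs, d, 0)
    g2 = np.where(obs, 2 - d, 0)

    # z | p, q  -- weights q_ik * p_kj (allele 1) and q_ik * (1 - p_kj)
    w1 = np.maximum(q[:, None, :] * p.T[None, :, :], 0.0) + _FLOOR
    w2 = np.maximum(q[:, None, :] * (1.0 - p).T[None, :, :], 0.0) + _FLOOR
    a = _sample_origin_counts(g1, w1, rng)
    b = _sample_origin_counts(g2, w2, rng)

    # p | z  -- conjugate Beta per population and locus
    n1 = a.sum(axis=0).T  # k x J
    n2 = b.sum(axis=0).T
    p_new = rng.beta(lam + n1, lam + n2)
    p_new = np.clip(p_new, _FLOOR, 1.0 - _FLOOR)

    # q | z  -- conjugate Dirichlet per individual
    counts = (a + b).sum(axis=1)  # I x k
    gam = np.maximum(rng.gamma(alpha + counts), _FLOOR)  # guard underflow at 0
    q_new = gam / gam.sum(axis=1, keepdims=True)
    return (a, b), p_new, q_new


def _update_alpha(
    alpha: float,
    q: np.ndarray,
    rng: np.random.Generator,
    proposal_sd: float = 0.25,
    alpha_max: float = 10.0,
) -> float:
    """Metropolis step for the Dirichlet concentration alpha.

    Uniform(0, alpha_max] prior; symmetric normal random-walk proposal.
    The conditional likelihood is the product of symmetric Dirichlet(alpha)
    densities at the current q rows.
    """
    import math

    def logpost(a: float) -> float:
        I, k = q.shape
        return I * (math.lgamma(k * a) - k * math.lgamma(a)) + (
            a - 1.0
        ) * float(np.log(q).sum())

    prop = alpha + rng.normal(0.0, proposal_sd)
    if prop <= 0.0 or prop > alpha_max:
        return alpha
    if math.log(rng.random() + _FLOOR) < logpost(prop) - logpost(alpha):
        return prop
    return alpha


def fit_structure(
    g,
    k: int,
    n_iter: int = 30_000,
    burn_in: int = 10_000,
    alpha: float = 1.0,
    lam: float = 1.0,
    seed: int = 0,
    update_alpha: bool = False,
) -> PosteriorSummary:
    """Run the Gibbs sampler and return posterior means over retained sweeps.

    Defaults use 30,000 sweeps with a 10,000-sweep burn-in; both are
    configurable (the test suite runs much shorter chains).  No thinning:
    the posterior mean averages every retained sweep.  The returned trace is
    the data log-likelihood at each retained state.

    ``update_alpha`` adds a Metropolis step inferring the Dirichlet
    concentration from the data (off by default, where ``alpha`` stays
    fixed).  A fixed alpha of 1 shrinks corner (purebred) ancestries toward
    the interior of the simplex; inferring alpha largely removes that
    shrinkage.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if n_iter <= burn_in:
        raise ParameterError("n_iter must exceed burn_in")
    d = _as_dosage(g)
    rng = np.random.default_rng(seed)

    q = np.full((d.shape[0], k), 1.0 / k)
    base = allele1_frequency(d)
    base = np.where(np.isnan(base), 0.5, base)
    p = np.clip(
        base[None, :] + rng.uniform(-0.05, 0.05, size=(k, d.shape[1])),
        0.01,
        0.99,
    )

    q_acc = np.zeros_like(q)
    p_acc = np.zeros_like(p)
    trace = np.empty(n_iter - burn_in)
    z = None
    for sweep in range(n_iter):
        z, p, q = gibbs_sweep(d, z, p, q, alpha, lam, rng)
        if update_alpha:
            alpha = _update_alpha(alpha, q, rng)
        if sweep >= burn_in:
            q_acc += q
            p_acc += p
            trace[sweep - burn_in] = admixture_loglik(d, q, p)
    n_ret = n_iter - burn_in
    return PosteriorSummary(
        q_mean=q_acc / n_ret,
        p_mean=p_acc / n_ret,
        n_sweeps=n_iter,
        burn_in=burn_in,
        loglik_trace=trace,
    )


def align_labels(q_a: np.ndarray, q_b_or_refs) -> tuple[int, ...]:
    """Permutation resolving label switching between two ancestry matrices.

    Returns the column permutation ``perm`` such that ``q_b[:, perm]`` best
    matches ``q_a`` under the total matched-column product
    sum_c sum_i q_a[i, c] * q_b[i, perm[c]], by exhaustive search (k <= 8).
    ``q_b_or_refs`` may also be an integer label vector (one population per
    sample), which is expanded to one-hot rows.
    """
    q_a = np.atleast_2d(np.asarray(q_a, dtype=float))
    q_b = np.asarray(q_b_or_refs)
    if q_b.ndim == 1:
        labels = q_b.astype(int)
        onehot = np.zeros((len(labels), q_a.shape[1]))
        onehot[np.arange(len(labels)), labels] = 1.0
        q_b = onehot
    q_b = np.atleast_2d(q_b.astype(float))
    k = q_a.shape[1]
    if q_b.shape[1] != k:
        raise DimensionError("ancestry matrices disagree on k")
    if q_a.shape[0] != q_b.shape[0]:
        raise DimensionError("ancestry matrices disagree on sample count")
    if k > 8:
        raise ParameterError("exhaustive alignment supported for k <= 8")
    cross = q_a.T @ q_b  # k x k agreement scores
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(k)):
        score = sum(cross[c, perm[c]] for c in range(k))
        if score > best_score:
            best_perm, best_score = perm, score
    return best_perm


def aligned_q(q_a: np.ndarray, q_b: np.ndarray) -> np.ndarray:
    """``q_b`` with columns permuted to match ``q_a``."""
    perm = align_labels(q_a, q_b)
    return np.atleast_2d(np.asarray(q_b, dtype=float))[:, list(perm)]
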