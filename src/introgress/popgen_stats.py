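"""Population-genetic summary statistics: heterozygosity, exact HWE testing,
pairwise F_st, the genomic relationship matrix, PCA and outlier exclusion."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedStatisticError
from .genotype_core import MISSING, GenotypeMatrix, allele1_frequency


@dataclass
class HetSummary:
    """Per-SNP and per-group heterozygosity.

    ``per_snp`` maps each group to a DataFrame with columns ``snp_id``,
    ``exp_het`` (2p(1-p)) and ``obs_het`` (heterozygote fraction among
    non-missing genotypes); ``summary`` holds per-group mean, SD and median
    of both, computed over SNPs with defined values.
    """

    per_snp: dict
    summary: pd.DataFrame


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    coords: np.ndarray
    sample_ids: list | None = None

    @property
    def n_components(self) -> int:
        return self.coords.shape[1]


def heterozygosity(g: GenotypeMatrix, by_group: bool = True) -> HetSummary:
    """Expected (2p(1-p)) and observed heterozygosity, per group.

    All-missing SNPs within a group are excluded from the summaries.
    """
    groups = list(dict.fromkeys(g.groups)) if by_group else ["ALL"]
    per_snp = {}
    rows = []
    for grp in groups:
        idx = (
            (g.groups == grp).nonzero()[0]
            if by_group
            else np.arange(g.n_samples)
        )
        d = g.dosage[idx]
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        p = allele1_frequency(d)
        with np.errstate(invalid="ignore", divide="ignore"):
            exp_het = 2.0 * p * (1.0 - p)
            obs_het = ((d == 1) & obs).sum(axis=0) / n_obs
        df = pd.DataFrame(
            {"snp_id": g.snps["snp_id"], "exp_het": exp_het, "obs_het": obs_het}
        )
        per_snp[str(grp)] = df
        ok = ~np.isnan(p)
        rows.append(
            {
                "group": str(grp),
                "n_snps": int(ok.sum()),
                "exp_mean": float(np.nanmean(exp_het[ok])) if ok.any() else np.nan,
                "exp_sd": float(np.nanstd(exp_het[ok])) if ok.any() else np.nan,
                "exp_median": float(np.nanmedian(exp_het[ok])) if ok.any() else np.nan,
                "obs_mean": float(np.nanmean(obs_het[ok])) if ok.any() else np.nan,
                "obs_sd": float(np.nanstd(obs_het[ok])) if ok.any() else np.nan,
                "obs_median": float(np.nanmedian(obs_het[ok])) if ok.any() else np.nan,
            }
        )
    return HetSummary(per_snp, pd.DataFrame(rows))


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts (same parity as the observed one) whose probability
    does not exceed the observed count's probability.
    """
    n_hom1, n_het, n_hom2 = int(n_hom1), int(n_het), int(n_hom2)
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise UndefinedStatisticError("all genotype counts are zero")
    n1 = 2 * n_hom1 + n_het  # allele-1 copies
    n2 = 2 * n - n1
    rare = min(n1, n2)
    if rare == 0:
        return 1.0
    hets = np.arange(rare % 2, rare + 1, 2)
    # log of unnormalized P(h) = 2^h * n! / (hom1(h)! h! hom2(h)!), with the
    # constant factors dropped (they cancel in the normalization)
    logw = (
        hets * math.log(2.0)
        - np.array([math.lgamma((n1 - h) / 2 + 1) for h in hets])
        - np.array([math.lgamma(h + 1) for h in hets])
        - np.array([math.lgamma((n2 - h) / 2 + 1) for h in hets])
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    obs_h = n_het
    p_obs = probs[np.searchsorted(hets, obs_h)]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def pairwise_fst(
    freqs_a, freqs_b, weights=None, estimator: str = "wright"
) -> float:
    """Pairwise F_st from two per-SNP allele-frequency vectors.

    The primary (``"wright"``) definition is the ratio-of-averages Wright
    estimator: sum_j (p_a - p_b)^2 / 4 divided by sum_j pbar (1 - pbar),
    with pbar the midpoint frequency, clamped to [0, 1].  ``"hudson"``
    divides by the average between-population heterozygosity instead.
    """
    pa = np.asarray(freqs_a, dtype=float).ravel()
    pb = np.asarray(freqs_b, dtype=float).ravel()
    if pa.shape != pb.shape:
        raise ParameterError("frequency vectors must have the same length")
    ok = ~(np.isnan(pa) | np.isnan(pb))
    pa, pb = pa[ok], pb[ok]
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()[ok]
    else:
        w = np.ones_like(pa)
    diff2 = (pa - pb) ** 2
    if estimator == "wright":
        pbar = 0.5 * (pa + pb)
        denom = float(np.sum(w * pbar * (1.0 - pbar)))
        num = float(np.sum(w * diff2 / 4.0))
    elif estimator == "hudson":
        denom = float(np.sum(w * (pa * (1 - pb) + pb * (1 - pa))))
        num = float(np.sum(w * diff2))
    else:
        raise ParameterError(f"unknown estimator {estimator!r}")
    if denom <= 0:
        raise UndefinedStatisticError("no polymorphic loci: F_st undefined")
    return float(np.clip(num / denom, 0.0, 1.0))


def grm(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Missing dosages are imputed with the per-SNP mean; monomorphic SNPs are
    dropped.  G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the centered dosage.
    """
    if g.n_samples < 2:
        raise ParameterError("need at least 2 samples")
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    p = allele1_frequency(g.dosage)
    poly = ~np.isnan(p) & (p > 0) & (p < 1)
    if not poly.any():
        raise UndefinedStatisticError("no polymorphic SNPs: GRM undefined")
    d = d[:, poly]
    p = p[poly]
    col_mean = 2.0 * p
    nan_mask = np.isnan(d)
    d[nan_mask] = np.broadcast_to(col_mean, d.shape)[nan_mask]
    z = d - col_mean
    scale = 2.0 * np.sum(p * (1.0 - p))
    G = (z @ z.T) / scale
    return 0.5 * (G + G.T)  # enforce exact symmetry against rounding


def pca_project(G: np.ndarray, n_components: int) -> PcaResult:
    """Eigendecomposition of a relationship matrix.

    Components are ordered by decreasing eigenvalue; sample coordinates are
    eigenvectors scaled by sqrt(max(eigenvalue, 0)).  The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ParameterError("relationship matrix must be square")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ParameterError("relationship matrix must be symmetric")
    if n_components > G.shape[0]:
        raise ParameterError("n_components exceeds sample count")
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:n_components]
    vals = vals[order]
    vecs = vecs[:, order]
    for c in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, c]))
        if vecs[i, c] < 0:
            vecs[:, c] = -vecs[:, c]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    return PcaResult(eigenvalues=vals, coords=coords)


def pca_outlier_filter(
    coords: PcaResult | np.ndarray,
    labels,
    n_sd: float = 3.0,
    components: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass removal of samples far from their group's PCA centroid.

    Distance is the Euclidean norm of per-component robust z-scores (median
    centroid, MAD-based scale) over the first ``components`` PCs; samples
    with distance > ``n_sd`` are removed.  Groups with fewer than 3 samples
    are skipped with a warning.  Returns (kept_indices, removed_indices).
    """
    X = coords.coords if isinstance(coords, PcaResult) else np.asarray(coords)
    X = X[:, :components]
    labels = np.asarray(labels)
    removed = np.zeros(len(labels), dtype=bool)
    for grp in dict.fromkeys(labels):
        idx = (labels == grp).nonzero()[0]
        if len(idx) < 3:
            warnings.warn(
                f"group {grp!r} has fewer than 3 samples; outlier filter skipped",
                stacklevel=2,
            )
            continue
        sub = X[idx]
        center = np.median(sub, axis=0)
        mad = np.median(np.abs(sub - center), axis=0)
        scale = np.maximum(1.4826 * mad, 1e-12)
        z = (sub - center) / scale
        dist = np.sqrt((z**2).sum(axis=1))
        removed[idx[dist > n_sd]] = True
    return (~removed).nonzero()[0], removed.nonzero()[0]
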