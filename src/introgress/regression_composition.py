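"""Breed composition by regression on reference allele frequencies.

Each sample's genotypes (allele-1 copies divided by 2, giving 0, 0.5 or 1)
are regressed on the reference breeds' allele-frequency vectors:
y = X beta + e, the slope(s) beta read as percentage breed contributions.
Two fitting modes are provided because the single-column X description
admits both readings:

  * ``per-breed`` (default): one simple least-squares regression of y on
    each breed's frequency vector, with an intercept; the slope is that
    breed's raw coefficient.
  * ``joint``: one multiple regression on all breed columns, no intercept.

Raw coefficients are then clipped to [0, 1] (negative -> 0, above 1 -> 1)
and renormalized by their sum so the composition lies on the simplex.  If
every coefficient clips to zero the composition is flagged undefined rather
than silently made uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError, ParameterError
from .genotype_core import MISSING, AlleleFrequencySet, GenotypeMatrix


@dataclass
class RegressionFit:
    raw_beta: np.ndarray
    clipped_beta: np.ndarray
    composition: np.ndarray  # NaN vector when undefined
    breeds_used: list[str]
    mode: str
    n_snps_used: int

    @property
    def defined(self) -> bool:
        return not np.any(np.isnan(self.composition))


def transform_genotypes(g) -> np.ndarray:
    """Allele-1 dosage / 2 -> values in {0, 0.5, 1}; missing becomes NaN."""
    d = g.dosage if isinstance(g, GenotypeMatrix) else np.asarray(g)
    y = d.astype(float) / 2.0
    y[d == MISSING] = np.nan
    return y


def renormalize_coefficients(raw_beta) -> tuple[np.ndarray, np.ndarray]:
    """Clip raw coefficients to [0, 1] and renormalize to the simplex.

    Negative values are coded as 0 and values above 1 as 1; the clipped
    vector is then divided by its sum.  If every coefficient clips to zero
    the composition is undefined and returned as all-NaN.
    """
    raw = np.asarray(raw_beta, dtype=float).ravel()
    clipped = np.clip(raw, 0.0, 1.0)
    total = clipped.sum()
    if total <= 0:
        return clipped, np.full(raw.shape, np.nan)
    return clipped, clipped / total


def fit_breed_composition(
    y, breed_freqs: AlleleFrequencySet, mode: str = "per-breed"
) -> RegressionFit:
    """Fit one sample's breed composition from its transformed genotypes.

    ``y`` is the sample's {0, 0.5, 1} vector over the same SNPs as
    ``breed_freqs``; missing entries are dropped pairwise (per regression).
    """
    y = np.asarray(y, dtype=float).ravel()
    F = breed_freqs.freqs
    if y.shape[0] != F.shape[1]:
        raise DimensionError("y and breed frequencies cover different SNP sets")
    k = F.shape[0]

    if mode == "per-breed":
        raw = np.empty(k)
        n_used = 0
        for b in range(k):
            ok = ~(np.isnan(y) | np.isnan(F[b]))
            if ok.sum() < 2:
                raise ParameterError("too few complete SNPs for regression")
            X = np.column_stack([np.ones(ok.sum()), F[b, ok]])
            coef, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
            raw[b] = coef[1]
            n_used = max(n_used, int(ok.sum()))
    elif mode == "joint":
        ok = ~np.isnan(y)
        for b in range(k):
            ok &= ~np.isnan(F[b])
        if ok.sum() < k:
            raise ParameterError("too few complete SNPs for regression")
        coef, *_ = np.linalg.lstsq(F[:, ok].T, y[ok], rcond=None)
        raw = coef
        n_used = int(ok.sum())
    else:
        raise ParameterError(f"unknown mode {mode!r}")

    clipped, comp = renormalize_coefficients(raw)
    return RegressionFit(
        raw_beta=raw,
        clipped_beta=clipped,
        composition=comp,
        breeds_used=list(breed_freqs.populations),
        mode=mode,
        n_snps_used=n_used,
    )


def estimate_compositions(
    g: GenotypeMatrix, breed_freqs: AlleleFrequencySet, mode: str = "per-breed"
) -> pd.DataFrame:
    """Per-sample compositions for a whole cohort.

    Returns a DataFrame with sample id, group, one column per reference
    breed, plus mode and SNP count.  Undefined samples carry NaN fractions.
    """
    Y = transform_genotypes(g)
    rows = []
    for i in range(g.n_samples):
        fit = fit_breed_composition(Y[i], breed_freqs, mode=mode)
        row = {
            "sample_id": g.samples["iid"].iat[i],
            "group": g.samples["fid"].iat[i],
        }
        row.update(dict(zip(fit.breeds_used, fit.composition)))
        row["mode"] = mode
        row["n_snps_used"] = fit.n_snps_used
        rows.append(row)
    return pd.DataFrame(rows)
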