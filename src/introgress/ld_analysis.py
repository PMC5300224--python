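"""Linkage disequilibrium: pairwise r2, sliding-window pruning, decay
profiles, and Sved effective-population-size trajectories.

r2 between two loci is the Hill-Robertson squared correlation

    r2 = (p_ij - p_i p_j)^2 / (p_i (1 - p_i) p_j (1 - p_j))

where p_ij is the two-marker haplotype frequency and p_i, p_j the marginal
allele frequencies.  Genotype data are unphased, so p_ij is obtained by an
EM over the double-heterozygote phase ambiguity (the maximum-likelihood
haplotype frequency); a faster genotype-correlation r2 is available for
pruning.

Sved's relation links expected r2 to effective population size Ne at
genetic distance c (Morgans): r2 = 1 / (1 + 4 c Ne), inverted as
Ne = (1/(4c)) (1/r2 - 1).  Physical distance converts to c at a fixed
1e8 base pairs per Morgan (1 cM/Mb), and the r2 at distance c reflects the
effective size 1/(2c) generations ago.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, UndefinedStatisticError
from .genotype_core import MISSING, GenotypeMatrix, allele1_frequency

#: distance bins (Mb) used for decay profiles, half-open [lo, hi)
DEFAULT_DECAY_BINS_MB: tuple = (
    (0.00, 0.02),
    (0.02, 0.04),
    (0.04, 0.06),
    (0.06, 0.08),
    (0.08, 0.10),
    (0.10, 0.20),
    (0.20, 0.30),
    (0.30, 0.40),
    (0.40, 0.50),
)

#: generation horizons for Ne trajectories
DEFAULT_GENERATIONS: tuple = (1, 5, 10, 20, 50, 100, 200)

BP_PER_MORGAN = 1e8


@dataclass
class HaplotypeFreqs:
    """Two-locus haplotype frequencies for allele 1/allele 2 coding."""

    p11: float
    p10: float
    p01: float
    p00: float
    n: int

    @property
    def p_i(self) -> float:
        return self.p11 + self.p10

    @property
    def p_j(self) -> float:
        return self.p11 + self.p01


def two_locus_haplotype_em(
    dosage_i,
    dosage_j,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> HaplotypeFreqs:
    """ML two-locus haplotype frequencies from unphased dosage pairs.

    Only the double heterozygote is phase-ambiguous; EM iterates the
    expected split of those individuals between the {11,00} and {10,01}
    resolutions.  With no double heterozygotes the direct gamete count is
    returned (EM converges in one step).  Margins equal the observed allele
    frequencies by construction.
    """
    di = np.asarray(dosage_i)
    dj = np.asarray(dosage_j)
    ok = (di != MISSING) & (dj != MISSING)
    di, dj = di[ok].astype(int), dj[ok].astype(int)
    n = di.size
    if n < 2:
        raise ParameterError("need >= 2 samples non-missing at both SNPs")

    # genotype pair counts n[g_i, g_j]
    tab = np.zeros((3, 3), dtype=int)
    np.add.at(tab, (di, dj), 1)

    # unambiguous haplotype contributions
    n11 = 2 * tab[2, 2] + tab[2, 1] + tab[1, 2]
    n10 = 2 * tab[2, 0] + tab[2, 1] + tab[1, 0]
    n01 = 2 * tab[0, 2] + tab[0, 1] + tab[1, 2]
    n00 = 2 * tab[0, 0] + tab[0, 1] + tab[1, 0]
    dh = tab[1, 1]  # double heterozygotes: {11,00} or {10,01}

    total = 2.0 * n
    p_i = (2 * tab[2].sum() + tab[1].sum()) / total
    p_j = (2 * tab[:, 2].sum() + tab[:, 1].sum()) / total

    # init at linkage equilibrium
    p11 = p_i * p_j
    for _ in range(max_iter):
        p10 = p_i - p11
        p01 = p_j - p11
        p00 = 1.0 - p11 - p10 - p01
        num = p11 * p00
        den = num + p10 * p01
        frac = 0.5 if den <= 0 else num / den
        new_p11 = (n11 + dh * frac) / total
        if abs(new_p11 - p11) < tol:
            p11 = new_p11
            break
        p11 = new_p11
    p10 = p_i - p11
    p01 = p_j - p11
    p00 = 1.0 - p11 - p10 - p01
    if dh == 0:
        # exact gamete count, no ambiguity
        p11, p10, p01, p00 = (x / total for x in (n11, n10, n01, n00))
    return HaplotypeFreqs(p11=p11, p10=p10, p01=p01, p00=p00, n=n)


def r2_pair(p_ij: float, p_i: float, p_j: float) -> float:
    """Hill-Robertson r2 from a haplotype frequency and its margins."""
    if not (0.0 < p_i < 1.0 and 0.0 < p_j < 1.0):
        raise UndefinedStatisticError("r2 undefined at a fixed margin")
    d = p_ij - p_i * p_j
    return float(d * d / (p_i * (1.0 - p_i) * p_j * (1.0 - p_j)))


def _genotype_r2(di: np.ndarray, dj: np.ndarray) -> float:
    """Squared Pearson correlation of dosages over shared non-missing
    samples (the composite-LD shortcut used for pruning)."""
    ok = (di != MISSING) & (dj != MISSING)
    x, y = di[ok].astype(float), dj[ok].astype(float)
    if x.size < 2:
        return np.nan
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def pairwise_ld(
    g: GenotypeMatrix,
    max_dist_bp: int = 500_000,
    method: str = "em",
    maf_min: float | None = None,
) -> pd.DataFrame:
    """All within-chromosome SNP pairs up to ``max_dist_bp`` apart.

    Returns a DataFrame with columns chrom, snp_i, snp_j, dist_bp, r2 and
    (for the EM method) p_ij, p_i, p_j.  Monomorphic loci are skipped.
    """
    if method not in ("em", "genotype"):
        raise ParameterError(f"unknown LD method {method!r}")
    f = allele1_frequency(g.dosage)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(f, 1.0 - f)
    usable = ~np.isnan(maf) & (maf > 0)
    if maf_min is not None:
        usable &= maf >= maf_min

    rows = []
    chroms = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    ids = g.snps["snp_id"].to_numpy()
    for chrom in np.unique(chroms):
        idx = ((chroms == chrom) & usable).nonzero()[0]
        idx = idx[np.argsort(pos[idx], kind="stable")]
        for a in range(len(idx)):
            ja = idx[a]
            for b in range(a + 1, len(idx)):
                jb = idx[b]
                dist = int(pos[jb] - pos[ja])
                if dist > max_dist_bp:
                    break
                if dist <= 0:
                    continue
                if method == "em":
                    hf = two_locus_haplotype_em(g.dosage[:, ja], g.dosage[:, jb])
                    try:
                        r2 = r2_pair(hf.p11, hf.p_i, hf.p_j)
                    except UndefinedStatisticError:
                        continue
                    rows.append(
                        (chrom, ids[ja], ids[jb], dist, r2, hf.p11, hf.p_i, hf.p_j)
                    )
                else:
                    r2 = _genotype_r2(g.dosage[:, ja], g.dosage[:, jb])
                    if np.isnan(r2):
                        continue
                    rows.append(
                        (chrom, ids[ja], ids[jb], dist, r2, np.nan, np.nan, np.nan)
                    )
    return pd.DataFrame(
        rows,
        columns=["chrom", "snp_i", "snp_j", "dist_bp", "r2", "p_ij", "p_i", "p_j"],
    )


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 10,
    r2_threshold: float = 0.10,
    method: str = "genotype",
) -> list[str]:
    """Sliding-window LD pruning; returns the kept SNP ids.

    Within each window of ``window`` SNPs, pairs are scanned repeatedly in
    (i, j) map order; whenever a pair exceeds the threshold the member with
    the lower MAF is removed (tie: the later map position).  The window then
    slides forward by ``step`` SNPs.  Deterministic given the tie rule.
    """
    if window < 2 or step < 1:
        raise ParameterError("window must be >= 2 and step >= 1")
    f = allele1_frequency(g.dosage)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(f, 1.0 - f)
    chroms = g.snps["chrom"].to_numpy()
    pos = g.snps["pos"].to_numpy()
    ids = g.snps["snp_id"].to_numpy()

    keep = np.ones(g.n_snps, dtype=bool)
    for chrom in np.unique(chroms):
        cidx = (chroms == chrom).nonzero()[0]
        cidx = cidx[np.argsort(pos[cidx], kind="stable")]
        start = 0
        while start < len(cidx):
            win = [j for j in cidx[start : start + window] if keep[j]]
            changed = True
            while changed:
                changed = False
                for a in range(len(win)):
                    if not keep[win[a]]:
                        continue
                    for b in range(a + 1, len(win)):
                        ja, jb = win[a], win[b]
                        if not (keep[ja] and keep[jb]):
                            continue
                        if method == "em":
                            hf = two_locus_haplotype_em(
                                g.dosage[:, ja], g.dosage[:, jb]
                            )
                            try:
                                r2 = r2_pair(hf.p11, hf.p_i, hf.p_j)
                            except UndefinedStatisticError:
                                continue
                        else:
                            r2 = _genotype_r2(g.dosage[:, ja], g.dosage[:, jb])
                        if np.isnan(r2) or r2 <= r2_threshold:
                            continue
                        # drop lower MAF; tie -> later map position
                        ma, mb = maf[ja], maf[jb]
                        if np.isnan(ma):
                            drop = ja
                        elif np.isnan(mb) or mb < ma:
                            drop = jb
                        elif ma < mb:
                            drop = ja
                        else:
                            drop = jb  # tie: jb is later in map order
                        keep[drop] = False
                        changed = True
            start += step
    return [str(s) for s in ids[keep]]


def ld_decay_profile(
    records: pd.DataFrame, bins_mb=DEFAULT_DECAY_BINS_MB
) -> pd.DataFrame:
    """Mean r2 per half-open physical-distance bin [lo, hi) in Mb.

    Empty bins are reported with NaN mean (undefined), never 0.
    """
    dist_mb = records["dist_bp"].to_numpy() / 1e6
    r2 = records["r2"].to_numpy()
    rows = []
    for lo, hi in bins_mb:
        sel = (dist_mb >= lo) & (dist_mb < hi)
        rows.append(
            {
                "bin_lo_mb": lo,
                "bin_hi_mb": hi,
                "n_pairs": int(sel.sum()),
                "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


def sved_ne(mean_r2: float, c_morgans: float) -> float:
    """Sved's inversion Ne = (1/(4c)) (1/r2 - 1)."""
    if c_morgans <= 0:
        raise ParameterError("distance c must be positive")
    if mean_r2 > 1.0:
        raise ParameterError("r2 cannot exceed 1")
    if mean_r2 <= 0.0:
        return float("inf")
    return (1.0 / (4.0 * c_morgans)) * (1.0 / mean_r2 - 1.0)


def ne_trajectory(
    records: pd.DataFrame,
    generations=DEFAULT_GENERATIONS,
    bp_per_morgan: float = BP_PER_MORGAN,
    rel_tol: float = 0.10,
) -> pd.DataFrame:
    """Effective population size t generations ago from LD at c = 1/(2t).

    For each horizon t, the target genetic distance is c = 1/(2t) Morgans
    (physical target c * bp_per_morgan); mean r2 is taken over record pairs
    whose distance lies within ``rel_tol`` (relative) of the target, and
    inverted through Sved's relation.  Horizons with no pairs in the band
    get NaN; mean r2 of 0 yields infinite Ne (flagged via the value itself).
    """
    dist_bp = records["dist_bp"].to_numpy().astype(float)
    r2 = records["r2"].to_numpy()
    rows = []
    for t in generations:
        c = 1.0 / (2.0 * t)
        target = c * bp_per_morgan
        sel = (dist_bp >= target * (1 - rel_tol)) & (
            dist_bp <= target * (1 + rel_tol)
        )
        if sel.any():
            mr2 = float(r2[sel].mean())
            ne = sved_ne(mr2, c)
        else:
            mr2, ne = np.nan, np.nan
        rows.append(
            {
                "generations_ago": t,
                "c_morgans": c,
                "target_bp": target,
                "n_pairs": int(sel.sum()),
                "mean_r2": mr2,
                "ne": ne,
            }
        )
    return pd.DataFrame(rows)
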