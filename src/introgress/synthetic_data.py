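"""Synthetic purebred panels and admixed cohorts with known ancestry.

Breed allele frequencies follow the Balding-Nichols model: at each SNP the
frequency in breed ``b`` is drawn from a Beta distribution whose mean is the
ancestral frequency ``p`` and whose variance is ``p (1 - p) F_b``, where
``F_b`` is the breed's divergence (F_st) from the ancestral pool.  Genotypes
of an individual with ancestry vector ``q`` are binomial draws from the
mixture frequency ``sum_k q_k f_kj`` at each SNP independently (random union
of gametes, loci in linkage equilibrium) — exactly the generative model the
maximum-likelihood and Bayesian ancestry estimators assume, so estimator
recovery on these cohorts is a correctly-specified test.

A first-order Markov haplotype generator is also provided so that the LD
machinery (haplotype EM, pruning, decay profiles) can be exercised on data
with known, geometrically decaying linkage disequilibrium.

Default divergence (F_st 0.05-0.15) is calibrated to the scale typically
observed between cattle breeds within and across the taurine/indicine
lineages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CyclicPedigreeError, DimensionError, ParameterError
from .genotype_core import (
    MISSING,
    AlleleFrequencySet,
    GenotypeMatrix,
    write_plink,
)


@dataclass
class TruthRecord:
    """Ground-truth ancestry for one simulated sample."""

    sample_id: str
    q_true: np.ndarray
    group_label: str

    def __post_init__(self) -> None:
        self.q_true = np.asarray(self.q_true, dtype=float)
        if np.any(self.q_true < 0) or abs(self.q_true.sum() - 1.0) > 1e-12:
            raise ParameterError("q_true must be a point on the simplex")


@dataclass
class BreedModel:
    """Balding-Nichols breed-divergence model parameters."""

    n_breeds: int
    ancestral_freqs: np.ndarray
    fst_per_breed: np.ndarray
    snp_map: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        self.fst_per_breed = np.asarray(self.fst_per_breed, dtype=float)
        if self.n_breeds < 1:
            raise ParameterError("n_breeds must be >= 1")
        if np.any((self.ancestral_freqs <= 0) | (self.ancestral_freqs >= 1)):
            raise ParameterError("ancestral frequencies must be strictly in (0,1)")
        if np.any((self.fst_per_breed <= 0) | (self.fst_per_breed >= 1)):
            raise ParameterError("fst_per_breed must be in (0,1)")


def default_snp_map(n_snps: int, spacing_bp: int = 10_000, chrom: int = 1):
    """Evenly spaced SNP map on a single autosome."""
    return pd.DataFrame(
        {
            "chrom": chrom,
            "snp_id": [f"snp{j}" for j in range(n_snps)],
            "pos": [(j + 1) * spacing_bp for j in range(n_snps)],
            "allele1": "A",
            "allele2": "B",
        }
    )


def simulate_breed_frequencies(
    n_snps: int,
    n_breeds: int,
    fst,
    seed: int,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    breed_names: list[str] | None = None,
    ancestral_freqs=None,
) -> AlleleFrequencySet:
    """Draw breed allele frequencies under the Balding-Nichols model.

    ``fst`` may be a scalar or one value per breed.  Ancestral frequencies
    are uniform on ``ancestral_range`` unless given explicitly via
    ``ancestral_freqs`` (which allows nesting the model hierarchically, e.g.
    lineages diverged from a common pool and breeds diverged within each
    lineage).  Each breed's frequency at each SNP is Beta with mean p and
    variance p(1-p)*fst.  Deterministic for fixed seed.
    """
    if n_snps < 1:
        raise ParameterError("n_snps must be >= 1")
    fst_arr = np.broadcast_to(np.asarray(fst, dtype=float), (n_breeds,)).copy()
    rng = np.random.default_rng(seed)
    if ancestral_freqs is None:
        lo, hi = ancestral_range
        if not 0 < lo < hi < 1:
            raise ParameterError("ancestral_range must satisfy 0 < lo < hi < 1")
        p = rng.uniform(lo, hi, size=n_snps)
    else:
        p = np.asarray(ancestral_freqs, dtype=float)
        if p.shape != (n_snps,):
            raise ParameterError("ancestral_freqs must have length n_snps")
    model = BreedModel(n_breeds, p, fst_arr)  # validates parameter domains
    freqs = np.empty((n_breeds, n_snps))
    for b in range(n_breeds):
        F = fst_arr[b]
        a = p * (1.0 - F) / F
        bb = (1.0 - p) * (1.0 - F) / F
        freqs[b] = rng.beta(a, bb)
    np.clip(freqs, 1e-6, 1.0 - 1e-6, out=freqs)
    if breed_names is None:
        breed_names = [f"B{b + 1}" for b in range(n_breeds)]
    return AlleleFrequencySet(
        freqs, list(breed_names), [f"snp{j}" for j in range(n_snps)]
    )


def expected_pairwise_fst(fst_a: float, fst_b: float, estimator: str = "wright") -> float:
    """Moment oracle: parametric pairwise F_st between two Balding-Nichols
    breeds with divergences ``fst_a`` and ``fst_b`` from the ancestral pool.

    With Beta variance p(1-p)F per breed, E[(p_a - p_b)^2] = (F_a + F_b)
    p(1-p) and E[pbar(1-pbar)] = p(1-p)(1 - (F_a + F_b)/4), so the Wright
    ratio-of-averages statistic converges to s/(4 - s) with s = F_a + F_b
    (~F/2 for two breeds at equal divergence F).  The Hudson form divides by
    E[p_a(1-p_b) + p_b(1-p_a)]/2 = p(1-p) and converges to s/2 (= F).
    """
    s = fst_a + fst_b
    if estimator == "wright":
        return s / (4.0 - s)
    if estimator == "hudson":
        return s / 2.0
    raise ParameterError(f"unknown estimator {estimator!r}")


def random_q_matrix(n: int, k: int, seed: int, alpha: float = 1.0) -> np.ndarray:
    """Rows drawn from a symmetric Dirichlet(alpha) on the k-simplex."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(k, alpha), size=n)


def simulate_admixed_cohort(
    freqs: AlleleFrequencySet,
    q_matrix: np.ndarray,
    missing_rate: float = 0.0,
    seed: int = 0,
    group_labels=None,
    sample_prefix: str = "ind",
    snp_map: pd.DataFrame | None = None,
) -> tuple[GenotypeMatrix, list[TruthRecord]]:
    """Draw genotypes Binomial(2, sum_k q_ik f_kj), then mask missingness.

    Returns the cohort and one :class:`TruthRecord` per sample carrying its
    generating ancestry row.
    """
    q = np.atleast_2d(np.asarray(q_matrix, dtype=float))
    if q.shape[1] != freqs.k:
        raise DimensionError(
            f"q has {q.shape[1]} populations but freqs has {freqs.k}"
        )
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
        raise ParameterError("q_matrix rows must sum to 1")
    if not 0 <= missing_rate < 1:
        raise ParameterError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    pi = q @ freqs.freqs
    dosage = rng.binomial(2, pi).astype(np.int8)
    if missing_rate > 0:
        mask = rng.random(dosage.shape) < missing_rate
        dosage[mask] = MISSING

    n = q.shape[0]
    if group_labels is None:
        group_labels = ["ADMIX"] * n
    elif isinstance(group_labels, str):
        group_labels = [group_labels] * n
    ids = [f"{sample_prefix}{i}" for i in range(n)]
    samples = pd.DataFrame({"fid": list(group_labels), "iid": ids})
    if snp_map is None:
        snp_map = default_snp_map(freqs.n_snps)
        snp_map["snp_id"] = freqs.snp_ids
    g = GenotypeMatrix(samples, snp_map, dosage)
    truths = [
        TruthRecord(ids[i], q[i], str(group_labels[i])) for i in range(n)
    ]
    return g, truths


# ---------------------------------------------------------------------------
# crossing schemes


def _topo_order(scheme: dict) -> list[str]:
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(node: str) -> None:
        if state.get(node) == 1:
            raise CyclicPedigreeError(f"cycle through node {node!r}")
        if state.get(node) == 2:
            return
        state[node] = 1
        spec = scheme[node]
        if not isinstance(spec, str):
            for parent in spec:
                if parent not in scheme:
                    raise ParameterError(f"unknown parent {parent!r} of {node!r}")
                visit(parent)
        state[node] = 2
        order.append(node)

    for node in scheme:
        visit(node)
    return order


def simulate_crossing_scheme(
    scheme: dict,
    freqs: AlleleFrequencySet,
    n_loci: int,
    seed: int,
    n_replicates: int = 1,
    with_genotypes: bool = True,
    nodes=None,
) -> tuple[GenotypeMatrix | None, list[TruthRecord]]:
    """Simulate a crossing scheme with per-locus breed-of-origin tracking.

    ``scheme`` maps node names either to a founder breed name (one of
    ``freqs.populations``) or to a pair of parent node names.  Each gamete
    picks, independently at every locus, one of the parent's two allele
    copies; the copy carries its breed of origin.  Realized ancestry of an
    animal is the mean breed indicator over its ``2 * n_loci`` copies, so
    E[realized] equals the parental mean (the pedigree expectation) and its
    variance shrinks as 1/n_loci.
    """
    if n_loci < 1 or n_loci > freqs.n_snps:
        raise ParameterError("need 1 <= n_loci <= number of SNPs in freqs")
    topo = _topo_order(scheme)
    rng = np.random.default_rng(seed)
    out_nodes = list(scheme) if nodes is None else list(nodes)

    all_rows = []
    truths: list[TruthRecord] = []
    f = freqs.freqs[:, :n_loci]
    for rep in range(n_replicates):
        origins: dict[str, np.ndarray] = {}
        for node in topo:
            spec = scheme[node]
            if isinstance(spec, str):
                b = freqs.populations.index(spec)
                origins[node] = np.full((2, n_loci), b, dtype=np.int8)
            else:
                p1, p2 = spec
                gametes = []
                for parent in (p1, p2):
                    pick = rng.integers(0, 2, size=n_loci)
                    gametes.append(origins[parent][pick, np.arange(n_loci)])
                origins[node] = np.vstack(gametes)
        for node in out_nodes:
            o = origins[node]
            q_real = np.bincount(o.ravel(), minlength=freqs.k) / (2 * n_loci)
            sid = f"{node}_r{rep}"
            truths.append(TruthRecord(sid, q_real, node))
            if with_genotypes:
                alle = rng.random((2, n_loci)) < f[o, np.arange(n_loci)]
                all_rows.append(alle.sum(axis=0).astype(np.int8))

    g = None
    if with_genotypes:
        samples = pd.DataFrame(
            {
                "fid": [t.group_label for t in truths],
                "iid": [t.sample_id for t in truths],
            }
        )
        snp_map = default_snp_map(n_loci)
        snp_map["snp_id"] = freqs.snp_ids[:n_loci]
        g = GenotypeMatrix(samples, snp_map, np.vstack(all_rows))
    return g, truths


#: Canchim crossing schemes (Charolais x Zebu), as directed mating graphs.
#: Scheme I produces CA (5/8 CH); scheme IV produces MA (21/32 CH) and the
#: C2/C3 genetic groups.
CANCHIM_SCHEME_I: dict = {
    "CH": "CH",
    "ZB": "ZB",
    "F1": ("CH", "ZB"),
    "G2": ("ZB", "F1"),
    "G3": ("CH", "G2"),
    "CA": ("G3", "G3"),
}

CANCHIM_SCHEME_IV: dict = {
    **CANCHIM_SCHEME_I,
    "A": ("CA", "ZB"),
    "MA": ("CH", "A"),
    "C2": ("CA", "MA"),
    "C3": ("MA", "MA"),
}


# ---------------------------------------------------------------------------
# Markov-correlated haplotypes (for the LD module)


def simulate_markov_haplotypes(
    n_samples: int,
    n_snps: int,
    rho: float,
    seed: int,
    spacing_bp: int = 10_000,
    chrom: int = 1,
    group_label: str = "LD",
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Genotypes from first-order Markov haplotypes with adjacent correlation
    ``rho`` (so loci at lag L have correlation rho**L, r2 = rho**(2L)).

    Allele frequencies are 0.5 at every locus (the stationary law of the
    symmetric chain).  Returns the cohort and the underlying phased
    haplotypes, shape ``(2 * n_samples, n_snps)``, for phased-truth oracles.
    """
    if not 0 <= rho < 1:
        raise ParameterError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_samples
    h = np.empty((n_hap, n_snps), dtype=np.int8)
    h[:, 0] = rng.random(n_hap) < 0.5
    keep_p = (1.0 + rho) / 2.0
    for j in range(1, n_snps):
        keep = rng.random(n_hap) < keep_p
        h[:, j] = np.where(keep, h[:, j - 1], 1 - h[:, j - 1])
    dosage = (h[0::2] + h[1::2]).astype(np.int8)
    samples = pd.DataFrame(
        {"fid": group_label, "iid": [f"ld{i}" for i in range(n_samples)]}
    )
    snp_map = default_snp_map(n_snps, spacing_bp=spacing_bp, chrom=chrom)
    return GenotypeMatrix(samples, snp_map, dosage), h


# ---------------------------------------------------------------------------
# fixture bundles


@dataclass
class GeneratorConfig:
    """Settings for a self-contained PLINK fixture bundle."""

    n_snps: int = 2000
    fst: float | tuple = 0.1
    breeds: tuple = ("NE", "CH")
    n_per_breed: int = 50
    n_admixed: int = 50
    admixed_group: str = "CAN"
    q_admixed: tuple = (0.375, 0.625)
    missing_rate: float = 0.0
    seed: int = 0
    prefix: str = "panel"
    extras: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def generate_fixture_bundle(config: GeneratorConfig, out_dir) -> dict[str, str]:
    """Write PLINK text+binary files, a truth table and the config.

    Returns a manifest mapping relative file names to SHA-256 checksums
    (also written to ``manifest.tsv``).  Byte-deterministic for a fixed
    config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    k = len(config.breeds)
    freqs = simulate_breed_frequencies(
        config.n_snps, k, config.fst, config.seed, breed_names=list(config.breeds)
    )
    q_rows = []
    labels = []
    for b, name in enumerate(config.breeds):
        e = np.zeros(k)
        e[b] = 1.0
        q_rows += [e] * config.n_per_breed
        labels += [name] * config.n_per_breed
    q_admix = np.asarray(config.q_admixed, dtype=float)
    q_rows += [q_admix] * config.n_admixed
    labels += [config.admixed_group] * config.n_admixed
    g, truths = simulate_admixed_cohort(
        freqs,
        np.vstack(q_rows),
        missing_rate=config.missing_rate,
        seed=config.seed + 1,
        group_labels=labels,
    )
    prefix = out / config.prefix
    files = write_plink(g, prefix, dialect="text")
    files += write_plink(g, prefix, dialect="binary")

    truth_path = out / "truth.tsv"
    with open(truth_path, "w") as fh:
        cols = "\t".join(f"q_{name}" for name in config.breeds)
        fh.write(f"sample_id\tgroup\t{cols}\n")
        for t in truths:
            qs = "\t".join(f"{v:.10f}" for v in t.q_true)
            fh.write(f"{t.sample_id}\t{t.group_label}\t{qs}\n")
    files.append(truth_path)

    config_path = out / "config.txt"
    with open(config_path, "w") as fh:
        for key in (
            "n_snps",
            "fst",
            "breeds",
            "n_per_breed",
            "n_admixed",
            "admixed_group",
            "q_admixed",
            "missing_rate",
            "seed",
            "prefix",
        ):
            fh.write(f"{key}={getattr(config, key)}\n")
    files.append(config_path)

    manifest = {f.name: _sha256(f) for f in files}
    with open(out / "manifest.tsv", "w") as fh:
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\n")
    return manifest
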