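"""Genotype containers, PLINK-format I/O, panel merging and quality control.

The central container is :class:`GenotypeMatrix`: a samples x SNPs table of
allele-1 dosages in {0, 1, 2} with ``-1`` marking missing genotypes.  Allele 1
is, by convention, the minor allele (frequency <= 0.5 after recoding; ties are
broken by keeping the lexicographically smaller allele name as allele 1).

Both PLINK dialects are supported: text PED/MAP and binary BED/BIM/FAM
(SNP-major, magic bytes 0x6c 0x1b 0x01).  Reading and writing round-trip
exactly in either dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MergeConflictError, ParameterError

logger = logging.getLogger(__name__)

MISSING = -1

#: 2-bit BED code -> allele-1 dosage (00=hom A1, 01=missing, 10=het, 11=hom A2)
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
#: allele-1 dosage -> 2-bit BED code, indexed by dosage + 1 (missing first)
_BED_ENCODE = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-1 dosage table.

    Attributes
    ----------
    samples : pandas.DataFrame
        Columns ``fid`` (family / breed group), ``iid`` (sample id).
    snps : pandas.DataFrame
        Columns ``snp_id``, ``chrom``, ``pos``, ``allele1``, ``allele2``.
    dosage : numpy.ndarray
        ``int8`` array of shape ``(n_samples, n_snps)`` counting copies of
        allele 1; ``-1`` is missing.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ParameterError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            raise ParameterError("dosage values must be in {0, 1, 2, -1}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def groups(self) -> np.ndarray:
        return self.samples["fid"].to_numpy()

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples.reset_index(drop=True).copy(),
            self.snps.reset_index(drop=True).copy(),
            self.dosage.copy(),
        )

    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples.reset_index(drop=True).copy(),
            self.snps.iloc[index].reset_index(drop=True),
            self.dosage[:, index].copy(),
        )

    def take_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.samples.iloc[index].reset_index(drop=True),
            self.snps.reset_index(drop=True).copy(),
            self.dosage[index, :].copy(),
        )


@dataclass
class AlleleFrequencySet:
    """k populations x J SNPs frequencies of allele 1 (NaN = undefined)."""

    freqs: np.ndarray
    populations: list[str]
    snp_ids: list[str]

    def __post_init__(self) -> None:
        self.freqs = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        if self.freqs.shape != (len(self.populations), len(self.snp_ids)):
            raise ParameterError("freqs shape must be (k populations, J SNPs)")

    @property
    def k(self) -> int:
        return self.freqs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]

    def population(self, name: str) -> np.ndarray:
        return self.freqs[self.populations.index(name)]


@dataclass
class QcReport:
    """Itemized record of every sample/SNP removed by :func:`qc_filter`."""

    samples_removed: pd.DataFrame
    snps_removed: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def n_samples_removed(self) -> int:
        return len(self.samples_removed)

    @property
    def n_snps_removed(self) -> int:
        return len(self.snps_removed)


# ---------------------------------------------------------------------------
# coding helpers


def allele1_frequency(dosage: np.ndarray) -> np.ndarray:
    """Per-SNP frequency of allele 1 among non-missing allele copies.

    Returns NaN for SNPs with all genotypes missing.
    """
    d = np.asarray(dosage)
    obs = d != MISSING
    n_copies = 2 * obs.sum(axis=0).astype(float)
    counts = np.where(obs, d, 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = counts / n_copies
    f[n_copies == 0] = np.nan
    return f


def recode_minor(g: GenotypeMatrix) -> GenotypeMatrix:
    """Flip allele coding so allele 1 is the minor allele at every SNP.

    Ties (frequency exactly 0.5) keep the lexicographically smaller allele
    name as allele 1, which makes the coding deterministic.
    """
    f = allele1_frequency(g.dosage)
    a1 = g.snps["allele1"].astype(str).to_numpy()
    a2 = g.snps["allele2"].astype(str).to_numpy()
    with np.errstate(invalid="ignore"):
        flip = f > 0.5
        tie = f == 0.5
    flip = np.where(tie, a1 > a2, flip)
    flip &= ~pd.isna(f)

    dosage = g.dosage.copy()
    miss = dosage == MISSING
    dosage[:, flip] = 2 - dosage[:, flip]
    dosage[miss] = MISSING

    snps = g.snps.reset_index(drop=True).copy()
    snps.loc[flip, ["allele1", "allele2"]] = snps.loc[
        flip, ["allele2", "allele1"]
    ].to_numpy()
    return GenotypeMatrix(g.samples.reset_index(drop=True).copy(), snps, dosage)


# ---------------------------------------------------------------------------
# PLINK I/O


def _read_map(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{path}: line {ln}: expected 4 fields")
            rows.append((int(parts[0]), parts[1], int(parts[3])))
    return pd.DataFrame(rows, columns=["chrom", "snp_id", "pos"])


def _read_text(prefix: Path) -> GenotypeMatrix:
    snp_df = _read_map(prefix.with_suffix(".map"))
    n_snps = len(snp_df)

    sample_rows = []
    allele_rows = []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{prefix.with_suffix('.ped')}: line {ln}: expected "
                    f"{6 + 2 * n_snps} fields for {n_snps} SNPs, got {len(parts)}"
                )
            sample_rows.append((parts[0], parts[1]))
            allele_rows.append(parts[6:])
    samples = pd.DataFrame(sample_rows, columns=["fid", "iid"])
    alleles = np.array(allele_rows, dtype=object).reshape(len(samples), n_snps, 2)

    # establish an allele pair per SNP from the observed alleles
    dosage = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    a1_list, a2_list = [], []
    for j in range(n_snps):
        col = alleles[:, j, :]
        seen = sorted({a for a in col.ravel() if a != "0"})
        if len(seen) > 2:
            raise FormatError(
                f"{prefix.with_suffix('.ped')}: SNP {snp_df['snp_id'][j]} has "
                f"more than two alleles: {seen}"
            )
        a1 = seen[0] if seen else "0"
        a2 = seen[1] if len(seen) > 1 else "0"
        a1_list.append(a1)
        a2_list.append(a2)
        nonmiss = (col[:, 0] != "0") & (col[:, 1] != "0")
        dosage[nonmiss, j] = (col[nonmiss, 0] == a1).astype(np.int8) + (
            col[nonmiss, 1] == a1
        ).astype(np.int8)
    snp_df["allele1"] = a1_list
    snp_df["allele2"] = a2_list
    return GenotypeMatrix(samples, snp_df, dosage)


def _read_binary(prefix: Path) -> GenotypeMatrix:
    fam = []
    with open(prefix.with_suffix(".fam")) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                fam.append((parts[0], parts[1]))
    samples = pd.DataFrame(fam, columns=["fid", "iid"])

    bim = []
    with open(prefix.with_suffix(".bim")) as fh:
        for line in fh:
            parts = line.split()
            if parts:
                bim.append((int(parts[0]), parts[1], int(parts[3]), parts[4], parts[5]))
    snp_df = pd.DataFrame(bim, columns=["chrom", "snp_id", "pos", "allele1", "allele2"])

    n, m = len(samples), len(snp_df)
    bpath = prefix.with_suffix(".bed")
    raw = bpath.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bpath}: bad magic bytes (not a SNP-major BED file)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise FormatError(
            f"{bpath}: expected {m * bytes_per_snp} data bytes for {n} samples "
            f"x {m} SNPs, found {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    codes = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (body >> (2 * shift)) & 0b11
    dosage = _BED_DECODE[codes[:, :n]].T
    return GenotypeMatrix(samples, snp_df, dosage)


def read_plink(prefix, dialect: str = "binary") -> GenotypeMatrix:
    """Read a PLINK fileset and return a minor-allele-coded GenotypeMatrix.

    Parameters
    ----------
    prefix : path
        Fileset prefix (``.ped``/``.map`` or ``.bed``/``.bim``/``.fam``).
    dialect : {"binary", "text"}
    """
    prefix = Path(prefix)
    if dialect == "text":
        g = _read_text(prefix)
    elif dialect == "binary":
        g = _read_binary(prefix)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return recode_minor(g)


def write_plink(g: GenotypeMatrix, prefix, dialect: str = "binary") -> list[Path]:
    """Write a GenotypeMatrix as a PLINK fileset; returns the written paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if dialect == "text":
        ped = prefix.with_suffix(".ped")
        with open(ped, "w") as fh:
            a1 = g.snps["allele1"].astype(str).to_numpy()
            a2 = g.snps["allele2"].astype(str).to_numpy()
            for i in range(g.n_samples):
                fields = [
                    str(g.samples["fid"].iat[i]),
                    str(g.samples["iid"].iat[i]),
                    "0",
                    "0",
                    "0",
                    "-9",
                ]
                row = g.dosage[i]
                for j in range(g.n_snps):
                    d = row[j]
                    if d == MISSING:
                        fields += ["0", "0"]
                    elif d == 2:
                        fields += [a1[j], a1[j]]
                    elif d == 1:
                        fields += [a1[j], a2[j]]
                    else:
                        fields += [a2[j], a2[j]]
                fh.write(" ".join(fields) + "\n")
        written.append(ped)
        mp = prefix.with_suffix(".map")
        with open(mp, "w") as fh:
            for _, r in g.snps.iterrows():
                fh.write(f"{r['chrom']} {r['snp_id']} 0 {r['pos']}\n")
        written.append(mp)
    elif dialect == "binary":
        n, m = g.n_samples, g.n_snps
        bytes_per_snp = (n + 3) // 4
        codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
        codes[:, :n] = _BED_ENCODE[(g.dosage + 1).T]
        packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
        for shift in range(4):
            packed |= codes[:, shift::4] << (2 * shift)
        bed = prefix.with_suffix(".bed")
        bed.write_bytes(_BED_MAGIC + packed.tobytes())
        written.append(bed)
        bim = prefix.with_suffix(".bim")
        with open(bim, "w") as fh:
            for _, r in g.snps.iterrows():
                fh.write(
                    f"{r['chrom']}\t{r['snp_id']}\t0\t{r['pos']}"
                    f"\t{r['allele1']}\t{r['allele2']}\n"
                )
        written.append(bim)
        fam = prefix.with_suffix(".fam")
        with open(fam, "w") as fh:
            for _, r in g.samples.iterrows():
                fh.write(f"{r['fid']} {r['iid']} 0 0 0 -9\n")
        written.append(fam)
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")
    return written


# ---------------------------------------------------------------------------
# merging / subsetting


def merge_panels(panels: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge breed panels: SNP intersection, sample union, minor recoding.

    Allele codings are reconciled by allele-pair matching; a swapped pair
    flips the dosage onto the first panel's coding.  Irreconcilable pairs
    raise :class:`MergeConflictError`.
    """
    if not panels:
        raise ParameterError("need at least one panel")
    base = panels[0]
    common = set(base.snps["snp_id"])
    for p in panels[1:]:
        common &= set(p.snps["snp_id"])
    keep = base.snps["snp_id"].isin(common).to_numpy().nonzero()[0]
    base_sub = base.take_snps(keep)
    order = {sid: j for j, sid in enumerate(base_sub.snps["snp_id"])}

    a1 = base_sub.snps["allele1"].astype(str).to_numpy()
    a2 = base_sub.snps["allele2"].astype(str).to_numpy()

    sample_frames = [base_sub.samples]
    dosage_blocks = [base_sub.dosage]
    conflicts: list[str] = []
    for p in panels[1:]:
        idx = np.array(
            [order.get(sid, -1) for sid in p.snps["snp_id"]], dtype=int
        )
        sel = idx >= 0
        cols = np.argsort(idx[sel])
        p_sub = p.take_snps(sel.nonzero()[0][cols])
        pa1 = p_sub.snps["allele1"].astype(str).to_numpy()
        pa2 = p_sub.snps["allele2"].astype(str).to_numpy()
        same = (pa1 == a1) & ((pa2 == a2) | (pa2 == "0") | (a2 == "0"))
        swapped = (pa1 == a2) & ((pa2 == a1) | (pa2 == "0"))
        # a monomorphic panel ("0" second allele) can also match on a1 == a2
        mono_match = (pa2 == "0") & (pa1 == a2)
        swapped |= mono_match & ~same
        bad = ~(same | swapped)
        if bad.any():
            conflicts.extend(p_sub.snps["snp_id"][bad])
            continue
        d = p_sub.dosage.copy()
        miss = d == MISSING
        d[:, swapped] = 2 - d[:, swapped]
        d[miss] = MISSING
        sample_frames.append(p_sub.samples)
        dosage_blocks.append(d)
    if conflicts:
        raise MergeConflictError(conflicts)

    merged = GenotypeMatrix(
        pd.concat(sample_frames, ignore_index=True),
        base_sub.snps,
        np.vstack(dosage_blocks),
    )
    return recode_minor(merged)


def extract_snp_subset(g: GenotypeMatrix, keep_ids) -> GenotypeMatrix:
    """Retain only SNPs in ``keep_ids`` (map order preserved).

    Ids absent from the map are silently dropped (counted in the log), which
    mirrors extracting a high-density panel down to a lower-density map.
    """
    keep = set(keep_ids)
    mask = g.snps["snp_id"].isin(keep).to_numpy()
    n_absent = len(keep) - int(mask.sum())
    if n_absent:
        logger.info("extract_snp_subset: %d requested ids not in map", n_absent)
    return g.take_snps(mask.nonzero()[0])


# ---------------------------------------------------------------------------
# quality control


def qc_filter(
    g: GenotypeMatrix,
    mind: float = 0.10,
    geno: float = 0.05,
    hwe_p: float | None = 1e-5,
    maf: float | None = None,
    chromosomes=range(1, 30),
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the standard QC cascade and return the filtered matrix + report.

    Order of application (fixed, documented): autosome filter, then sample
    call rate (missing fraction > ``mind`` removed), then SNP call rate
    (missing fraction > ``geno``), then HWE exact test (p < ``hwe_p``), then
    optional MAF (< ``maf``).  Thresholds follow the usual PLINK semantics:
    ``mind 0.10`` removes samples with call rate below 0.90, etc.
    """
    for name, val in (("mind", mind), ("geno", geno)):
        if not 0 <= val <= 1:
            raise ParameterError(f"{name} must be in [0, 1]")
    from .popgen_stats import hwe_exact_test  # local import: avoids cycle

    snps_removed = []
    samples_removed = []

    work = g.copy()
    if chromosomes is not None:
        chrom_ok = work.snps["chrom"].isin(list(chromosomes)).to_numpy()
        for sid in work.snps["snp_id"][~chrom_ok]:
            snps_removed.append((sid, "chromosome"))
        work = work.take_snps(chrom_ok.nonzero()[0])

    if work.n_snps > 0:
        miss_rate = (work.dosage == MISSING).mean(axis=1)
    else:
        miss_rate = np.zeros(work.n_samples)
    bad_sample = miss_rate > mind
    for i in bad_sample.nonzero()[0]:
        samples_removed.append(
            (work.samples["iid"].iat[i], "sample call rate", 1.0 - miss_rate[i])
        )
    work = work.take_samples((~bad_sample).nonzero()[0])

    if work.n_samples > 0:
        snp_miss = (work.dosage == MISSING).mean(axis=0)
    else:
        snp_miss = np.zeros(work.n_snps)
    bad_snp = snp_miss > geno
    for j in bad_snp.nonzero()[0]:
        snps_removed.append((work.snps["snp_id"].iat[j], "SNP call rate"))
    work = work.take_snps((~bad_snp).nonzero()[0])

    if hwe_p is not None and work.n_samples > 0:
        d = work.dosage
        obs = d != MISSING
        n_hom1 = ((d == 2) & obs).sum(axis=0)
        n_het = ((d == 1) & obs).sum(axis=0)
        n_hom2 = ((d == 0) & obs).sum(axis=0)
        pvals = np.ones(work.n_snps)
        for j in range(work.n_snps):
            tot = n_hom1[j] + n_het[j] + n_hom2[j]
            if tot > 0:
                pvals[j] = hwe_exact_test(n_hom1[j], n_het[j], n_hom2[j])
        bad_hwe = pvals < hwe_p
        for j in bad_hwe.nonzero()[0]:
            snps_removed.append((work.snps["snp_id"].iat[j], "HWE"))
        work = work.take_snps((~bad_hwe).nonzero()[0])

    if maf is not None and work.n_samples > 0:
        f = allele1_frequency(work.dosage)
        with np.errstate(invalid="ignore"):
            m = np.minimum(f, 1.0 - f)
        bad_maf = (m < maf) | np.isnan(m)
        for j in bad_maf.nonzero()[0]:
            snps_removed.append((work.snps["snp_id"].iat[j], "MAF"))
        work = work.take_snps((~bad_maf).nonzero()[0])

    report = QcReport(
        samples_removed=pd.DataFrame(
            samples_removed, columns=["iid", "reason", "call_rate"]
        ),
        snps_removed=pd.DataFrame(snps_removed, columns=["snp_id", "reason"]),
        thresholds={
            "mind": mind,
            "geno": geno,
            "hwe_p": hwe_p,
            "maf": maf,
            "chromosomes": list(chromosomes) if chromosomes is not None else None,
        },
    )
    return work, report


def allele_frequencies(
    g: GenotypeMatrix, by_group: bool = False
) -> AlleleFrequencySet:
    """Allele-1 frequencies, overall or per breed group (FID).

    SNPs with all genotypes missing in a group get NaN (undefined), never a
    silent zero.
    """
    snp_ids = list(g.snps["snp_id"])
    if not by_group:
        return AlleleFrequencySet(
            allele1_frequency(g.dosage)[None, :], ["ALL"], snp_ids
        )
    groups = list(dict.fromkeys(g.groups))
    rows = []
    for grp in groups:
        idx = (g.groups == grp).nonzero()[0]
        rows.append(allele1_frequency(g.dosage[idx]))
    return AlleleFrequencySet(np.vstack(rows), [str(x) for x in groups], snp_ids)
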