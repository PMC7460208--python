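"""Genotype containers, VCF input/output, site filtering and LD pruning.

The in-memory representation is a dense diploid allele-dosage matrix
(samples x variants, int8, ``-1`` for missing) plus a variant table.
Dosage is the count of alternate alleles and is only meaningful for
biallelic records; multiallelic records are carried through parsing with a
flag and removed by :func:`filter_sites` before any analysis.

Coordinates are VCF-style 1-based inclusive internally; BED output is
0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

_AUTOSOME_RE = re.compile(r"^(chr)?\d+$", re.IGNORECASE)


def is_autosome(name: str, autosome_names: set[str] | None = None) -> bool:
    """True if ``name`` is an autosome.

    By default any purely numeric contig name (optionally ``chr``-prefixed)
    is treated as autosomal; an explicit name set overrides this.
    """
    if autosome_names is not None:
        return name in autosome_names
    return bool(_AUTOSOME_RE.match(name))


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-variants diploid dosage matrix.

    Attributes
    ----------
    sample_ids : list of str
    variants : DataFrame with columns chrom, pos (1-based), ref, alt,
        n_alt (number of ALT alleles; >1 flags a multiallelic record).
    genotypes : int8 array of shape (n_samples, n_variants); values in
        {0, 1, 2} or -1 for a missing call.
    """

    sample_ids: list[str]
    variants: pd.DataFrame
    genotypes: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def validate(self) -> None:
        if self.genotypes.shape != (self.n_samples, self.n_variants):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{self.n_samples} samples x {self.n_variants} variants"
            )
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    def take_variants(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[:, idx],
        )

    def take_samples(self, names: list[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        rows = [lookup[n] for n in names]
        return GenotypeMatrix(
            sample_ids=list(names),
            variants=self.variants,
            genotypes=self.genotypes[rows, :],
        )


@dataclass
class PopulationMap:
    """Assignment of samples to populations plus a designated outgroup."""

    sample_to_pop: dict[str, str]
    populations: list[str]
    outgroup: str | None = None

    @property
    def analysis_populations(self) -> list[str]:
        """Ordered study populations, excluding the outgroup."""
        return [p for p in self.populations if p != self.outgroup]

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    @property
    def study_samples(self) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p != self.outgroup]

    @property
    def outgroup_samples(self) -> list[str]:
        if self.outgroup is None:
            return []
        return self.samples_of(self.outgroup)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        absent = sorted(set(self.sample_to_pop) - set(gm.sample_ids))
        if absent:
            raise ValueError(f"samples in population map absent from VCF: {absent}")


@dataclass
class FilterReport:
    """Per-criterion removal counts; applied in the listed precedence order."""

    input_count: int
    removed_non_biallelic: int = 0
    removed_non_autosome: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.input_count,
            "removed_non_biallelic": self.removed_non_biallelic,
            "removed_non_autosome": self.removed_non_autosome,
            "removed_call_rate": self.removed_call_rate,
            "removed_maf": self.removed_maf,
            "retained": self.retained,
        }

    def check_conservation(self) -> None:
        removed = (
            self.removed_non_biallelic
            + self.removed_non_autosome
            + self.removed_call_rate
            + self.removed_maf
        )
        if removed + self.retained != self.input_count:
            raise AssertionError("filter report counts do not conserve variants")


def _dosage_from_alleles(arr: np.ndarray) -> np.ndarray:
    """Diploid dosage from a cyvcf2 genotype array (n_samples x >=2).

    Any negative allele (``.``) makes the call missing, so half-calls
    like ``./1`` count as missing rather than as one observed copy.
    """
    alleles = arr[:, :2]
    dos = (alleles > 0).sum(axis=1).astype(np.int8)
    dos[(alleles < 0).any(axis=1)] = MISSING
    return dos


def read_vcf(path: str | Path, autosome_names: set[str] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    All records are returned; multiallelic records are flagged via the
    ``n_alt`` column rather than dropped. Half-calls and ``./.`` become
    missing.  ``autosome_names`` is accepted here only for symmetry; the
    autosome filter itself is applied by :func:`filter_sites`.
    """
    path = str(path)
    vcf = VCF(path, gts012=False)
    if "GT" not in {f["ID"] for f in vcf.header_iter() if f["HeaderType"] == "FORMAT"}:
        raise ValueError(f"{path}: no GT FORMAT field in header")
    samples = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    n_alt: list[int] = []
    dosages: list[np.ndarray] = []
    i = 0
    try:
        for v in vcf:
            chroms.append(v.CHROM)
            pos.append(v.POS)
            ref.append(v.REF)
            alt.append(",".join(v.ALT) if v.ALT else ".")
            n_alt.append(len(v.ALT))
            dosages.append(_dosage_from_alleles(v.genotype.array()))
            i += 1
    except Exception as exc:  # htslib parse failure
        raise ValueError(f"{path}: malformed VCF near record {i + 1}: {exc}") from exc
    variants = pd.DataFrame(
        {"chrom": chroms, "pos": np.asarray(pos, dtype=np.int64), "ref": ref,
         "alt": alt, "n_alt": np.asarray(n_alt, dtype=np.int8)}
    )
    geno = (
        np.asarray(dosages, dtype=np.int8).T
        if dosages
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(sample_ids=samples, variants=variants, genotypes=geno)
    gm.validate()
    return gm


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCFv4.2 (GT only, unphased) for biallelic data."""
    if (gm.variants["n_alt"] > 1).any():
        raise ValueError("write_vcf supports biallelic records only")
    path = Path(path)
    # indexed by dosage + 1: -1 (missing), 0, 1, 2
    lut = np.array(["./.", "0/0", "0/1", "1/1"], dtype=object)
    chrom = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    ref = gm.variants["ref"].to_numpy()
    alt = gm.variants["alt"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popkit\n")
        for c in dict.fromkeys(chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        geno = gm.genotypes
        for j in range(gm.n_variants):
            gts = lut[geno[:, j].astype(np.int64) + 1]
            fh.write(
                f"{chrom[j]}\t{pos[j]}\t.\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_population_map(path: str | Path, outgroup: str | None = None) -> PopulationMap:
    """Read a two-column TSV (sample_id, population)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                         dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty population map") from None
    if df.empty:
        raise ValueError(f"{path}: empty population map")
    if df["sample"].isna().any() or df["population"].isna().any():
        raise ValueError(f"{path}: malformed rows in population map")
    dup = df["sample"][df["sample"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample rows: {sorted(set(dup))}")
    pops = list(dict.fromkeys(df["population"]))
    if outgroup is not None and outgroup not in pops:
        raise ValueError(f"{path}: outgroup {outgroup!r} not among populations {pops}")
    return PopulationMap(
        sample_to_pop=dict(zip(df["sample"], df["population"])),
        populations=pops,
        outgroup=outgroup,
    )


def write_population_map(popmap: PopulationMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.sample_to_pop.items():
            fh.write(f"{s}\t{p}\n")


def pooled_maf(gm: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per variant over non-missing calls, all samples pooled."""
    geno = gm.genotypes
    called = geno != MISSING
    n_copies = 2 * called.sum(axis=0)
    alt_copies = np.where(called, geno, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, alt_copies / np.maximum(n_copies, 1), np.nan)
    return np.fmin(p, 1.0 - p)


def filter_sites(
    gm: GenotypeMatrix,
    max_missing: float = 0.1,
    min_maf: float = 0.05,
    autosomes_only: bool = True,
    autosome_names: set[str] | None = None,
    apply_maf: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep biallelic autosomal SNPs passing call-rate and MAF thresholds.

    Call rate must be strictly greater than ``1 - max_missing`` and pooled
    minor-allele frequency strictly greater than ``min_maf`` (both strict,
    mirroring PLINK-style "call rate >90% and MAF > 0.05").  Criteria are
    applied with the precedence non-biallelic > non-autosome > call rate >
    MAF, so each removed variant is counted once.
    """
    report = FilterReport(input_count=gm.n_variants)
    ref_len = gm.variants["ref"].str.len().to_numpy()
    alt_len = gm.variants["alt"].str.len().to_numpy()
    biallelic = (gm.variants["n_alt"].to_numpy() == 1) & (ref_len == 1) & (alt_len == 1)
    report.removed_non_biallelic = int((~biallelic).sum())

    if autosomes_only:
        auto = gm.variants["chrom"].map(
            lambda c: is_autosome(c, autosome_names)
        ).to_numpy()
    else:
        auto = np.ones(gm.n_variants, dtype=bool)
    report.removed_non_autosome = int((biallelic & ~auto).sum())

    called_frac = (gm.genotypes != MISSING).mean(axis=0) if gm.n_samples else np.zeros(gm.n_variants)
    callrate_ok = called_frac > (1.0 - max_missing)
    report.removed_call_rate = int((biallelic & auto & ~callrate_ok).sum())

    if apply_maf:
        maf = pooled_maf(gm)
        maf_ok = maf > min_maf
    else:
        maf_ok = np.ones(gm.n_variants, dtype=bool)
    keep = biallelic & auto & callrate_ok & maf_ok
    report.removed_maf = int((biallelic & auto & callrate_ok & ~maf_ok).sum())
    report.retained = int(keep.sum())
    report.check_conservation()
    if report.retained == 0:
        logger.warning("filter_sites removed every variant")
    return gm.take_variants(np.flatnonzero(keep)), report


def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns on pairwise-complete rows.

    ``X`` is float with NaN for missing.  Monomorphic/undefined pairs get 0.
    """
    M = (~np.isnan(X)).astype(np.float64)
    Xz = np.where(np.isnan(X), 0.0, X)
    n = M.T @ M
    sx = Xz.T @ M          # sum of x over rows where y present: entry (i,j)
    sy = sx.T
    sxy = Xz.T @ Xz
    sxx = (Xz**2).T @ M
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r2 = cov**2 / (vx * vy)
    r2 = np.where(np.isfinite(r2), r2, 0.0)
    # round so threshold comparisons at exactly-rational r2 (common with
    # small discrete dosage data) are stable across equivalent formulas
    return np.round(r2, 12)


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_threshold: float = 0.2,
) -> np.ndarray:
    """Greedy windowed LD pruning on genotype (dosage) r-squared.

    Windows of ``window_snps`` consecutive variants advance by
    ``step_snps``; within a window, while any kept pair exceeds the
    threshold, the pair member with the lower pooled MAF is removed
    (tie: the later variant in position order).  Returns the kept variant
    indices in order.  PLINK bit-parity is not promised; the rule above
    defines the behaviour.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if step_snps < 1:
        raise ValueError("step_snps must be >= 1")
    V = gm.n_variants
    keep = np.ones(V, dtype=bool)
    if V == 0:
        return np.array([], dtype=int)
    maf = pooled_maf(gm)
    X = gm.genotypes.astype(np.float64)
    X[gm.genotypes == MISSING] = np.nan
    for start in range(0, max(V - 1, 1), step_snps):
        stop = min(start + window_snps, V)
        idx = np.arange(start, stop)
        if idx.size < 2:
            continue
        r2 = _pairwise_r2(X[:, idx])
        local_keep = keep[idx].copy()
        for a in range(idx.size):
            if not local_keep[a]:
                continue
            for b in range(a + 1, idx.size):
                if not local_keep[a]:
                    break
                if not local_keep[b]:
                    continue
                if r2[a, b] > r2_threshold:
                    ia, ib = idx[a], idx[b]
                    if maf[ia] < maf[ib]:
                        local_keep[a] = False
                    elif maf[ib] < maf[ia]:
                        local_keep[b] = False
                    else:  # tie: drop the later variant in position order
                        local_keep[b] = False
        keep[idx] = local_keep
        if stop == V:
            break
    return np.flatnonzero(keep)
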