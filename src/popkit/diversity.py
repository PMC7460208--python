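"""Per-population diversity statistics and pairwise differentiation.

The central object is the molecular coancestry matrix ``f``: for two
populations i and j (possibly i = j), ``f_ij`` is the probability that two
alleles drawn at random, one from each population's frequency profile, are
identical in state, averaged over loci.  Gene diversity is ``H = 1 - f``,
Nei's minimum distance is ``D_nei(i,j) = (f_ii + f_jj)/2 - f_ij`` and the
pairwise differentiation index is the Nei G_ST form
``F_ST = (H_T - H_S)/H_T`` — all exact algebraic consequences of ``f``,
which makes the identities between them testable to machine precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variant_io import GenotypeMatrix, MISSING, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class AlleleFrequencyTable:
    """Per-(population, variant) alternate-allele counts and frequencies."""

    populations: list[str]
    alt_copies: np.ndarray      # (P, V) int — alternate gene copies observed
    called_copies: np.ndarray   # (P, V) int — non-missing gene copies
    n_diploids: np.ndarray      # (P,) int   — population sizes

    @property
    def freq(self) -> np.ndarray:
        """Alt frequency; NaN where a population has zero calls at a locus."""
        with np.errstate(invalid="ignore", divide="ignore"):
            f = self.alt_copies / self.called_copies
        return np.where(self.called_copies > 0, f, np.nan)

    @property
    def covered(self) -> np.ndarray:
        """(P, V) bool — population has at least one call at the locus."""
        return self.called_copies > 0

    def complete_loci(self) -> np.ndarray:
        """Indices of loci with calls in every population."""
        return np.flatnonzero(self.covered.all(axis=0))


def allele_frequencies(gm: GenotypeMatrix, popmap: PopulationMap,
                       populations: list[str] | None = None) -> AlleleFrequencyTable:
    """Alternate-allele frequencies per population over non-missing calls."""
    pops = populations if populations is not None else popmap.populations
    alt = np.zeros((len(pops), gm.n_variants), dtype=np.int64)
    called = np.zeros_like(alt)
    sizes = np.zeros(len(pops), dtype=np.int64)
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    for k, pop in enumerate(pops):
        samples = popmap.samples_of(pop)
        if not samples:
            raise ValueError(f"population {pop!r} has no samples")
        rows = np.array([index[s] for s in samples])
        sub = gm.genotypes[rows, :]
        ok = sub != MISSING
        alt[k] = np.where(ok, sub, 0).sum(axis=0)
        called[k] = 2 * ok.sum(axis=0)
        sizes[k] = len(samples)
    table = AlleleFrequencyTable(list(pops), alt, called, sizes)
    n_flagged = int((~table.covered).sum())
    if n_flagged:
        logger.info("allele_frequencies: %d (population, locus) cells without calls", n_flagged)
    return table


def observed_expected_het(
    gm: GenotypeMatrix, popmap: PopulationMap,
    populations: list[str] | None = None, unbiased: bool = True,
) -> pd.DataFrame:
    """Observed and expected heterozygosity per population.

    H_O is the fraction of heterozygous calls among non-missing genotypes,
    averaged over loci.  H_E is the per-locus mean of ``2p(1-p)`` with the
    small-sample correction ``2n/(2n-1)`` (PLINK convention) unless
    ``unbiased=False``.
    """
    pops = populations if populations is not None else popmap.populations
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    rows = []
    for pop in pops:
        samples = popmap.samples_of(pop)
        if not samples:
            raise ValueError(f"population {pop!r} has no samples")
        if unbiased and len(samples) < 2:
            raise ValueError(
                f"population {pop!r} has a single diploid; the 2n/(2n-1) "
                "H_E correction is undefined"
            )
        sub = gm.genotypes[np.array([index[s] for s in samples]), :]
        ok = sub != MISSING
        copies = 2 * ok.sum(axis=0)
        # H_O: heterozygote fraction per locus, then mean over covered loci
        het = ((sub == 1) & ok).sum(axis=0)
        called = ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho_site = np.where(called > 0, het / np.maximum(called, 1), np.nan)
            p = np.where(copies > 0, np.where(ok, sub, 0).sum(axis=0) / np.maximum(copies, 1), np.nan)
            he_site = 2.0 * p * (1.0 - p)
            if unbiased:
                corr_ok = copies > 1
                he_site = np.where(corr_ok, he_site * copies / np.maximum(copies - 1, 1), np.nan)
        rows.append(
            {
                "population": pop,
                "n": len(samples),
                "H_O": float(np.nanmean(ho_site)),
                "H_E": float(np.nanmean(he_site)),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def _rarefied_alleles(counts: np.ndarray, total: np.ndarray, g: int) -> np.ndarray:
    """Expected rarefied allele presence ``1 - C(total-c, g)/C(total, g)``.

    Vectorised via log-gamma; entries where ``total - c < g`` contribute 1
    (the allele is certain to appear).
    """
    c = counts.astype(np.float64)
    N = total.astype(np.float64)
    rest = N - c
    with np.errstate(invalid="ignore"):
        log_ratio = (
            gammaln(rest + 1) - gammaln(rest - g + 1)
            - gammaln(N + 1) + gammaln(N - g + 1)
        )
    ratio = np.where(rest >= g, np.exp(log_ratio), 0.0)
    return 1.0 - ratio


def allelic_richness(
    freqs: AlleleFrequencyTable, rarefaction_g: int | None = None
) -> pd.DataFrame:
    """Hypergeometric-rarefaction allelic richness per population.

    ``A_R`` is the expected number of distinct alleles in a sample of ``g``
    gene copies.  ``g`` defaults to the gene-copy count of the smallest
    population (2 x its diploid count); loci with fewer than ``g``
    non-missing copies in a population are skipped and counted.
    """
    if rarefaction_g is None:
        rarefaction_g = int(2 * freqs.n_diploids.min())
    g = int(rarefaction_g)
    if g < 2:
        raise ValueError("rarefaction depth g must be >= 2")
    rows = []
    for k, pop in enumerate(freqs.populations):
        total = freqs.called_copies[k]
        usable = total >= g
        alt = freqs.alt_copies[k][usable]
        tot = total[usable]
        ref = tot - alt
        ar = _rarefied_alleles(ref, tot, g) + _rarefied_alleles(alt, tot, g)
        rows.append(
            {
                "population": pop,
                "A_R": float(ar.mean()) if ar.size else np.nan,
                "g": g,
                "loci_used": int(usable.sum()),
                "loci_skipped": int((~usable).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("population")


def inbreeding_coefficient(
    gm: GenotypeMatrix, popmap: PopulationMap,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per population.

    Per individual, ``F = (O_hom - E_hom) / (L - E_hom)`` where ``E_hom``
    sums ``1 - 2p(1-p) * 2n/(2n-1)`` over that individual's called loci,
    with ``p`` and ``n`` from its own population (PLINK ``--het`` style).
    The population value is the mean over its individuals.
    """
    pops = populations if populations is not None else popmap.populations
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    out = []
    for pop in pops:
        samples = popmap.samples_of(pop)
        if len(samples) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 diploids")
        rows = np.array([index[s] for s in samples])
        sub = gm.genotypes[rows, :]
        ok = sub != MISSING
        copies = 2 * ok.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(copies > 0, np.where(ok, sub, 0).sum(axis=0) / np.maximum(copies, 1), np.nan)
            e_het_site = 2.0 * p * (1.0 - p) * copies / np.maximum(copies - 1, 1)
        usable_site = (copies > 1) & np.isfinite(e_het_site)
        f_vals = []
        for r in range(sub.shape[0]):
            use = ok[r] & usable_site
            L = int(use.sum())
            if L == 0:
                logger.warning("individual %s has no usable loci; skipped", samples[r])
                continue
            o_hom = float((sub[r, use] != 1).sum())
            e_hom = float(L - e_het_site[use].sum())
            denom = L - e_hom
            if denom == 0:
                logger.warning("individual %s: degenerate F denominator; skipped", samples[r])
                continue
            f_vals.append((o_hom - e_hom) / denom)
        out.append({"population": pop, "F": float(np.mean(f_vals)) if f_vals else np.nan,
                    "n_individuals": len(f_vals)})
    return pd.DataFrame(out).set_index("population")


@dataclass
class CoancestryMatrix:
    """Symmetric per-locus-averaged allele-identity probabilities."""

    populations: list[str]
    f: np.ndarray  # (P, P)

    def __post_init__(self) -> None:
        if not np.allclose(self.f, self.f.T, atol=1e-12):
            raise ValueError("coancestry matrix must be symmetric")


def coancestry(freqs: AlleleFrequencyTable, complete_only: bool = False) -> CoancestryMatrix:
    """Molecular coancestry ``f_ij = mean_loci [p_i p_j + (1-p_i)(1-p_j)]``.

    Each pair is averaged over its shared-coverage loci
    (pairwise-complete); ``complete_only=True`` restricts every entry to
    the loci covered in all populations.
    """
    p = freqs.freq
    cov = freqs.covered
    if complete_only:
        keep = cov.all(axis=0)
        p = p[:, keep]
        cov = cov[:, keep]
    P = len(freqs.populations)
    f = np.zeros((P, P))
    for i in range(P):
        for j in range(i, P):
            shared = cov[i] & cov[j]
            if not shared.any():
                raise ValueError(
                    f"no shared loci between populations "
                    f"{freqs.populations[i]!r} and {freqs.populations[j]!r}"
                )
            pi, pj = p[i, shared], p[j, shared]
            f[i, j] = f[j, i] = float(np.mean(pi * pj + (1 - pi) * (1 - pj)))
    return CoancestryMatrix(list(freqs.populations), f)


def nei_minimum_distance(f: CoancestryMatrix) -> pd.DataFrame:
    """Nei's minimum genetic distance ``(f_ii + f_jj)/2 - f_ij``."""
    diag = np.diag(f.f)
    D = (diag[:, None] + diag[None, :]) / 2.0 - f.f
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=f.populations, columns=f.populations)


def pairwise_fst(f: CoancestryMatrix) -> tuple[pd.DataFrame, int]:
    """Pairwise Nei G_ST: ``(H_T - H_S)/H_T`` per population pair.

    ``H_T = 1 - (f_ii + f_jj + 2 f_ij)/4`` and ``H_S = 1 - (f_ii + f_jj)/2``.
    Negative estimates are truncated to 0; the truncation count is
    returned.  A pair with ``H_T = 0`` (both fixed and identical) is
    defined as 0 with a warning.
    """
    diag = np.diag(f.f)
    h_s = 1.0 - (diag[:, None] + diag[None, :]) / 2.0
    h_t = 1.0 - (diag[:, None] + diag[None, :] + 2.0 * f.f) / 4.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = (h_t - h_s) / h_t
    degenerate = h_t == 0
    if degenerate.any():
        n_deg = int(np.triu(degenerate, 1).sum())
        if n_deg:
            logger.warning("pairwise_fst: %d pairs with H_T = 0 set to 0", n_deg)
        fst = np.where(degenerate, 0.0, fst)
    n_trunc = int(np.triu(fst < 0, 1).sum())
    fst = np.clip(fst, 0.0, 1.0)
    np.fill_diagonal(fst, 0.0)
    return pd.DataFrame(fst, index=f.populations, columns=f.populations), n_trunc


def pairwise_summary(f: CoancestryMatrix) -> pd.DataFrame:
    """Per-population average F_ST and D_nei against all other populations."""
    fst, _ = pairwise_fst(f)
    dnei = nei_minimum_distance(f)
    P = len(f.populations)
    if P < 2:
        raise ValueError("need >= 2 populations")
    mask = ~np.eye(P, dtype=bool)
    return pd.DataFrame(
        {
            "avg_FST": (fst.to_numpy() * mask).sum(axis=1) / (P - 1),
            "avg_Dnei": (dnei.to_numpy() * mask).sum(axis=1) / (P - 1),
        },
        index=f.populations,
    )


def diversity_summary(
    gm: GenotypeMatrix, popmap: PopulationMap,
    populations: list[str] | None = None,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Table of H_O, H_E, A_R, F and within-population coancestry f_ii.

    Two expected-heterozygosity columns are emitted: ``H_E`` (per-site
    unbiased mean, PLINK-style) and ``H_E_nei`` = 1 - f_ii (the coancestry
    form without small-sample correction); the two differ by the 2n/(2n-1)
    factor and are both reported because either convention is common.
    """
    pops = populations if populations is not None else popmap.populations
    het = observed_expected_het(gm, popmap, pops)
    freqs = allele_frequencies(gm, popmap, pops)
    ar = allelic_richness(freqs, rarefaction_g)
    fcoef = inbreeding_coefficient(gm, popmap, pops)
    f = coancestry(freqs)
    out = het.join(ar[["A_R", "g"]]).join(fcoef[["F"]])
    out["f_ii"] = np.diag(f.f)
    out["H_E_nei"] = 1.0 - np.diag(f.f)
    return out
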