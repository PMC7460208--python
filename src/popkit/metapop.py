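"""Metapopulation diversity partitioning and conservation prioritisation.

Total gene diversity splits into a within-subpopulation component and an
average between-subpopulation Nei-distance component,

    H_T = H_S + D_G,

and total allelic diversity into segregating-allele and private-allele
components,

    A_T = A_S + D_A.

Both identities are exact under the s-squared double-sum averaging
convention used here (diagonal terms included, equal subpopulation
weights), which is why they serve as machine-precision invariants.
Leave-one-out contributions quantify what each subpopulation adds to the
pool: positive means its removal loses diversity.  The pool optimiser
finds mixture proportions maximising either expected heterozygosity
(criterion H) or the expected number of distinct alleles (criterion K).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import AlleleFrequencyTable, CoancestryMatrix, coancestry
from .variant_io import GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

PARTITION_COMPONENTS = ("H_S", "D_G", "H_T", "A_S", "D_A", "A_T")


def partition_gene_diversity(f: CoancestryMatrix) -> tuple[float, float, float]:
    """Split total gene diversity into H_S (within) and D_G (between).

    H_S = (1/s) sum_i (1 - f_ii); D_G = (1/s^2) sum_ij D_nei(i, j);
    H_T = 1 - (1/s^2) sum_ij f_ij.  The identity H_T = H_S + D_G holds by
    construction.
    """
    s = len(f.populations)
    if s < 2:
        raise ValueError("need >= 2 subpopulations")
    diag = np.diag(f.f)
    h_s = float(np.mean(1.0 - diag))
    dnei = (diag[:, None] + diag[None, :]) / 2.0 - f.f
    d_g = float(dnei.sum() / s**2)
    h_t = float(1.0 - f.f.sum() / s**2)
    return h_s, d_g, h_t


def allele_presence(freqs: AlleleFrequencyTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ref_present, alt_present, complete) boolean arrays of shape (P, V).

    An allele is present in a population when at least one copy was
    observed; ``complete`` marks loci covered in every population (loci
    failing this are excluded from the partition and counted by callers).
    """
    ref = (freqs.called_copies - freqs.alt_copies) > 0
    alt = freqs.alt_copies > 0
    complete = freqs.covered.all(axis=0)
    return ref, alt, complete


def partition_allelic_diversity(
    ref_present: np.ndarray, alt_present: np.ndarray,
    loci: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Split allelic diversity into A_S (segregating) and D_A (private).

    Per locus: A_S = (1/s) sum_i (K_i - 1) with K_i the number of alleles
    segregating in subpopulation i; D_A = (1/s^2) sum_ij (u_ij + u_ji)/2
    with u_ij the alleles of i absent from j (diagonal 0); A_T =
    (1/s^2) sum_ij (K_union(i,j) - 1).  Averaged over loci; the identity
    A_T = A_S + D_A is exact.
    """
    if loci is not None:
        ref_present = ref_present[:, loci]
        alt_present = alt_present[:, loci]
    s, V = ref_present.shape
    if s < 2:
        raise ValueError("need >= 2 subpopulations")
    if V == 0:
        raise ValueError("no loci available for the allelic partition")
    K = ref_present.astype(np.int64) + alt_present.astype(np.int64)
    if (K == 0).any():
        raise ValueError("locus with an empty allele set; restrict to complete loci")
    a_s = float((K - 1).mean(axis=0).mean())
    d_a_sum = 0.0
    a_t_sum = 0.0
    for i in range(s):
        for j in range(s):
            u_ij = ((ref_present[i] & ~ref_present[j]).sum()
                    + (alt_present[i] & ~alt_present[j]).sum())
            u_ji = ((ref_present[j] & ~ref_present[i]).sum()
                    + (alt_present[j] & ~alt_present[i]).sum())
            k_union = ((ref_present[i] | ref_present[j]).astype(np.int64)
                       + (alt_present[i] | alt_present[j]).astype(np.int64))
            d_a_sum += (u_ij + u_ji) / 2.0
            a_t_sum += float((k_union - 1).sum())
    d_a = d_a_sum / (s**2 * V)
    a_t = a_t_sum / (s**2 * V)
    return a_s, d_a, a_t


def pooled_allelic_diversity(ref_present: np.ndarray, alt_present: np.ndarray,
                             loci: np.ndarray | None = None) -> float:
    """Pooled-metapopulation allele count minus one, averaged over loci.

    Emitted alongside the pairwise-average A_T for comparison; the two
    coincide for biallelic loci segregating everywhere but differ when
    alleles are private.
    """
    if loci is not None:
        ref_present = ref_present[:, loci]
        alt_present = alt_present[:, loci]
    k_pool = ref_present.any(axis=0).astype(np.int64) + alt_present.any(axis=0).astype(np.int64)
    return float((k_pool - 1).mean())


@dataclass
class PartitionResult:
    """Six-component partition plus per-subpopulation leave-one-out
    percent contributions (positive = loss of diversity on removal)."""

    components: dict[str, float]
    contributions: pd.DataFrame  # rows: subpopulations, cols: PARTITION_COMPONENTS
    a_t_pooled: float | None = None
    loci_used: int | None = None
    loci_excluded: int | None = None

    def check_identities(self, tol: float = 1e-10) -> None:
        c = self.components
        if abs(c["H_T"] - c["H_S"] - c["D_G"]) > tol:
            raise AssertionError("gene-diversity partition identity violated")
        if abs(c["A_T"] - c["A_S"] - c["D_A"]) > tol:
            raise AssertionError("allelic-diversity partition identity violated")


def _partition_all(freqs: AlleleFrequencyTable, subset: list[int],
                   loci: np.ndarray) -> dict[str, float]:
    sub_freqs = AlleleFrequencyTable(
        [freqs.populations[i] for i in subset],
        freqs.alt_copies[subset][:, loci],
        freqs.called_copies[subset][:, loci],
        freqs.n_diploids[subset],
    )
    f = coancestry(sub_freqs)
    h_s, d_g, h_t = partition_gene_diversity(f)
    ref, alt, _ = allele_presence(sub_freqs)
    a_s, d_a, a_t = partition_allelic_diversity(ref, alt)
    return {"H_S": h_s, "D_G": d_g, "H_T": h_t, "A_S": a_s, "D_A": d_a, "A_T": a_t}


def loo_contributions(
    gm_or_freqs: GenotypeMatrix | AlleleFrequencyTable,
    popmap: PopulationMap | None = None,
    populations: list[str] | None = None,
) -> PartitionResult:
    """Leave-one-out percent contributions of each subpopulation.

    For each subpopulation i and component X in {H_S, D_G, H_T, A_S, D_A,
    A_T}: ``contribution = 100 * (X_full - X_without_i) / X_full``.  The
    locus set is fixed to loci covered in all subpopulations so the full
    and reduced metapopulations are computed over identical data.
    """
    if isinstance(gm_or_freqs, AlleleFrequencyTable):
        freqs = gm_or_freqs
        if populations is not None:
            idx = [freqs.populations.index(p) for p in populations]
            freqs = AlleleFrequencyTable(
                [freqs.populations[i] for i in idx],
                freqs.alt_copies[idx], freqs.called_copies[idx],
                freqs.n_diploids[idx],
            )
    else:
        from .diversity import allele_frequencies
        if popmap is None:
            raise ValueError("popmap required when passing a GenotypeMatrix")
        pops = populations if populations is not None else popmap.analysis_populations
        freqs = allele_frequencies(gm_or_freqs, popmap, pops)
    s = len(freqs.populations)
    if s < 3:
        raise ValueError("leave-one-out needs >= 3 subpopulations")
    loci = freqs.complete_loci()
    n_excluded = freqs.alt_copies.shape[1] - loci.size
    full = _partition_all(freqs, list(range(s)), loci)
    rows = []
    for i in range(s):
        reduced = _partition_all(freqs, [k for k in range(s) if k != i], loci)
        rows.append(
            {
                comp: (
                    100.0 * (full[comp] - reduced[comp]) / full[comp]
                    if full[comp] != 0.0
                    else 0.0  # component absent from the full pool; nothing to lose
                )
                for comp in PARTITION_COMPONENTS
            }
        )
    contrib = pd.DataFrame(rows, index=freqs.populations)
    ref, alt, _ = allele_presence(freqs)
    result = PartitionResult(
        components=full,
        contributions=contrib,
        a_t_pooled=pooled_allelic_diversity(ref, alt, loci),
        loci_used=int(loci.size),
        loci_excluded=int(n_excluded),
    )
    result.check_identities()
    return result


# ---------------------------------------------------------------------------
# Pool optimisation


@dataclass
class PoolSolution:
    """Optimal mixture proportions over subpopulations (simplex)."""

    criterion: str
    proportions: pd.Series
    objective: float
    converged: bool = True


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / np.arange(1, v.size + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def expected_heterozygosity_of_pool(c: np.ndarray, f: np.ndarray) -> float:
    """Gene diversity of a mixture: ``H(c) = 1 - c' f c``."""
    return float(1.0 - c @ f @ c)


def expected_alleles_of_pool(c: np.ndarray, freq: np.ndarray, g: int) -> float:
    """Expected distinct alleles in ``g`` gene copies drawn from the pool.

    Pool allele frequencies are the c-weighted population frequencies; for
    each allele the inclusion probability is ``1 - (1 - P_a)^g``, summed
    over the two alleles and averaged over loci.
    """
    p_pool = c @ freq
    e = (1.0 - (1.0 - p_pool) ** g) + (1.0 - p_pool**g)
    return float(e.mean())


def optimize_pool(
    f: CoancestryMatrix | None = None,
    freqs: AlleleFrequencyTable | None = None,
    criterion: str = "H",
    resolution: float = 0.01,
    g: int = 20,
    max_iter: int = 2000,
    tol: float = 1e-12,
    n_random_starts: int = 8,
    seed: int = 0,
) -> PoolSolution:
    """Mixture proportions maximising pool diversity.

    Criterion ``"H"`` maximises ``1 - c'fc`` over the simplex by projected
    gradient ascent with multi-start (uniform start first, then vertices,
    then seeded random points; ties keep the earliest start, so degenerate
    instances return the uniform solution).  Criterion ``"K"`` greedily
    assigns weight increments of size ``resolution`` to whichever
    subpopulation most increases the expected distinct-allele count.
    """
    if criterion == "H":
        if f is None:
            raise ValueError("criterion H needs a coancestry matrix")
        F = f.f
        s = F.shape[0]
        starts = [np.full(s, 1.0 / s)]
        starts += [np.eye(s)[i] for i in range(s)]
        rng = np.random.default_rng(seed)
        for _ in range(n_random_starts):
            starts.append(rng.dirichlet(np.ones(s)))
        best_c, best_val, best_ok = None, -np.inf, True
        lam = np.linalg.eigvalsh(F)[-1]
        step = 1.0 / max(2.0 * abs(lam), 1e-9)
        for c0 in starts:
            c = c0.copy()
            ok = False
            for _ in range(max_iter):
                grad = -2.0 * F @ c
                c_new = _project_simplex(c + step * grad)
                if np.max(np.abs(c_new - c)) < tol:
                    c = c_new
                    ok = True
                    break
                c = c_new
            val = expected_heterozygosity_of_pool(c, F)
            if val > best_val + 1e-12:
                best_c, best_val, best_ok = c, val, ok
        if not best_ok:
            logger.warning("optimize_pool(H): best start did not fully converge")
        return PoolSolution("H", pd.Series(best_c, index=f.populations),
                            best_val, best_ok)
    if criterion == "K":
        if freqs is None:
            raise ValueError("criterion K needs an allele-frequency table")
        loci = freqs.complete_loci()
        p = freqs.freq[:, loci]
        s = p.shape[0]
        n_steps = int(round(1.0 / resolution))
        counts = np.zeros(s)
        for _ in range(n_steps):
            best_i, best_val = 0, -np.inf
            for i in range(s):
                trial = counts.copy()
                trial[i] += 1
                val = expected_alleles_of_pool(trial / trial.sum(), p, g)
                if val > best_val + 1e-15:
                    best_i, best_val = i, val
            counts[best_i] += 1
        c = counts / counts.sum()
        return PoolSolution("K", pd.Series(c, index=freqs.populations),
                            expected_alleles_of_pool(c, p, g), True)
    raise ValueError(f"unknown criterion {criterion!r}")
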