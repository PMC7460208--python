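"""Synthetic subdivided-population genotype data with planted truth.

Emulates a resequencing study design of ten small, geographically isolated
study populations (3-6 diploids each) plus a larger wild outgroup:
biallelic autosomal SNPs whose subpopulation allele frequencies drift
around a shared ancestral frequency under the Balding-Nichols model,
within-individual allele correlation (inbreeding, F_is), missing calls,
low-frequency deleterious alleles carrying SIFT-style scores, and planted
selective-sweep windows in which the study group is driven toward fixation.

All randomness flows from the single integer seed in the configuration;
per-stage generators are derived from it with fixed stream offsets so the
output files are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .variant_io import (
    GenotypeMatrix,
    MISSING,
    PopulationMap,
    write_population_map,
    write_vcf,
)

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# Stream offsets so each stage draws from an independent substream of the seed.
_STREAM_BASE, _STREAM_SWEEP, _STREAM_ANNOT, _STREAM_GENES = 0, 1, 2, 3

#: Study-population sample sizes of the emulated design (ten groups, 50 diploids).
DEFAULT_SUBPOP_SIZES = (6, 6, 4, 4, 5, 6, 5, 5, 3, 6)

#: Per-subpopulation inbreeding defaults spanning the near-outbred to
#: strongly inbred range observed in small isolated livestock populations.
DEFAULT_FIS = (0.01, 0.05, 0.02, 0.22, 0.32, 0.10, 0.27, 0.34, 0.14, 0.35)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic metapopulation.

    ``drift_F`` is the Balding-Nichols differentiation parameter of each
    study subpopulation (scalar broadcast or one value per subpopulation);
    ``outgroup_drift_F`` plays the same role for the outgroup, which has
    diverged further from the common ancestor than the study populations
    have from each other.  ``sweep_windows`` are (chrom, start, end,
    target) tuples in 0-based half-open bp; target is ``"study"`` (the
    pooled non-outgroup samples), ``"outgroup"`` or a population label.
    """

    n_subpops: int = 10
    samples_per_subpop: tuple[int, ...] = DEFAULT_SUBPOP_SIZES
    n_outgroup: int = 15
    n_variants: int = 20_000
    genome: tuple[tuple[str, int], ...] = (("1", 10_000_000), ("2", 10_000_000))
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    drift_F: float | tuple[float, ...] = 0.10
    outgroup_drift_F: float = 0.30
    inbreeding_Fis: float | tuple[float, ...] = DEFAULT_FIS
    outgroup_Fis: float = 0.0
    missing_rate: float = 0.02
    sweep_windows: tuple[tuple[str, int, int, str], ...] = ()
    sweep_fix_freq: float = 0.98
    deleterious_fraction: float = 0.01
    deleterious_freq_law: tuple = ("lowfreq_mixture", 0.7, 0.05, 0.6)
    sift_threshold: float = 0.05
    subpop_labels: tuple[str, ...] | None = None
    outgroup_label: str = "wild"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_subpop) != self.n_subpops:
            raise ValueError("samples_per_subpop must have length n_subpops")
        if any(n < 1 for n in self.samples_per_subpop):
            raise ValueError("every subpopulation needs at least one sample")
        if self.n_outgroup < 0:
            raise ValueError("n_outgroup must be >= 0")
        for F in list(self.drift_values()) + [self.outgroup_drift_F]:
            if not (0.0 <= F < 1.0):
                raise ValueError(f"drift_F must lie in [0, 1): got {F}")
        for fis in list(self.fis_values()) + [self.outgroup_Fis]:
            if not (0.0 <= fis < 1.0):
                raise ValueError(f"inbreeding_Fis must lie in [0, 1): got {fis}")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if not (0.0 <= self.deleterious_fraction <= 1.0):
            raise ValueError("deleterious_fraction must lie in [0, 1]")
        lengths = dict(self.genome)
        for chrom, start, end, _target in self.sweep_windows:
            if chrom not in lengths:
                raise ValueError(f"sweep window on undeclared chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(
                    f"sweep window {chrom}:{start}-{end} outside chromosome length"
                )

    def drift_values(self) -> list[float]:
        if np.isscalar(self.drift_F):
            return [float(self.drift_F)] * self.n_subpops
        return [float(x) for x in self.drift_F]  # type: ignore[union-attr]

    def fis_values(self) -> list[float]:
        if np.isscalar(self.inbreeding_Fis):
            return [float(self.inbreeding_Fis)] * self.n_subpops
        return [float(x) for x in self.inbreeding_Fis]  # type: ignore[union-attr]

    @property
    def labels(self) -> list[str]:
        if self.subpop_labels is not None:
            if len(self.subpop_labels) != self.n_subpops:
                raise ValueError("subpop_labels must have length n_subpops")
            return list(self.subpop_labels)
        return [f"pop{i + 1:02d}" for i in range(self.n_subpops)]

    @property
    def all_pop_labels(self) -> list[str]:
        labels = self.labels
        if self.n_outgroup > 0:
            labels = labels + [self.outgroup_label]
        return labels


@dataclass
class SimulationTruth:
    """Planted ground truth for parameter-recovery tests."""

    ancestral_freq: np.ndarray                      # (V,)
    subpop_freq: dict[str, np.ndarray]              # label -> (V,)
    sweep_windows: list[dict] = field(default_factory=list)
    deleterious_flag: np.ndarray | None = None      # (V,) bool
    sift_score: np.ndarray | None = None            # (V,) float, NaN = unscored

    def to_json(self, path: str | Path, full_arrays: bool | None = None) -> None:
        """Write truth to JSON; per-variant arrays only for modest sizes."""
        V = int(self.ancestral_freq.shape[0])
        if full_arrays is None:
            full_arrays = V <= 100_000
        obj: dict = {
            "n_variants": V,
            "sweep_windows": self.sweep_windows,
            "deleterious_indices": (
                np.flatnonzero(self.deleterious_flag).tolist()
                if self.deleterious_flag is not None
                else []
            ),
        }
        if full_arrays:
            obj["ancestral_freq"] = np.round(self.ancestral_freq, 6).tolist()
            obj["subpop_freq"] = {
                k: np.round(v, 6).tolist() for k, v in self.subpop_freq.items()
            }
            if self.sift_score is not None:
                obj["sift_score"] = [
                    None if np.isnan(x) else round(float(x), 6) for x in self.sift_score
                ]
        with open(path, "w") as fh:
            json.dump(obj, fh, separators=(",", ":"))
            fh.write("\n")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _draw_ancestral(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    law = config.ancestral_freq_law
    if law[0] == "uniform":
        return rng.uniform(law[1], law[2], size=config.n_variants)
    if law[0] == "beta":
        return np.clip(rng.beta(law[1], law[2], size=config.n_variants), 1e-6, 1 - 1e-6)
    raise ValueError(f"unknown ancestral_freq_law {law!r}")


def _deleterious_freqs(
    config: SimulationConfig, rng: np.random.Generator, k: int
) -> np.ndarray:
    """Ancestral alt frequencies for deleterious sites: mostly rare alleles."""
    law = config.deleterious_freq_law
    if law[0] != "lowfreq_mixture":
        raise ValueError(f"unknown deleterious_freq_law {law!r}")
    p_low, cut, fmax = float(law[1]), float(law[2]), float(law[3])
    low = rng.random(k) < p_low
    freqs = np.where(
        low,
        rng.uniform(0.002, cut, size=k),
        rng.uniform(cut, fmax, size=k),
    )
    return freqs


def _draw_positions(config: SimulationConfig, rng: np.random.Generator):
    """Allocate variants across chromosomes and draw sorted unique positions."""
    lengths = np.array([L for _, L in config.genome], dtype=np.float64)
    counts = rng.multinomial(config.n_variants, lengths / lengths.sum())
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for (name, L), k in zip(config.genome, counts):
        if k > L:
            raise ValueError(f"more variants than positions on chromosome {name}")
        pos = np.array([], dtype=np.int64)
        while pos.size < k:
            extra = rng.integers(1, L + 1, size=2 * (k - pos.size) + 16)
            pos = np.unique(np.concatenate([pos, extra]))
            if pos.size > k:
                pos = np.sort(rng.choice(pos, size=k, replace=False))
        chroms.extend([name] * k)
        positions.append(np.sort(pos))
    return np.array(chroms), np.concatenate(positions) if positions else np.array([], dtype=np.int64)


def _genotypes_for_group(
    freqs: np.ndarray, n: int, fis: float, rng: np.random.Generator
) -> np.ndarray:
    """Diploid dosages for one group: one allele drawn from the group
    frequency, the second copied with probability ``fis`` else drawn
    independently (the standard inbreeding construction)."""
    a1 = rng.random((n, freqs.size)) < freqs
    copy = rng.random((n, freqs.size)) < fis
    a2 = np.where(copy, a1, rng.random((n, freqs.size)) < freqs)
    return (a1.astype(np.int8) + a2.astype(np.int8))


def simulate_metapopulation(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """Simulate the base (sweep-free) metapopulation.

    Subpopulation frequencies follow Balding-Nichols
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``
    (``F = 0`` copies ``p`` exactly).  Deleterious sites (chosen
    Bernoulli(deleterious_fraction)) get ancestral frequencies from a
    low-frequency law before drift, so their alternate alleles stay rare.
    """
    rng = _rng(config, _STREAM_BASE)
    V = config.n_variants
    p_anc = _draw_ancestral(config, rng)

    del_flag = rng.random(V) < config.deleterious_fraction
    k = int(del_flag.sum())
    if k:
        p_anc = p_anc.copy()
        p_anc[del_flag] = _deleterious_freqs(config, rng, k)

    chroms, positions = _draw_positions(config, rng)
    ref_idx = rng.integers(0, 4, size=V)
    alt_idx = (ref_idx + rng.integers(1, 4, size=V)) % 4

    labels = config.labels
    drift = config.drift_values()
    fis = config.fis_values()
    subpop_freq: dict[str, np.ndarray] = {}
    sample_ids: list[str] = []
    sample_pops: list[str] = []
    blocks: list[np.ndarray] = []
    groups = list(zip(labels, config.samples_per_subpop, drift, fis))
    if config.n_outgroup > 0:
        groups.append(
            (config.outgroup_label, config.n_outgroup,
             config.outgroup_drift_F, config.outgroup_Fis)
        )
    for label, n, F, f_is in groups:
        if F == 0.0:
            freqs = p_anc.copy()
        else:
            a = p_anc * (1.0 - F) / F
            b = (1.0 - p_anc) * (1.0 - F) / F
            freqs = rng.beta(a, b)
        subpop_freq[label] = freqs
        blocks.append(_genotypes_for_group(freqs, n, f_is, rng))
        sample_ids.extend(f"{label}_{i + 1:02d}" for i in range(n))
        sample_pops.extend([label] * n)

    geno = np.concatenate(blocks, axis=0)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "n_alt": np.ones(V, dtype=np.int8),
        }
    )
    gm = GenotypeMatrix(sample_ids=sample_ids, variants=variants, genotypes=geno)
    gm.validate()
    popmap = PopulationMap(
        sample_to_pop=dict(zip(sample_ids, sample_pops)),
        populations=config.all_pop_labels,
        outgroup=config.outgroup_label if config.n_outgroup > 0 else None,
    )
    truth = SimulationTruth(
        ancestral_freq=p_anc,
        subpop_freq=subpop_freq,
        deleterious_flag=del_flag,
        sift_score=None,
    )
    return gm, popmap, truth


def _target_samples(target: str, popmap: PopulationMap) -> list[str]:
    if target == "study":
        return popmap.study_samples
    if target == "outgroup":
        return popmap.outgroup_samples
    if target in popmap.populations:
        return popmap.samples_of(target)
    raise ValueError(f"unknown sweep target {target!r}")


def plant_sweeps(
    gm: GenotypeMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
    popmap: PopulationMap,
) -> GenotypeMatrix:
    """Drive the target group toward fixation inside each declared window.

    Within a window the target group's genotypes at every variant are
    redrawn from frequency ``sweep_fix_freq`` for the allele that was
    already the group major allele, shrinking within-group diversity
    while leaving the other group untouched.  Windows containing no
    variants are recorded in the truth and logged, not an error.
    """
    if not config.sweep_windows:
        return gm
    rng = _rng(config, _STREAM_SWEEP)
    geno = gm.genotypes.copy()
    chrom = gm.variants["chrom"].to_numpy()
    pos = gm.variants["pos"].to_numpy()
    sample_index = {s: i for i, s in enumerate(gm.sample_ids)}
    for (c, start, end, target) in config.sweep_windows:
        rows = np.array([sample_index[s] for s in _target_samples(target, popmap)])
        # window bp are 0-based half-open; positions are 1-based
        in_win = np.flatnonzero((chrom == c) & (pos - 1 >= start) & (pos - 1 < end))
        rec = {"chrom": c, "start": int(start), "end": int(end),
               "target": target, "n_variants": int(in_win.size)}
        truth.sweep_windows.append(rec)
        if in_win.size == 0:
            logger.warning("sweep window %s:%d-%d contains no variants", c, start, end)
            continue
        sub = geno[np.ix_(rows, in_win)]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0)
        copies = 2 * called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_alt = np.where(copies > 0, alt / np.maximum(copies, 1), 0.5)
        fix_freq = np.where(p_alt >= 0.5, config.sweep_fix_freq, 1.0 - config.sweep_fix_freq)
        new = (
            (rng.random(sub.shape) < fix_freq).astype(np.int8)
            + (rng.random(sub.shape) < fix_freq).astype(np.int8)
        )
        new[sub == MISSING] = MISSING  # preserve missingness pattern
        geno[np.ix_(rows, in_win)] = new
        rec["fix_freq"] = float(config.sweep_fix_freq)
    return GenotypeMatrix(gm.sample_ids, gm.variants, geno)


_TOLERATED_CONSEQUENCES = ("missense_variant", "synonymous_variant", "intron_variant")


def synthesize_annotations(
    gm: GenotypeMatrix,
    truth: SimulationTruth,
    config: SimulationConfig,
    path: str | Path,
) -> pd.DataFrame:
    """Write a VEP-like per-(variant, consequence) SIFT annotation TSV.

    Deleterious variants (per truth) get a SIFT score strictly below the
    configured threshold; others score in [threshold, 1].  A random subset
    of variants gets a second, higher-scoring consequence row to exercise
    the worst-consequence (minimum-score) reduction downstream.
    """
    rng = _rng(config, _STREAM_ANNOT)
    V = gm.n_variants
    flag = truth.deleterious_flag
    if flag is None:
        flag = np.zeros(V, dtype=bool)
    thr = config.sift_threshold
    scores = np.where(
        flag,
        rng.uniform(0.0, max(thr - 1e-6, 0.0), size=V),
        rng.uniform(thr, 1.0, size=V),
    )
    truth.sift_score = scores
    rows = {
        "chrom": gm.variants["chrom"],
        "pos": gm.variants["pos"],
        "ref": gm.variants["ref"],
        "alt": gm.variants["alt"],
        "consequence": np.where(flag, "missense_variant",
                                rng.choice(_TOLERATED_CONSEQUENCES, size=V)),
        "sift_score": np.round(scores, 4),
    }
    ann = pd.DataFrame(rows)
    # extra (tolerated) consequence rows for ~15% of variants
    extra_mask = rng.random(V) < 0.15
    extra = ann[extra_mask].copy()
    extra["consequence"] = "intron_variant"
    extra["sift_score"] = np.round(
        rng.uniform(np.maximum(extra["sift_score"].to_numpy(), thr), 1.0), 4
    )
    ann = (
        pd.concat([ann, extra], ignore_index=True)
        .sort_values(["chrom", "pos", "sift_score"], kind="mergesort")
        .reset_index(drop=True)
    )
    ann.to_csv(path, sep="\t", index=False)
    return ann


def synthesize_genes(
    config: SimulationConfig, path: str | Path, mean_gene_bp: int = 30_000,
    spacing_bp: int = 60_000,
) -> pd.DataFrame:
    """Write a synthetic BED4 gene annotation covering the genome.

    Genes are laid down deterministically (given the seed) at roughly
    ``spacing_bp`` intervals with jittered lengths, giving the sweep stage
    realistic interval-overlap input.
    """
    rng = _rng(config, _STREAM_GENES)
    rows = []
    gid = 0
    for chrom, L in config.genome:
        start = int(rng.integers(0, spacing_bp))
        while start < L - 1000:
            length = int(rng.integers(mean_gene_bp // 3, mean_gene_bp * 2))
            end = min(start + length, L)
            gid += 1
            rows.append((chrom, start, end, f"GENE{gid:05d}"))
            start = end + int(rng.integers(spacing_bp // 3, spacing_bp))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    bed.to_csv(path, sep="\t", index=False, header=False)
    return bed


def simulate_dataset(
    config: SimulationConfig, outdir: str | Path
) -> tuple[GenotypeMatrix, PopulationMap, SimulationTruth]:
    """Run the full generator and write VCF, popmap, annotations, genes, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm, popmap, truth = simulate_metapopulation(config)
    gm = plant_sweeps(gm, truth, config, popmap)
    synthesize_annotations(gm, truth, config, outdir / "annotations.tsv")
    synthesize_genes(config, outdir / "genes.bed")
    write_vcf(gm, outdir / "genotypes.vcf")
    write_population_map(popmap, outdir / "populations.tsv")
    truth.to_json(outdir / "truth.json")
    with open(outdir / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=1, default=list)
        fh.write("\n")
    return gm, popmap, truth


def demo_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The full-scale demonstration design: ~20,000 10-kb windows across 18
    autosomes, 800k SNPs (4 per kb — a scaled-down echo of real
    resequencing density), 20 planted sweeps in the study group."""
    genome = tuple((str(i + 1), 11_110_000) for i in range(18))
    sweeps = []
    for i in range(20):
        chrom = str((i % 18) + 1)
        w = 100 + 45 * i
        sweeps.append((chrom, w * 10_000, (w + 1) * 10_000, "study"))
    defaults = dict(
        n_variants=800_000,
        genome=genome,
        sweep_windows=tuple(sweeps),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
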