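"""Windowed selective-sweep scan: theta-pi, F_ST, Z-scores, top-quantile calls.

Non-overlapping windows (default 10 kb, tiling each chromosome from
position 0, half-open 0-based) are scored with nucleotide diversity per
group, the outgroup/study diversity ratio, and the Hudson F_ST between the
two groups.  Both the F_ST and the ratio columns are Z-transformed over
unmasked windows and a window is called a sweep candidate when it sits in
the top quantile (default 1%) of both, the joint-tail rule used for
domestication scans.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_io import GenotypeMatrix, MISSING, PopulationMap

logger = logging.getLogger(__name__)


def _group_site_stats(gm: GenotypeMatrix, samples: list[str]):
    """Per-site alt copies and called gene copies for a sample group."""
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    rows = np.array([index[s] for s in samples])
    sub = gm.genotypes[rows, :]
    ok = sub != MISSING
    alt = np.where(ok, sub, 0).sum(axis=0).astype(np.float64)
    copies = (2 * ok.sum(axis=0)).astype(np.float64)
    return alt, copies


def pi_per_site(alt: np.ndarray, copies: np.ndarray) -> np.ndarray:
    """Unbiased per-site nucleotide diversity ``2p(1-p) * c/(c-1)``.

    Equals the proportion of differing pairs among all pairs of sampled
    gene copies.  Sites with fewer than two copies are NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / copies
        pi = 2.0 * p * (1.0 - p) * copies / (copies - 1.0)
    return np.where(copies >= 2, pi, np.nan)


def hudson_fst_components(
    alt_a: np.ndarray, copies_a: np.ndarray,
    alt_b: np.ndarray, copies_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson F_ST numerator and denominator.

    N = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1);
    D = pA(1-pB) + pB(1-pA), with nA, nB the called gene-copy counts.
    Sites with fewer than two copies in either group are NaN.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = alt_a / copies_a
        pb = alt_b / copies_b
        num = ((pa - pb) ** 2
               - pa * (1 - pa) / (copies_a - 1.0)
               - pb * (1 - pb) / (copies_b - 1.0))
        den = pa * (1 - pb) + pb * (1 - pa)
    ok = (copies_a >= 2) & (copies_b >= 2)
    return np.where(ok, num, np.nan), np.where(ok, den, np.nan)


def hudson_fst(gm: GenotypeMatrix, samples_a: list[str], samples_b: list[str]) -> float:
    """Genome-wide Hudson F_ST (ratio of averages over all usable sites)."""
    alt_a, cop_a = _group_site_stats(gm, samples_a)
    alt_b, cop_b = _group_site_stats(gm, samples_b)
    num, den = hudson_fst_components(alt_a, cop_a, alt_b, cop_b)
    d = np.nansum(den)
    if d == 0:
        raise ValueError("Hudson F_ST undefined: zero between-group diversity")
    return float(np.nansum(num) / d)


def _window_index(gm: GenotypeMatrix, window_bp: int,
                  chrom_lengths: dict[str, int] | None):
    """Assign each variant to a window and enumerate all windows per chromosome."""
    chrom = gm.variants["chrom"].to_numpy()
    pos0 = gm.variants["pos"].to_numpy() - 1  # 0-based
    win_of_variant = pos0 // window_bp
    chroms = list(dict.fromkeys(chrom))
    frames = []
    for c in chroms:
        sel = chrom == c
        if chrom_lengths and c in chrom_lengths:
            n_win = int(np.ceil(chrom_lengths[c] / window_bp))
        else:
            n_win = int(win_of_variant[sel].max()) + 1 if sel.any() else 0
        frames.append(pd.DataFrame({
            "chrom": c,
            "win": np.arange(n_win),
        }))
    windows = pd.concat(frames, ignore_index=True)
    windows["start"] = windows["win"] * window_bp
    windows["end"] = windows["start"] + window_bp
    return windows, win_of_variant


def _sum_by_window(values: np.ndarray, keys: pd.MultiIndex, windows: pd.DataFrame):
    s = pd.Series(values).groupby([keys.get_level_values(0), keys.get_level_values(1)]).sum()
    s.index.names = ["chrom", "win"]
    return windows.set_index(["chrom", "win"]).index.map(s).to_numpy()


def window_pi(
    gm: GenotypeMatrix, samples: list[str], window_bp: int = 10_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window nucleotide diversity per bp for one sample group.

    theta-pi of a window is the sum of per-site unbiased ``2p(1-p)``
    divided by the window length in bp (so SNP-free windows are 0).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    alt, copies = _group_site_stats(gm, samples)
    pi = pi_per_site(alt, copies)
    windows, win_of = _window_index(gm, window_bp, chrom_lengths)
    keys = pd.MultiIndex.from_arrays([gm.variants["chrom"], win_of])
    pi_sum = _sum_by_window(np.nan_to_num(pi), keys, windows)
    n_snps = _sum_by_window(np.isfinite(pi).astype(float), keys, windows)
    out = windows.copy()
    out["n_snps"] = np.nan_to_num(n_snps).astype(int)
    out["pi"] = np.nan_to_num(pi_sum) / window_bp
    return out[["chrom", "start", "end", "n_snps", "pi"]]


def window_fst(
    gm: GenotypeMatrix, samples_a: list[str], samples_b: list[str],
    window_bp: int = 10_000, chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-window Hudson F_ST (ratio of per-site sums), truncated to [0, 1].

    Windows whose between-group diversity denominator sums to zero are
    masked (NaN).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    alt_a, cop_a = _group_site_stats(gm, samples_a)
    alt_b, cop_b = _group_site_stats(gm, samples_b)
    num, den = hudson_fst_components(alt_a, cop_a, alt_b, cop_b)
    windows, win_of = _window_index(gm, window_bp, chrom_lengths)
    keys = pd.MultiIndex.from_arrays([gm.variants["chrom"], win_of])
    num_sum = np.nan_to_num(_sum_by_window(np.nan_to_num(num), keys, windows))
    den_sum = np.nan_to_num(_sum_by_window(np.nan_to_num(den), keys, windows))
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(den_sum > 0, num_sum / np.maximum(den_sum, 1e-300), np.nan)
    out = windows.copy()
    out["fst"] = np.clip(fst, 0.0, 1.0)
    return out[["chrom", "start", "end", "fst"]]


def zscore(values: np.ndarray | pd.Series, name: str = "statistic") -> np.ndarray:
    """Standardise to mean 0, sample sd 1 (ddof=1); NaN entries propagate."""
    x = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ValueError(f"zscore({name}): need >= 2 finite values")
    sd = np.std(x[finite], ddof=1)
    if sd == 0:
        raise ValueError(f"zscore({name}): zero standard deviation")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - x[finite].mean()) / sd
    return out


def window_scan(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    window_bp: int = 10_000,
    min_snps: int = 10,
    chrom_lengths: dict[str, int] | None = None,
    log2_ratio: bool = False,
) -> pd.DataFrame:
    """Full window statistic table for the study group vs the outgroup.

    The ratio direction is outgroup over study group, so a sweep in the
    study group (locally reduced diversity) raises the ratio.  Windows
    with fewer than ``min_snps`` SNPs, zero study-group diversity, or an
    undefined F_ST are masked and excluded from the Z-transformations.
    """
    if popmap.outgroup is None:
        raise ValueError("window_scan needs a designated outgroup")
    study = popmap.study_samples
    out_s = popmap.outgroup_samples
    pi_study = window_pi(gm, study, window_bp, chrom_lengths)
    pi_out = window_pi(gm, out_s, window_bp, chrom_lengths)
    fst = window_fst(gm, study, out_s, window_bp, chrom_lengths)
    table = pi_study.rename(columns={"pi": "pi_study"}).copy()
    table["pi_outgroup"] = pi_out["pi"].to_numpy()
    table["fst"] = fst["fst"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = table["pi_outgroup"].to_numpy() / table["pi_study"].to_numpy()
    table["pi_ratio"] = np.where(table["pi_study"].to_numpy() > 0, ratio, np.nan)
    masked = (
        (table["n_snps"].to_numpy() < min_snps)
        | ~np.isfinite(table["pi_ratio"].to_numpy())
        | ~np.isfinite(table["fst"].to_numpy())
    )
    table["masked"] = masked
    ratio_stat = table["pi_ratio"].to_numpy().copy()
    if log2_ratio:
        ratio_stat = np.log2(ratio_stat)
    fst_stat = table["fst"].to_numpy().copy()
    ratio_stat[masked] = np.nan
    fst_stat[masked] = np.nan
    table["z_fst"] = zscore(fst_stat, "F_ST")
    table["z_ratio"] = zscore(ratio_stat, "theta-pi ratio")
    return table


@dataclass
class SweepCallSet:
    """Top-quantile intersection calls with merged intervals."""

    candidates: pd.DataFrame
    merged: pd.DataFrame
    quantile: float
    thresholds: dict[str, float] = field(default_factory=dict)
    genes: pd.DataFrame | None = None


def _merge_adjacent(cand: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, sub in cand.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        cur_s, cur_e = None, None
        for _, r in sub.iterrows():
            if cur_s is None:
                cur_s, cur_e = r["start"], r["end"]
            elif r["start"] <= cur_e:
                cur_e = max(cur_e, r["end"])
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = r["start"], r["end"]
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def call_sweeps(
    table: pd.DataFrame, quantile: float = 0.99, union: bool = False
) -> SweepCallSet:
    """Call windows in the joint upper tail of Z_FST and Z_ratio.

    Thresholds are empirical order statistics over unmasked windows
    (inclusive: ties at the cutoff are admitted).  The default rule is
    the intersection of the two top-quantile sets; ``union=True`` relaxes
    to either tail.
    """
    unmasked = ~table["masked"].to_numpy()
    n = int(unmasked.sum())
    if n < 100:
        logger.warning("only %d unmasked windows; top-quantile cutoff unstable", n)
    if n == 0:
        raise ValueError("no unmasked windows to call from")
    thr_fst = float(np.quantile(table.loc[unmasked, "z_fst"], quantile, method="higher"))
    thr_ratio = float(np.quantile(table.loc[unmasked, "z_ratio"], quantile, method="higher"))
    in_fst = unmasked & (table["z_fst"].to_numpy() >= thr_fst)
    in_ratio = unmasked & (table["z_ratio"].to_numpy() >= thr_ratio)
    called = (in_fst | in_ratio) if union else (in_fst & in_ratio)
    cand = table.loc[called].copy()
    cand["in_top_fst"] = in_fst[called]
    cand["in_top_ratio"] = in_ratio[called]
    return SweepCallSet(
        candidates=cand.reset_index(drop=True),
        merged=_merge_adjacent(cand),
        quantile=quantile,
        thresholds={"z_fst": thr_fst, "z_ratio": thr_ratio},
    )


def read_bed4(path) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                      dtype={0: str})
    return bed


_GFF_ID_RE = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene records of a GFF3 as half-open 0-based intervals."""
    gff = pd.read_csv(path, sep="\t", header=None, comment="#",
                      names=["chrom", "source", "type", "start", "end",
                             "score", "strand", "frame", "attr"],
                      dtype={0: str})
    genes = gff[gff["type"] == "gene"].copy()
    genes["name"] = genes["attr"].map(
        lambda a: (m.group(1) if (m := _GFF_ID_RE.search(a)) else a)
    )
    genes["start"] = genes["start"].astype(int) - 1  # GFF is 1-based inclusive
    return genes[["chrom", "start", "end", "name"]].reset_index(drop=True)


def annotate_windows(calls: SweepCallSet, annotation: pd.DataFrame) -> pd.DataFrame:
    """Overlap candidate windows with gene intervals (>= 1 bp, half-open).

    Returns one row per (window, gene) overlap; the deduplicated gene list
    is attached to ``calls.genes``.  Raises when the annotation and the
    windows share no chromosome names.
    """
    cand = calls.candidates
    if len(cand) and len(annotation):
        shared = set(cand["chrom"]) & set(annotation["chrom"])
        if not shared:
            raise ValueError(
                "no chromosome names shared between windows "
                f"({sorted(set(cand['chrom']))[:5]}...) and annotation "
                f"({sorted(set(annotation['chrom']))[:5]}...)"
            )
    rows = []
    for chrom, sub in cand.groupby("chrom", sort=False):
        genes_c = annotation[annotation["chrom"] == chrom]
        if genes_c.empty:
            continue
        gs = genes_c["start"].to_numpy()
        ge = genes_c["end"].to_numpy()
        for _, w in sub.iterrows():
            hit = (gs < w["end"]) & (ge > w["start"])  # half-open overlap
            for name in genes_c.loc[hit, "name"]:
                rows.append((chrom, int(w["start"]), int(w["end"]), name))
    overlaps = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    calls.genes = (
        overlaps[["gene"]].drop_duplicates().reset_index(drop=True)
        if len(overlaps)
        else pd.DataFrame(columns=["gene"])
    )
    return overlaps
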