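"""Deleterious-variant classification, frequency spectra and set intersections.

SIFT scores predict substitution tolerance on [0, 1]; scores near 0 mark
putatively deleterious variants (operationalised here as score < 0.05,
the standard SIFT convention, configurable).  A variant may carry several
transcript consequences; the minimum score across them (worst
consequence) decides its class.  Downstream summaries are the pooled
site-frequency spectrum of the deleterious set and, per population,
presence/absence intersection counts (UpSet-style).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import AlleleFrequencyTable, allele_frequencies
from .variant_io import GenotypeMatrix, MISSING, PopulationMap

logger = logging.getLogger(__name__)

DEFAULT_SIFT_THRESHOLD = 0.05

_PURINES = {"A", "G"}

_VEP_SIFT_RE = re.compile(r"SIFT=(?:[a-z_]+\(([0-9.]+)\)|([0-9.]+))")


def mutation_class(ref: str, alt: str) -> str:
    """"transition" (purine<->purine or pyrimidine<->pyrimidine) or
    "transversion" (purine<->pyrimidine)."""
    return "transition" if (ref in _PURINES) == (alt in _PURINES) else "transversion"


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a per-(variant, consequence) SIFT annotation table.

    Two dialects are accepted:

    * the minimal TSV written by the simulator, with a header line
      ``chrom  pos  ref  alt  consequence  sift_score``;
    * VEP's tab output (``#Uploaded_variation  Location  Allele ...``)
      with ``SIFT=deleterious(0.01)``-style entries in the Extra column,
      where ref/alt are recovered from the uploaded-variation identifier
      ``chrom_pos_ref/alt``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#Uploaded_variation"):
        return _read_vep_tab(path)
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "consequence", "sift_score"}
    missing = required - set(ann.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return ann


def _read_vep_tab(path: Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    raw.columns = [c.lstrip("#") for c in raw.columns]
    rows = []
    for i, r in raw.iterrows():
        m = re.match(r"(.+)_(\d+)_([ACGT]+)/([ACGT]+)$", str(r["Uploaded_variation"]))
        if not m:
            raise ValueError(f"{path}: row {i + 2}: unparseable variant id "
                             f"{r['Uploaded_variation']!r}")
        sift = np.nan
        extra = str(r.get("Extra", ""))
        sm = _VEP_SIFT_RE.search(extra)
        if sm:
            sift = float(sm.group(1) or sm.group(2))
        rows.append((m.group(1), int(m.group(2)), m.group(3), m.group(4),
                     r.get("Consequence", "."), sift))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                       "consequence", "sift_score"])


def classify_deleterious(
    annotations: pd.DataFrame, threshold: float = DEFAULT_SIFT_THRESHOLD
) -> pd.DataFrame:
    """One row per variant with its minimum SIFT score and deleterious flag.

    Deleterious iff min score < threshold (strict).  Rows without a score
    are kept but can never be deleterious.  Scores outside [0, 1] raise
    with the offending row number.
    """
    s = annotations["sift_score"]
    bad = s.notna() & ((s < 0) | (s > 1))
    if bad.any():
        raise ValueError(
            f"SIFT score outside [0, 1] at annotation rows {list(annotations.index[bad][:5])}"
        )
    grouped = (
        annotations.sort_values("sift_score", na_position="last", kind="mergesort")
        .groupby(["chrom", "pos", "ref", "alt"], sort=False, as_index=False)
        .first()
    )
    grouped = grouped.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    grouped["deleterious"] = grouped["sift_score"].notna() & (grouped["sift_score"] < threshold)
    grouped["mutation_class"] = [
        mutation_class(r, a) if len(r) == 1 and len(a) == 1 else "other"
        for r, a in zip(grouped["ref"], grouped["alt"])
    ]
    return grouped


def _match_variants(table: pd.DataFrame, gm: GenotypeMatrix) -> np.ndarray:
    """Indices into gm.variants for each table row; -1 where unmatched."""
    key = pd.MultiIndex.from_arrays(
        [gm.variants["chrom"], gm.variants["pos"], gm.variants["ref"], gm.variants["alt"]]
    )
    lookup = pd.Series(np.arange(gm.n_variants), index=key)
    probe = pd.MultiIndex.from_arrays(
        [table["chrom"], table["pos"], table["ref"], table["alt"]]
    )
    idx = lookup.reindex(probe).to_numpy()
    return np.where(np.isnan(idx), -1, idx).astype(int)


def frequency_spectrum(
    table: pd.DataFrame,
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    bins: np.ndarray | None = None,
    pooled: bool = True,
) -> pd.DataFrame:
    """Site-frequency spectrum of deleterious variants.

    Alternate-allele frequency is computed over the pooled study samples
    (outgroup excluded); bins are left-closed with default width 0.05.
    Also tabulated per mutation class.  An empty deleterious set yields an
    all-zero spectrum with a warning.
    """
    if bins is None:
        bins = np.round(np.arange(0.0, 1.0 + 1e-9, 0.05), 10)
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    dele = table[table["deleterious"]]
    samples = popmap.study_samples if pooled else gm.sample_ids
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    rows = np.array([index[s] for s in samples])
    sub = gm.genotypes[rows, :]
    ok = sub != MISSING
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(ok, sub, 0).sum(axis=0) / np.maximum(2 * ok.sum(axis=0), 1)
    labels = [f"[{bins[i]:.2f},{bins[i + 1]:.2f})" for i in range(len(bins) - 1)]
    classes = ["transition", "transversion"]
    counts = {c: np.zeros(len(labels), dtype=int) for c in ["all"] + classes}
    if dele.empty:
        logger.warning("frequency_spectrum: empty deleterious set")
    else:
        vidx = _match_variants(dele, gm)
        matched = vidx >= 0
        if not matched.all():
            logger.warning("frequency_spectrum: %d deleterious variants not in the "
                           "genotype matrix", int((~matched).sum()))
        f = freq[vidx[matched]]
        # left-closed bins; the final edge is inclusive so frequency 1.0 counts
        which = np.clip(np.digitize(f, bins, right=False) - 1, 0, len(labels) - 1)
        np.add.at(counts["all"], which, 1)
        mc = dele.loc[matched, "mutation_class"].to_numpy()
        for c in classes:
            np.add.at(counts[c], which[mc == c], 1)
    out = pd.DataFrame({"bin": labels})
    for c in ["all"] + classes:
        out[c] = counts[c]
    return out


def presence_matrix(
    table: pd.DataFrame, gm: GenotypeMatrix, popmap: PopulationMap,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Deleterious variants x populations presence flags (alt count > 0)."""
    pops = populations if populations is not None else popmap.analysis_populations
    freqs = allele_frequencies(gm, popmap, pops)
    dele = table[table["deleterious"]]
    vidx = _match_variants(dele, gm)
    keep = vidx >= 0
    present = (freqs.alt_copies[:, vidx[keep]] > 0).T
    return pd.DataFrame(present, columns=pops,
                        index=dele.index[keep]).astype(bool)


def intersection_sets(
    table: pd.DataFrame, gm: GenotypeMatrix, popmap: PopulationMap,
    populations: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact-subset (UpSet) counts of deleterious-variant presence.

    Returns ``(subset_counts, per_population)``: for every population
    subset observed, the number of deleterious variants present in exactly
    that subset (these partition the variants present anywhere); and per
    population its total and population-specific counts.
    """
    pres = presence_matrix(table, gm, popmap, populations)
    pops = list(pres.columns)
    codes = pres.to_numpy() @ (1 << np.arange(len(pops)))
    rows = []
    for code, count in zip(*np.unique(codes, return_counts=True)):
        if code == 0:
            continue  # absent everywhere (e.g. only in the outgroup)
        members = [p for b, p in enumerate(pops) if code >> b & 1]
        rows.append({"subset": ",".join(members), "size": len(members),
                     "count": int(count),
                     **{p: (p in members) for p in pops}})
    if rows:
        subsets = pd.DataFrame(rows).sort_values("count", ascending=False).reset_index(drop=True)
    else:
        subsets = pd.DataFrame(columns=["subset", "size", "count", *pops])
    per_pop = pd.DataFrame(
        {
            "total": pres.sum(axis=0),
            "specific": [
                int(((codes == (1 << i))).sum()) for i in range(len(pops))
            ],
        },
        index=pops,
    )
    return subsets, per_pop
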