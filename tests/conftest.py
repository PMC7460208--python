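from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from popkit.variant_io import GenotypeMatrix, PopulationMap


def make_gm(
    dosages,
    chroms=None,
    positions=None,
    sample_ids=None,
    ref=None,
    alt=None,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (samples x variants) dosage array."""
    geno = np.asarray(dosages, dtype=np.int8)
    n, v = geno.shape
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if chroms is None:
        chroms = ["1"] * v
    if positions is None:
        positions = np.arange(1, v + 1) * 100
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": ref if ref is not None else ["A"] * v,
            "alt": alt if alt is not None else ["G"] * v,
            "n_alt": np.ones(v, dtype=np.int8),
        }
    )
    gm = GenotypeMatrix(sample_ids=list(sample_ids), variants=variants, genotypes=geno)
    gm.validate()
    return gm


def make_popmap(assignments: dict[str, list[str]], outgroup=None) -> PopulationMap:
    s2p = {s: p for p, samples in assignments.items() for s in samples}
    return PopulationMap(sample_to_pop=s2p, populations=list(assignments), outgroup=outgroup)


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated dataset shared across tests (session-scoped)."""
    from popkit.simdata import SimulationConfig, simulate_metapopulation

    cfg = SimulationConfig(
        n_variants=5_000,
        genome=(("1", 2_000_000), ("2", 2_000_000)),
        seed=42,
    )
    gm, popmap, truth = simulate_metapopulation(cfg)
    return cfg, gm, popmap, truth
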