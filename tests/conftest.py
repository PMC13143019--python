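"""Shared fixtures: small simulated datasets and toy genome layouts.

All fixtures are generated programmatically and seeded; the session-scoped
simulation fixtures are reused across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import hybarrier as hb
from hybarrier import simulate
from hybarrier.ancestry import AncestryMatrix
from hybarrier.intervals import GenomeLayout, IntervalSet


def small_config(**kw) -> hb.SimConfig:
    """A reduced forward-simulation configuration for unit tests."""
    base = dict(
        n_chromosomes=4,
        n_sites=60,
        chrom_length_bp=1_000_000,
        n_hybrid_males=80,
        pop_size=300,
        generations=8,
        prop_fixed_diff=0.8,
        seed=11,
    )
    base.update(kw)
    return hb.SimConfig(**base)


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """A small end-to-end dataset on disk (VCFs, annotations, truth)."""
    outdir = tmp_path_factory.mktemp("simdata")
    cfg = small_config(
        missing_rate=0.02,
        bdmi_spec=[hb.BdmiPair((0, 30), (1, 30), (0, 1), 1.0)],
    )
    return cfg, simulate.simulate_dataset(cfg, outdir, n_diploid_females=3)


@pytest.fixture(scope="session")
def truth_matrix(sim_dataset):
    """Ancestry truth of the sampled males as an AncestryMatrix."""
    cfg, out = sim_dataset
    return AncestryMatrix(
        out.population.sample_ids,
        out.panels.sites[["chrom", "pos"]].copy(),
        out.population.ancestry.astype(np.int8),
    )


@pytest.fixture
def toy_layout():
    return GenomeLayout(
        {"chr1": 10_000, "chr2": 8_000},
        centromeres={"chr1": (4_000, 4_400), "chr2": (1_000, 1_200)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_intervals(rng, layout: GenomeLayout, n: int, max_len: int = 800) -> IntervalSet:
    """Random (possibly overlapping) intervals across a layout."""
    rows = []
    chroms = list(layout.chrom_lengths)
    for _ in range(n):
        c = chroms[rng.integers(len(chroms))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, layout.chrom_lengths[c] - length))
        rows.append((c, start, start + length))
    return IntervalSet.from_records(rows)


def coverage_mask(ivs: IntervalSet, layout: GenomeLayout) -> dict[str, np.ndarray]:
    """Per-base boolean occupancy — the independent oracle for interval ops."""
    masks = {c: np.zeros(L, dtype=bool) for c, L in layout.chrom_lengths.items()}
    for r in ivs.df.itertuples(index=False):
        masks[r.chrom][r.start : r.end] = True
    return masks


def matrix_from_array(data: np.ndarray, positions=None, chrom="chr1") -> AncestryMatrix:
    """Wrap a raw {0,1,-1} array as an AncestryMatrix on one chromosome."""
    n, m = data.shape
    pos = positions if positions is not None else np.arange(m) * 100 + 100
    sites = pd.DataFrame({"chrom": [chrom] * m, "pos": pos})
    return AncestryMatrix([f"s{i}" for i in range(n)], sites, data.astype(np.int8))
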