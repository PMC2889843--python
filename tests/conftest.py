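import numpy as np
import pytest

from founderage.genmap import Marker, build_marker_map
from founderage.haplotypes import AlleleFrequencies, AncestralHaplotype
from founderage.synthetic_data import (
    SimConfig,
    SimulationError,
    evenly_spaced_snp_map,
    random_snp_pool,
    simulate_dataset,
)


@pytest.fixture
def three_marker_map():
    """Markers at 0.5 / 1.0 / 2.0 Mb distal of the locus, 1 cM/Mb."""
    markers = [
        Marker("m1", 500_000, "snp", ("A", "a"), 0.0),
        Marker("m2", 1_000_000, "snp", ("B", "b"), 0.0),
        Marker("m3", 2_000_000, "snp", ("C", "c"), 0.0),
    ]
    return build_marker_map(markers, 0, cm_per_mb=1.0)


@pytest.fixture
def one_marker_scene():
    """Single marker at exactly theta = 0.01 (linear map), p_N(anc) = 0.1."""
    mk = Marker("m1", 1_000_000, "snp", ("A", "B"), 0.0)
    mmap = build_marker_map([mk], 0, cm_per_mb=1.0, map_function="linear")
    anc = AncestralHaplotype(("A",), np.array([1.0]))
    freqs = AlleleFrequencies(
        control=[{"A": 0.1, "B": 0.9}], carrier=[{"A": 1.0, "B": 0.0}]
    )
    return mmap, anc, freqs


@pytest.fixture
def msh2_like_map():
    """19 SNP markers evenly spanning 12.3 Mb, locus midway, 1 cM/Mb."""
    return evenly_spaced_snp_map(19, 12_300_000)


def simulate_conditioned(mmap, *, g_true, r, n_cases, n_controls, seed,
                         genealogy="branching", maf_range=(0.2, 0.8),
                         max_tries=50):
    """Simulate one dataset, retrying fresh seeds until the conditioned
    branching population can supply n_cases carriers."""
    for k in range(max_tries):
        rng = np.random.default_rng(seed + 77_777 * k)
        pool = random_snp_pool(mmap, rng, maf_range)
        cfg = SimConfig(
            g_true=g_true,
            r=r,
            n_cases=n_cases,
            n_controls=n_controls,
            marker_map=mmap,
            background_pool=pool,
            seed=seed + 77_777 * k + 1,
            genealogy=genealogy,
        )
        try:
            ds, truth = simulate_dataset(cfg)
        except SimulationError:
            continue
        return ds, truth, pool
    raise RuntimeError("could not condition the simulation")
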