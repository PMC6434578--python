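import numpy as np
import pytest

from hybridassign import (
    LocalAncestryHMM,
    MarkerMap,
    PanelSpec,
    make_marker_map,
    simulate_panels,
)
from hybridassign.synthetic import Chromosome


@pytest.fixture(scope="session")
def small_map():
    """Two chromosomes, 120 SNPs each, ~1 Morgan scale."""
    return make_marker_map([120, 120], [5_000_000, 4_000_000], [1.0, 0.8], seed=11)


@pytest.fixture(scope="session")
def perfect_panel(small_map):
    """Fixed-difference ('perfect marker') parental panel on small_map."""
    spec = PanelSpec(n_pop_a=20, n_pop_b=20, target_fst=0.01,
                     diag_fraction=1.0, diag_delta=1.0, seed=21)
    panel, ga, gb, _ = simulate_panels(small_map, spec)
    return panel, ga, gb


@pytest.fixture(scope="session")
def lowfst_panel(small_map):
    """Weakly differentiated panel (target FST 0.01, no diagnostic SNPs)."""
    spec = PanelSpec(n_pop_a=30, n_pop_b=30, target_fst=0.01,
                     diag_fraction=0.0, seed=22)
    panel, ga, gb, _ = simulate_panels(small_map, spec)
    return panel, ga, gb


@pytest.fixture(scope="session")
def perfect_hmm(perfect_panel):
    return LocalAncestryHMM().fit(perfect_panel[0])


def single_chrom_map(n_snps=60, length_bp=1_000_000, length_morgan=1.0, seed=5):
    return make_marker_map([n_snps], [length_bp], [length_morgan], seed=seed)


def manual_map(positions_bp, length_bp=100, length_morgan=1.0, name="c"):
    return MarkerMap(
        [Chromosome(name, length_bp, length_morgan)],
        {name: np.asarray(positions_bp, dtype=np.int64)},
    )
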