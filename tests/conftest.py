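import numpy as np
import pytest

from ovipop import simulate
from ovipop._util import decode
from ovipop.genotypes import GenotypeTable
from ovipop.mthap import synthetic_diagnostic_table


@pytest.fixture(scope="session")
def small_ref():
    """Miniature reference at 1% scale (~490 kb + full-length MT)."""
    return simulate.build_reference(scale=0.01, seed=3)


@pytest.fixture(scope="session")
def diag_table(small_ref):
    return synthetic_diagnostic_table(decode(small_ref.chromosome("MT").seq))


@pytest.fixture(scope="session")
def scaled_layout():
    return simulate.reference_layout(scale=0.01)


def combine_tables(*tables) -> GenotypeTable:
    """Concatenate genotype tables that share one panel object."""
    first = tables[0]
    return GenotypeTable(
        first.panel,
        sum((list(t.ids) for t in tables), []),
        sum((list(t.populations) for t in tables), []),
        np.concatenate([t.ploidy for t in tables]),
        np.concatenate([t.data for t in tables], axis=0),
    )


def canonical_dataset(seed, side="west", n_snps=20_000, n_per_pop=20,
                      missing_rate=0.6, n_west=1, n_east=1):
    """Simulated modern + ancient dataset under the canonical tree.

    Returns (combined table, modern-only table, ancient population label, panel).
    """
    cfg = simulate.SimulationConfig(n_snps=n_snps, seed=seed)
    tree = simulate.canonical_tree(n_west=n_west, n_east=n_east)
    freqs = simulate.simulate_frequencies(tree, cfg)
    panel = simulate.build_panel(cfg)
    rng = np.random.default_rng(seed + 1_000_003)
    modern_pops = ["outgroup"] + [c for c in freqs.columns
                                  if c.startswith(("west", "east"))]
    modern = simulate.draw_genotypes(freqs, panel, "diploid", cfg, rng=rng,
                                     populations=modern_pops,
                                     n_per_pop=n_per_pop)
    ancient = simulate.draw_genotypes(freqs, panel, "pseudohaploid", cfg,
                                      rng=rng, populations=[f"ancient_{side}"],
                                      missing_rate=missing_rate)
    combined = combine_tables(modern, ancient)
    return combined, modern, f"ancient_{side}", panel
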