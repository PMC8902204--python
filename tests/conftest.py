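import numpy as np
import pytest

from f2qtl.experiment import make_config, run_scenario_grid, simulate_lineage
from f2qtl.genome import build_genome_map


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome map: 40 markers, a handful of QTLs."""
    return build_genome_map(2, [100.0, 300.0], 40, 4,
                            np.random.default_rng(7))


def toy_config(**overrides):
    """A minutes-scale configuration preserving the full phase structure."""
    base = dict(
        n_markers=300, n_qtl=10,
        hp_phase1_generations=8, hp_phase1_size=150,
        hp_phase2_generations=4, hp_phase2_end_size=120,
        line_males=3, line_females=20, line_generations=3,
        f1_males=4, f1_females=40, f1_generations=2,
        f2_males=5, f2_females=50, f2_generations=3,
        rp_generations=(2, 3), rp_sizes=(50,), h2_levels=(0.3,),
        replicates=1,
    )
    base.update(overrides)
    return make_config("mini", **base)


@pytest.fixture(scope="session")
def toy_lineage():
    return simulate_lineage(toy_config(seed=42), replicate=0)


@pytest.fixture(scope="session")
def grid_11():
    """Eleven desk-profile replicates of the full RP x h2 grid (shared by the
    detection-count, monotonicity and heritability-recovery checks)."""
    cfg = make_config("desk", seed=1, replicates=11)
    grid, reports = run_scenario_grid(cfg)
    return cfg, grid, reports
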