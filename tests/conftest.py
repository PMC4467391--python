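from pathlib import Path

import pytest

from cnevolve import simulate as sim
from cnevolve.pipeline import analyze_sample
from cnevolve.progression import SampleEventSet

DATA = Path(__file__).resolve().parent.parent / "data"

PURITY = {"dcis1": 0.8, "dcis2": 0.8, "primary": 0.8, "metastasis": 0.9}


@pytest.fixture(scope="session")
def event_table_path() -> Path:
    return DATA / "progression_events.tsv"


@pytest.fixture(scope="session")
def scenario() -> sim.Scenario:
    return sim.four_stage_scenario()


@pytest.fixture(scope="session")
def sim_data(scenario):
    """Window counts + SNP depths for the four-stage scenario (fixed seed)."""
    counts = sim.simulate_counts(
        scenario.tree, scenario.events, depth=1000, window_bp=50_000,
        genome=scenario.genome, seed=11,
    )
    snps = sim.simulate_snp_counts(
        scenario.tree, scenario.events, n_sites=4000, depth=80,
        genome=scenario.genome, seed=12,
    )
    return counts, snps


@pytest.fixture(scope="session")
def analyzed(scenario, sim_data):
    """Per-sample (track, segments, events) for the four-stage scenario."""
    counts, snps = sim_data
    out = {}
    for s in scenario.stage_order:
        out[s] = analyze_sample(counts[s].windows, snps[s], PURITY[s], sample=s)
    return out


@pytest.fixture(scope="session")
def event_sets(scenario, analyzed):
    return [SampleEventSet(s, analyzed[s][2]) for s in scenario.stage_order]
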