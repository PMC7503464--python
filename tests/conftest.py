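import numpy as np
import pytest

from trelax import (
    KineticScenario,
    fit_double_exponential,
    generate_transient,
    preprocess_transient,
)
from trelax.io import replicate_seeds


@pytest.fixture(scope="session")
def wt_scenario() -> KineticScenario:
    """Default wild-type-anchored noisy titration scenario."""
    return KineticScenario(seed=1)


@pytest.fixture(scope="session")
def noiseless_scenario() -> KineticScenario:
    return KineticScenario(noise_sd=0.0)


def run_titration(scenario: KineticScenario):
    """Generate and fit the full replicates-by-concentrations design."""
    seeds = replicate_seeds(scenario.seed,
                            len(scenario.ligand_totals) * scenario.replicates)
    records, fits = [], []
    i = 0
    for conc in scenario.ligand_totals:
        for rep in range(1, scenario.replicates + 1):
            rec = generate_transient(scenario, conc, seeds[i], replicate=rep,
                                     label=f"L{conc:g}_r{rep}")
            records.append(rec)
            fits.append(fit_double_exponential(preprocess_transient(rec)))
            i += 1
    return records, fits


@pytest.fixture(scope="session")
def wt_titration(wt_scenario):
    """Records and fits of the 5 concentrations x 5 replicates design."""
    return run_titration(wt_scenario)
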