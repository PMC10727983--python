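import warnings

import numpy as np
import pandas as pd
import pytest

from cfrepeat import annotation, quantify, synthetic

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def toy_cfg():
    return synthetic.SimulationConfig(
        seed=7, n_healthy=10, n_case=10, n_genes=12, n_subfamilies=3, instances_per_subfamily=4
    )


@pytest.fixture(scope="session")
def toy_genome(toy_cfg):
    return synthetic.make_toy_genome(toy_cfg)


@pytest.fixture(scope="session")
def aware_catalog(toy_genome):
    return annotation.build_catalog(toy_genome.genes, toy_genome.instances, "repeat_aware")


@pytest.fixture(scope="session")
def cohort(toy_cfg, aware_catalog):
    """Planted NB cohort: rmsk:Alu_sf0 up at log2fc=2."""
    cfg = synthetic.SimulationConfig(
        seed=11,
        n_healthy=25,
        n_case=25,
        n_genes=12,
        n_subfamilies=3,
        instances_per_subfamily=4,
        planted_up=[("rmsk:Alu_sf0", 2.0)],
        dispersion=0.2,
    )
    matrix, metadata, truth = synthetic.simulate_counts(aware_catalog, cfg)
    return matrix, metadata, truth


def make_rmsk_text(rows):
    header = "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n"
    return header + "".join("\t".join(map(str, r)) + "\n" for r in rows)
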