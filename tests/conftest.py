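import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gutferm as gf

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """Bundled printed qPCR means (11 taxa x 10 conditions) + printed F/B."""
    return gf.load_table1()


@pytest.fixture(scope="session")
def sim_slow():
    """One slow-prebiotic synthetic experiment with ground truth."""
    cfg = gf.scenario_config("prebiotic_slow", seed=7)
    return gf.simulate_fermentation(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_taxa_table(values: dict[str, float], treatment="FLS", time_h=24.0,
                    n_rep=1) -> gf.TaxonAbundanceTable:
    """Single-condition taxa table from a taxon -> Log10 load mapping."""
    rows = [dict(taxon=t, treatment=treatment, time_h=time_h,
                 experiment=1, replicate=r + 1, log10_gcn=v)
            for t, v in values.items() for r in range(n_rep)]
    return gf.TaxonAbundanceTable(pd.DataFrame(rows))


def make_voc_table(values: dict[str, dict[tuple[str, float], list[float]]],
                   unit="mg_per_kg") -> gf.VocTable:
    """VOC table from compound -> {(treatment, time): replicate values}."""
    rows = []
    for compound, conds in values.items():
        for (tr, th), reps in conds.items():
            for i, v in enumerate(reps):
                rows.append(dict(compound=compound, treatment=tr, time_h=th,
                                 experiment=1 + i // 2, replicate=1 + i % 2,
                                 value=float(v), detected=True))
    return gf.VocTable(pd.DataFrame(rows), unit=unit)
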