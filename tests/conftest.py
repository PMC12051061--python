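import numpy as np
import pytest

import sensomics as sm


@pytest.fixture(scope="session")
def default_world():
    """The package's default synthetic scenario at the canonical demo seed:
    50 fractions, 300 compounds/features, 3 planted taste-actives,
    12 panelists with unit score noise."""
    gt = sm.generate_ground_truth(300, 50, 3, seed=1)
    ft = sm.simulate_feature_table(gt)
    records = sm.simulate_taste_records(gt, ft)
    cmap = {s: c for c, ss in gt.panel.synonym_table.items() for s in ss}
    mapped = sm.map_descriptors(records, cmap)
    kept = sm.consensus_filter(mapped, 2)
    tp = sm.aggregate_profile(
        kept, fractions=gt.fraction_ids, categories=sorted(gt.panel.categories)
    )
    return gt, ft, records, tp


@pytest.fixture(scope="session")
def default_report(default_world):
    gt, ft, _, tp = default_world
    return sm.run_correlation(ft, tp)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
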