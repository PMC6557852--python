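import numpy as np
import pytest

import moultclim as mc
from moultclim.simulate import BASE_TRACT_AREAS


@pytest.fixture(scope="session")
def layout():
    return mc.default_layout()


@pytest.fixture(scope="session")
def areas_one(layout):
    """Single-species area table using the generator's baseline tract areas."""
    return mc.TractAreaTable(
        {("spA", t.name): BASE_TRACT_AREAS[t.name] for t in layout.tracts}
    )


@pytest.fixture(scope="session")
def make_record(layout):
    """Factory for records; defaults to nothing moulted."""

    def _make(
        species="spA",
        year=1900,
        sex="unknown",
        scores=None,
        lc=0.0,
        mc_prop=0.0,
        specimen_id="s1",
    ):
        feather_scores = {label: 0 for label in layout.discrete_labels}
        if scores:
            feather_scores.update(scores)
        return mc.MoultRecord(
            specimen_id=specimen_id,
            species_id=species,
            collection_year=year,
            sex=sex,
            feather_scores=feather_scores,
            lc_proportion=lc,
            mc_proportion=mc_prop,
        )

    return _make


@pytest.fixture(scope="session")
def random_records(layout, make_record):
    """100 records with random scores, proportions and scattered missing
    feathers, for oracle comparisons."""
    rng = np.random.default_rng(2024)
    records = []
    for i in range(100):
        scores = {}
        for label in layout.discrete_labels:
            u = rng.random()
            scores[label] = None if u < 0.08 else int(u > 0.5)
        # guard against a fully-missing tract
        for tract in mc.default_layout().tracts:
            if tract.labels and all(scores[l] is None for l in tract.labels):
                scores[tract.labels[0]] = 1
        records.append(
            make_record(
                scores=scores,
                lc=float(rng.random()),
                mc_prop=float(rng.random()),
                specimen_id=f"r{i}",
            )
        )
    return records


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset reused across tests."""
    return mc.simulate_dataset(mc.SyntheticConfig(n_species=6, n_specimens=60, seed=7))
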