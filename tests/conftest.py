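import numpy as np
import pytest

from anticipation import CarrierRecord, build_design, generate_cohort
from anticipation.simulate import CohortConfig


def make_carrier(family_id="F1", person_id="p1", sex="female", gene="MLH1",
                 generation=0, age=50.0, event=True, **kw):
    return CarrierRecord(
        family_id=family_id, person_id=person_id, sex=sex, raw_gene=gene,
        generation_depth=generation, age=age, event=event, **kw,
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One simulated study-scale cohort (239 families, NREM generative law)."""
    cfg = CohortConfig(seed=20250101)
    carriers, families = generate_cohort(cfg)
    return cfg, carriers, families


@pytest.fixture(scope="session")
def default_design(default_cohort):
    _, carriers, _ = default_cohort
    return build_design(carriers)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
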