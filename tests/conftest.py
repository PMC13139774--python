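import numpy as np
import pytest

from mscontab.records import MutationRecord, filter_records
from mscontab.signatures import build_feature_views
from mscontab.synth import SynthConfig, generate_dataset


def make_record(
    cohort="C0", sample_id="S0", gene="TP53", chromosome="17",
    position=7674220, ref="C", alt="T", coding_flag=True,
) -> MutationRecord:
    return MutationRecord(cohort=cohort, sample_id=sample_id, gene=gene,
                          chromosome=chromosome, position=position,
                          ref=ref, alt=alt, coding_flag=coding_flag)


@pytest.fixture(scope="session")
def small_dataset():
    """12 planted-cluster cohorts at reduced burden (fast unit-test scale)."""
    cfg = SynthConfig(n_cohorts=12, burden=(600.0, 300.0), seed=5)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_views(small_dataset):
    retained, _ = filter_records(small_dataset.records)
    return build_feature_views(retained)


@pytest.fixture(scope="session")
def small_truth(small_dataset, small_views):
    return small_dataset.labels_array(small_views.cohorts)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
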