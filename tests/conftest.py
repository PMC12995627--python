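import numpy as np
import pandas as pd
import pytest

from pyrosig import ExpressionMatrix, SyntheticConfig, generate_cohort, load_paper_fixture
from pyrosig.registry import SUBTYPES


@pytest.fixture(scope="session")
def table2():
    return load_paper_fixture("table2").table


@pytest.fixture(scope="session")
def table5():
    return load_paper_fixture("table5")


@pytest.fixture(scope="session")
def recovery_config():
    """Planted-signal cohort configuration used by the recovery checks:
    nine universal genes, forty subtype-specific, five hundred null,
    twenty pairs per subtype, log2 noise SD 0.8."""
    return dict(
        n_pairs_per_subtype={s: 20 for s in SUBTYPES},
        n_universal=9,
        n_subtype_specific=40,
        n_null=500,
        noise_sd=0.8,
    )


@pytest.fixture(scope="session")
def planted_cohort(recovery_config):
    return generate_cohort(SyntheticConfig(seed=7, **recovery_config))


def make_matrix(values: dict[str, list[float]], probes: list[str], meta_rows) -> ExpressionMatrix:
    """Hand-build a small ExpressionMatrix; meta_rows are
    (sample, subject, subtype, group, pair) tuples."""
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "subject_id", "subtype", "group", "pair_id"]
    ).set_index("sample_id")
    vals = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), dtype=float)
    return ExpressionMatrix(values=vals, sample_meta=meta)


@pytest.fixture
def tiny_matrix():
    """3 probes x 4 samples, one subtype, two tumor/control pairs."""
    rng = np.random.default_rng(0)
    cols = ["p1_T", "p1_C", "p2_T", "p2_C"]
    values = {c: rng.normal(8, 1, size=3).tolist() for c in cols}
    meta = [
        ("p1_T", "s1", "LumA", "tumor", "p1"),
        ("p1_C", "s1", "LumA", "control", "p1"),
        ("p2_T", "s2", "LumA", "tumor", "p2"),
        ("p2_C", "s2", "LumA", "control", "p2"),
    ]
    return make_matrix(values, ["a_at", "b_at", "c_at"], meta)
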