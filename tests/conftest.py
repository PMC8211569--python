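import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20210617)


@pytest.fixture
def toy_matrix():
    """A 3-gene x 4-sample expression matrix with hand-checkable values."""
    from glucoscreen import ExpressionMatrix

    return ExpressionMatrix(
        gene_ids=["A", "B", "C"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [10.0, 20.0, 30.0, 40.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
    )


@pytest.fixture
def biogrid_file(tmp_path):
    """A miniature BioGRID tab-format file: 5 evidence lines covering one
    duplicated pair (in both orientations) and one self-loop."""
    lines = [
        "#BioGRID interactions",
        "INTERACTOR_A\tINTERACTOR_B\tOFFICIAL_SYMBOL_A\tOFFICIAL_SYMBOL_B\t"
        "EXPERIMENTAL_SYSTEM\tORGANISM_A_ID\tORGANISM_B_ID",
        "1\t2\tENO1\tPPP2R1A\tTwo-hybrid\t9606\t9606",
        "2\t1\tPPP2R1A\tENO1\tAffinity Capture-MS\t9606\t9606",
        "3\t4\tMDH2\tSLC25A11\tTwo-hybrid\t9606\t9606",
        "5\t5\tGAPDH\tGAPDH\tTwo-hybrid\t9606\t9606",
        "6\t7\tADH6\tPGM2\tTwo-hybrid\t9606\t9606",
    ]
    path = tmp_path / "biogrid.tab"
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
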