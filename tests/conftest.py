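import numpy as np
import pytest

from subtyperx.io_formats import ExpressionMatrix, GeneSet, SampleAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    """3 genes x 4 samples, strictly positive values."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
    )


@pytest.fixture
def claudin_expr():
    return ExpressionMatrix(
        gene_ids=["CLDN3", "CLDN4", "CLDN7", "CDH1", "OTHER"],
        sample_ids=["s1", "s2"],
        values=np.array(
            [
                [1.0, 0.0],
                [2.0, 0.0],
                [3.0, 0.0],
                [4.0, 0.0],
                [9.0, 9.0],
            ]
        ),
    )


@pytest.fixture
def three_subtype_annotations():
    ann = []
    for s in ("Basal", "HER2", "Luminal"):
        for i in range(4):
            ann.append(SampleAnnotation(sample_id=f"{s}_{i:03d}", subtype=s))
    return ann


@pytest.fixture
def yaptaz_like_set():
    return GeneSet(name="SETA", genes=["g1", "g2"])
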