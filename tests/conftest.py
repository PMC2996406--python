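import numpy as np
import pandas as pd
import pytest

from tdfquant.io import SampleMeta
from tdfquant.matrix import ExpressionMatrix


def make_design(n_bio: int = 2, n_tech: int = 2, ecotypes=("RB", "SU"), transects=("1", "2")):
    """Balanced sample sheet for a 2x2 x n_bio x n_tech design."""
    samples = []
    for e in ecotypes:
        for tr in transects:
            for b in range(1, n_bio + 1):
                bio = f"{e}{tr}b{b}"
                for t in range(1, n_tech + 1):
                    samples.append(
                        SampleMeta(
                            sample_id=f"{bio}t{t}",
                            ecotype=e,
                            transect=tr,
                            biological_replicate=bio,
                            technical_replicate=str(t),
                        )
                    )
    return samples


def matrix_from_values(values, samples, transcript_ids=None) -> ExpressionMatrix:
    """ExpressionMatrix from a transcripts x runs array (NaN = absent)."""
    values = np.asarray(values, dtype=float)
    ids = transcript_ids or [f"t{i}" for i in range(values.shape[0])]
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "ecotype": s.ecotype,
                "transect": s.transect,
                "biological_replicate": s.biological_replicate,
                "technical_replicate": s.technical_replicate,
            }
            for s in samples
        ]
    ).set_index("sample_id")
    return ExpressionMatrix(
        intensity=pd.DataFrame(values, index=ids, columns=meta.index),
        samples=meta,
        transcripts=pd.DataFrame(
            {"primer_combo": "pc01", "size": np.linspace(80, 480, len(ids))}, index=ids
        ),
    )


@pytest.fixture
def small_design():
    return make_design(n_bio=2, n_tech=2)


@pytest.fixture
def paper_design():
    """The study's replicate structure: 2x2 cells, 8 pools each, run twice."""
    return make_design(n_bio=8, n_tech=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20201118)
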