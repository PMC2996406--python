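"""Transcript-by-sample expression matrix container.

The matrix holds normalized (or raw) peak heights in RFU for every
transcript-derived fragment and every electrophoresis run.  Absence of a
peak is encoded as NaN in the intensity frame; ``presence`` derives the
boolean mask from it, so the two can never disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["ecotype", "transect", "biological_replicate", "technical_replicate"]


@dataclass
class ExpressionMatrix:
    """Transcripts x sample-runs intensity matrix with sample metadata.

    Parameters
    ----------
    intensity
        DataFrame indexed by transcript id, one column per sample run.
        NaN marks an absent (undetected) peak; present values must be >= 0.
    samples
        DataFrame indexed by sample id with columns ``ecotype``, ``transect``,
        ``biological_replicate`` and ``technical_replicate`` (the last one is
        absent after technical replicates have been averaged).
    transcripts
        DataFrame indexed by transcript id with columns ``primer_combo`` and
        ``size`` (representative fragment length, bp).
    """

    intensity: pd.DataFrame
    samples: pd.DataFrame
    transcripts: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.transcripts is None:
            self.transcripts = pd.DataFrame(index=self.intensity.index)
        if list(self.intensity.columns) != list(self.samples.index):
            raise ValueError("intensity columns must match sample metadata index")
        if list(self.intensity.index) != list(self.transcripts.index):
            raise ValueError("intensity index must match transcript metadata index")
        vals = self.intensity.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("present intensities must be non-negative")

    @property
    def presence(self) -> pd.DataFrame:
        """Boolean presence mask (True where a peak was detected)."""
        return self.intensity.notna()

    @property
    def n_transcripts(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.intensity.copy(), self.samples.copy(), self.transcripts.copy()
        )

    def subset_transcripts(self, ids) -> "ExpressionMatrix":
        ids = list(ids)
        return ExpressionMatrix(
            self.intensity.loc[ids], self.samples.copy(), self.transcripts.loc[ids]
        )
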