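"""The Cohort container: scale profiles, demographics, diagnosis labels."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scales import CANONICAL_SCALES, DEMOGRAPHIC_COLUMNS, LABEL_COLUMN


@dataclass(frozen=True)
class Cohort:
    """One row per participant: 13 T-scores, demographics, binary diagnosis.

    ``profiles`` columns follow the canonical scale order; ``labels`` is 1
    for schizophrenia, 0 for healthy; ``demographics`` carries age (years),
    gender (1=male), education (years) and marital status (1=married).
    """

    profiles: pd.DataFrame
    demographics: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        profiles = self.profiles.loc[:, list(CANONICAL_SCALES)].reset_index(drop=True)
        demo = self.demographics.loc[:, list(DEMOGRAPHIC_COLUMNS)].reset_index(drop=True)
        labels = np.asarray(self.labels, dtype=int)
        if not (len(profiles) == len(demo) == labels.size):
            raise ValueError("row counts disagree across fields")
        if not np.isfinite(profiles.to_numpy(dtype=float)).all():
            raise ValueError("non-finite T-scores")
        if labels.size and not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")
        object.__setattr__(self, "profiles", profiles)
        object.__setattr__(self, "demographics", demo)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, index) -> "Cohort":
        index = np.asarray(index)
        return Cohort(self.profiles.iloc[index],
                      self.demographics.iloc[index],
                      self.labels[index])

    def stratum(self, label: int) -> "Cohort":
        return self.subset(np.flatnonzero(self.labels == label))

    def to_frame(self) -> pd.DataFrame:
        """Single flat table (profiles + demographics + diagnosis)."""
        out = pd.concat([self.profiles, self.demographics], axis=1)
        out[LABEL_COLUMN] = self.labels
        return out
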