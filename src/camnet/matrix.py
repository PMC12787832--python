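"""Feature-by-sample omics matrices with an explicit preprocessing stage.

The metabolomics cascade (presence filter -> minimum imputation -> sum
normalization -> QC-RSD filter -> log10) is narrated as a fixed order; the
``stage`` attribute enforces that order as a contract rather than silently
reordering. Missing entries are stored as NaN; the missing-value mask is
derived from the values, never kept separately.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import LAYERS


class Stage(str, enum.Enum):
    RAW = "raw"
    FILTERED = "filtered"
    IMPUTED = "imputed"
    NORMALIZED = "normalized"
    QC_FILTERED = "qc_filtered"
    LOGGED = "logged"


STAGE_ORDER = list(Stage)


@dataclass
class OmicsMatrix:
    """One omics layer: features x samples.

    ``values`` is a DataFrame indexed by feature id with sample-id columns;
    NaN marks a missing (undetected) entry.
    """

    values: pd.DataFrame
    layer: str = "transcript"
    stage: Stage = Stage.RAW

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        self.stage = Stage(self.stage)
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean grid, True where the entry is missing."""
        return self.values.isna()

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def require_stage(self, stage: Stage) -> None:
        if self.stage != stage:
            raise ValueError(
                f"operation requires stage {stage.value!r} but matrix is at "
                f"{self.stage.value!r}; the cascade order is "
                + " -> ".join(s.value for s in STAGE_ORDER)
            )

    def advanced(self, values: pd.DataFrame, stage: Stage) -> "OmicsMatrix":
        """Copy with new values and a stage one step further along the cascade."""
        if STAGE_ORDER.index(stage) <= STAGE_ORDER.index(self.stage):
            raise ValueError(
                f"stage may only advance: {self.stage.value} -> {stage.value} is not forward"
            )
        return replace(self, values=values, stage=stage)

    # -- I/O ---------------------------------------------------------------
    # TSV dialect: first column feature id, header row of sample ids, empty
    # cell = missing.

    def to_tsv(self, path) -> None:
        self.values.to_csv(
            path, sep="\t", index_label="feature_id", float_format="%.10g", na_rep=""
        )

    @classmethod
    def from_tsv(cls, path, layer: str = "transcript", stage: Stage = Stage.RAW) -> "OmicsMatrix":
        v = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(v.astype(float), layer=layer, stage=stage)
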