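"""Sample design tables: which sample belongs to which treatment group, and
which injections are pooled quality-control (QC) samples.

A design is layer-specific: the transcript and protein layers of the study
use n = 3 biological replicates per group, the metabolite layer n = 6 plus
pooled-QC injections interspersed in the run. QC flags are only meaningful
for the metabolite layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

LAYERS = ("transcript", "protein", "metabolite")


@dataclass
class SampleDesign:
    """Mapping sample -> group / QC status for one omics layer.

    Parameters
    ----------
    table : pandas.DataFrame
        Indexed by ``sample_id`` with columns ``group`` (string, empty for
        QC samples) and ``is_qc`` (bool).
    layer : str
        One of ``transcript``, ``protein``, ``metabolite``.
    """

    table: pd.DataFrame
    layer: str = "transcript"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if "is_qc" not in self.table.columns:
            self.table = self.table.assign(is_qc=False)
        self.table["is_qc"] = self.table["is_qc"].astype(bool)
        qc = self.table["is_qc"]
        if qc.any() and self.layer != "metabolite":
            raise ValueError(
                f"QC samples are only permitted on the metabolite layer, not {self.layer!r}"
            )
        missing_group = (~qc) & (
            self.table["group"].isna() | (self.table["group"].astype(str) == "")
        )
        if missing_group.any():
            bad = self.table.index[missing_group].tolist()
            raise ValueError(f"non-QC samples without a group: {bad}")

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> list[str]:
        """Unique group labels of the biological samples, in table order."""
        g = self.table.loc[~self.table["is_qc"], "group"]
        return list(dict.fromkeys(g))

    def samples_in_group(self, group: str) -> list[str]:
        sel = (~self.table["is_qc"]) & (self.table["group"] == group)
        ids = list(self.table.index[sel])
        if not ids:
            raise KeyError(f"no samples in group {group!r}")
        return ids

    @property
    def qc_samples(self) -> list[str]:
        return list(self.table.index[self.table["is_qc"]])

    def __len__(self) -> int:
        return len(self.table)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "layer", self.layer)
        out.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        t = pd.read_csv(path, sep="\t", index_col="sample_id", dtype={"group": str})
        layer = t["layer"].iloc[0] if len(t) else "transcript"
        t = t.drop(columns=["layer"], errors="ignore")
        t["group"] = t["group"].fillna("")
        return cls(t, layer=layer)
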