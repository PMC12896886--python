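"""Core containers shared across the pipeline.

The central object is :class:`ExpressionStudy`, a probe-set × sample matrix of
log2 intensities together with a sample sheet that records, for every sample,
which dataset it came from, which array platform measured it, and its tissue
class (sCSC, dCSC, normal, tumor, LCM variants, cell lines, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Fixed vocabulary of tissue classes the pipeline understands.
TISSUE_CLASSES = (
    "sCSC",
    "dCSC",
    "normal",
    "normal_lcm",
    "normal_crypt",
    "tumor",
    "tumor_lcm",
    "tumor_crypt",
    "cell_line",
    "stem_ref",
)

#: Array platforms supported by the cross-platform integration step.
PLATFORMS = ("HuGene1.0ST", "U133plus2")

SAMPLE_SHEET_COLUMNS = ("sample_id", "dataset_id", "platform", "tissue_class")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


@dataclass
class ExpressionStudy:
    """Probe-set level expression study.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, probes in rows, samples in columns.
    sample_sheet
        DataFrame with columns ``sample_id``, ``dataset_id``, ``platform``,
        ``tissue_class``; one row per column of ``values``.
    """

    values: pd.DataFrame
    sample_sheet: pd.DataFrame

    def __post_init__(self) -> None:
        self.sample_sheet = self.sample_sheet.reset_index(drop=True)
        self.validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def classes(self) -> pd.Series:
        """Tissue class per sample, indexed by sample id."""
        return self.sample_sheet.set_index("sample_id")["tissue_class"].loc[
            self.sample_ids
        ]

    def platforms(self) -> pd.Series:
        return self.sample_sheet.set_index("sample_id")["platform"].loc[
            self.sample_ids
        ]

    def samples_of_class(self, tissue_class: str) -> list[str]:
        cls = self.classes()
        return list(cls.index[cls == tissue_class])

    def subset_samples(self, sample_ids) -> "ExpressionStudy":
        sample_ids = list(sample_ids)
        sheet = self.sample_sheet[self.sample_sheet["sample_id"].isin(sample_ids)]
        return ExpressionStudy(self.values[sample_ids].copy(), sheet.copy())

    def with_values(self, values: pd.DataFrame) -> "ExpressionStudy":
        return replace(self, values=values)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        vals = self.values
        if not np.isfinite(vals.to_numpy(dtype=float)).all():
            raise DataError("expression matrix contains non-finite values")
        if vals.index.has_duplicates:
            raise DataError("duplicate probe ids")
        if vals.columns.has_duplicates:
            raise DataError("duplicate sample ids")
        missing = set(SAMPLE_SHEET_COLUMNS) - set(self.sample_sheet.columns)
        if missing:
            raise DataError(f"sample sheet missing columns: {sorted(missing)}")
        sheet_ids = set(self.sample_sheet["sample_id"])
        matrix_ids = set(vals.columns)
        if sheet_ids != matrix_ids:
            raise DataError(
                "sample sheet and matrix disagree: "
                f"{sorted(sheet_ids ^ matrix_ids)[:5]} ..."
            )

    # -- text IO -----------------------------------------------------------
    def to_tsv(self, matrix_path, sheet_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
        self.sample_sheet.to_csv(sheet_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, matrix_path, sheet_path) -> "ExpressionStudy":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        sheet = pd.read_csv(sheet_path, sep="\t")
        return cls(values, sheet)
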