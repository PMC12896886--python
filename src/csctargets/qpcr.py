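"""Relative qPCR quantification (2^-ΔΔCt) and the CSC-specificity call.

ΔCt normalizes a gene's cycle threshold to a housekeeping gene within each
cell line; ΔΔCt references that to a designated CSC line, so
RQ = 2^-ΔΔCt is the expression relative to the reference line (the method
assumes a doubling per cycle; no efficiency correction is applied).

The specificity call renders the validation rubric: a gene is considered
CSC-specific when enough independent CSC lines exceed the normal-tissue
control by a fold threshold, and the CSC signal also stands above enough
conventional cancer cell lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError

__all__ = ["CtTable", "RQTable", "ddct_quantify", "specificity_call"]

LINE_TYPES = ("csc", "cancer_line", "normal")


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: gene, line, line_type (csc / cancer_line / normal),
    replicate, ct.  The housekeeping gene must be measured in every line.
    """

    data: pd.DataFrame
    housekeeping: str
    reference_line: str
    normal_line: str

    def __post_init__(self):
        need = {"gene", "line", "line_type", "replicate", "ct"}
        missing = need - set(self.data.columns)
        if missing:
            raise DataError(f"Ct table missing columns: {sorted(missing)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if np.any(~np.isfinite(ct)) or np.any(ct <= 0) or np.any(ct > 40):
            raise DataError("Ct values must lie in (0, 40]")
        bad = set(self.data["line_type"]) - set(LINE_TYPES)
        if bad:
            raise DataError(f"unknown line types: {sorted(bad)}")
        lines = set(self.data["line"])
        hk_lines = set(self.data.loc[self.data["gene"] == self.housekeeping, "line"])
        if lines - hk_lines:
            raise DataError(
                f"housekeeping gene {self.housekeeping!r} not measured in lines "
                f"{sorted(lines - hk_lines)}"
            )
        if self.reference_line not in lines:
            raise DataError(f"reference line {self.reference_line!r} not in table")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - {self.housekeeping})

    @property
    def lines(self) -> list[str]:
        return sorted(set(self.data["line"]))

    def line_types(self) -> pd.Series:
        return self.data.drop_duplicates("line").set_index("line")["line_type"]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, housekeeping, reference_line, normal_line) -> "CtTable":
        return cls(pd.read_csv(path), housekeeping, reference_line, normal_line)


@dataclass
class RQTable:
    """Relative quantities (gene × line), RQ = 1 in the reference line."""

    rq: pd.DataFrame
    ddct: pd.DataFrame
    reference_line: str
    normal_line: str
    line_types: pd.Series = field(repr=False, default=None)

    @property
    def percent(self) -> pd.DataFrame:
        """RQ expressed as percent of the reference CSC line."""
        return 100.0 * self.rq

    def lines_of_type(self, line_type: str) -> list[str]:
        return [ln for ln in self.rq.columns if self.line_types.get(ln) == line_type]


def ddct_quantify(ct: CtTable, aggregation: str = "mean_ct") -> RQTable:
    """2^-ΔΔCt relative quantification.

    ΔCt = mean Ct(gene) - mean Ct(housekeeping) per line; ΔΔCt references the
    designated CSC line; RQ = 2^-ΔΔCt.  ``aggregation`` is either ``mean_ct``
    (average Ct before the deltas, the conventional form) or
    ``per_replicate`` (per-replicate RQ combined by geometric mean).
    """
    if aggregation not in ("mean_ct", "per_replicate"):
        raise DataError(f"unknown aggregation {aggregation!r}")
    df = ct.data
    hk = df[df["gene"] == ct.housekeeping]
    hk_mean = hk.groupby("line")["ct"].mean()

    genes, lines = ct.genes, ct.lines
    dct = pd.DataFrame(index=genes, columns=lines, dtype=float)
    for (gene, line), grp in df[df["gene"] != ct.housekeeping].groupby(["gene", "line"]):
        if aggregation == "mean_ct":
            dct.loc[gene, line] = grp["ct"].mean() - hk_mean[line]
        else:
            per_rep = grp["ct"].to_numpy() - hk_mean[line]
            dct.loc[gene, line] = float(np.mean(per_rep))  # geomean of 2^-x == 2^-mean(x)
    if dct.isna().any().any():
        missing = [
            (g, l) for g in genes for l in lines if pd.isna(dct.loc[g, l])
        ]
        raise DataError(f"missing Ct measurements for {missing[:5]} ...")
    ddct = dct.sub(dct[ct.reference_line], axis=0)
    rq = 2.0 ** (-ddct)
    return RQTable(
        rq=rq,
        ddct=ddct,
        reference_line=ct.reference_line,
        normal_line=ct.normal_line,
        line_types=ct.line_types(),
    )


def specificity_call(
    rq: RQTable,
    fold_min: float = 3.0,
    min_csc_lines: int = 3,
    min_cancer_lines: int = 4,
) -> pd.DataFrame:
    """Call each gene ``acceptable``, ``partial`` or ``rejected``.

    Two criteria, combined with AND for ``acceptable``:

    1. at least ``min_csc_lines`` CSC lines show RQ >= ``fold_min`` × the
       normal-colon control;
    2. the median CSC RQ exceeds ``fold_min`` × RQ in at least
       ``min_cancer_lines`` conventional cancer cell lines
       (set ``min_cancer_lines=0`` for the single-criterion reading).

    ``partial`` when exactly one criterion holds, ``rejected`` otherwise.
    """
    csc_lines = rq.lines_of_type("csc")
    cancer_lines = rq.lines_of_type("cancer_line")
    if rq.normal_line not in rq.rq.columns:
        raise DataError(f"normal control {rq.normal_line!r} missing from RQ table")

    rows = []
    for gene in rq.rq.index:
        r = rq.rq.loc[gene]
        n_csc = int(np.sum([r[l] >= fold_min * r[rq.normal_line] for l in csc_lines]))
        med_csc = float(np.median([r[l] for l in csc_lines])) if csc_lines else np.nan
        n_cancer = int(np.sum([med_csc >= fold_min * r[l] for l in cancer_lines]))
        crit1 = n_csc >= min_csc_lines
        crit2 = n_cancer >= min_cancer_lines
        status = "acceptable" if (crit1 and crit2) else "partial" if (crit1 or crit2) else "rejected"
        rows.append(
            {
                "gene": gene,
                "n_csc_pass": n_csc,
                "n_cancer_pass": n_cancer,
                "status": status,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
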