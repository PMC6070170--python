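"""Relative-quantification arithmetic for expression validation.

Two methods:

* Livak 2^-ΔΔCt for qRT-PCR: ΔΔCt = (Ct_target,sample − Ct_ref,sample) −
  (Ct_target,calibrator − Ct_ref,calibrator); the fold change is 2^−ΔΔCt.
  Technical replicates are averaged on the Ct scale before the formula, the
  standard Livak practice.  No amplification-efficiency correction is
  applied.
* Reference-normalized band densitometry for semi-quantitative RT-PCR:
  (target/reference) density ratio of a sample over the calibrator's ratio.
  A zero target density is a valid "undetected" observation and yields a
  relative level of 0.

The calibrator tissue is a required input, never inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

__all__ = [
    "CtRecord",
    "ExpressionRecord",
    "ddct_fold_change",
    "band_relative",
    "ddct_table",
    "read_ct_csv",
    "expression_to_tsv",
]


@dataclass(frozen=True)
class CtRecord:
    """One qPCR measurement: a cycle threshold for (gene, tissue, replicate)."""

    gene_id: str
    tissue: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not 0 < self.ct < 60:
            raise ValueError(f"Ct {self.ct} outside plausible range (0,60)")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    tissue: str
    relative_level: float
    method: Literal["ddct", "band_density"]
    undetected: bool = False

    def __post_init__(self) -> None:
        if self.relative_level < 0:
            raise ValueError("relative_level must be >= 0")


def ddct_fold_change(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_cal: float,
    ct_ref_cal: float,
) -> float:
    """Livak fold change 2^-ΔΔCt of a sample relative to the calibrator."""
    ddct = (ct_target_sample - ct_ref_sample) - (ct_target_cal - ct_ref_cal)
    return 2.0 ** (-ddct)


def band_relative(
    d_target: float, d_ref: float, d_target_cal: float, d_ref_cal: float
) -> float:
    """Reference-normalized band-density ratio relative to the calibrator.

    ``d_target`` may be 0 (band undetected); any zero reference or calibrator
    density raises ``ValueError``.
    """
    if d_ref <= 0 or d_ref_cal <= 0 or d_target_cal <= 0:
        raise ValueError("reference and calibrator densities must be > 0")
    if d_target < 0:
        raise ValueError("densities must be >= 0")
    return (d_target / d_ref) / (d_target_cal / d_ref_cal)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    """Read a CSV of columns gene, tissue, replicate, ct (or density)."""
    df = pd.read_csv(path)
    expected = {"gene", "tissue", "replicate"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return df


def ddct_table(
    df: pd.DataFrame,
    reference_gene: str,
    calibrator_tissue: str,
    value_column: str = "ct",
) -> list[ExpressionRecord]:
    """Fold changes of every (gene, tissue) relative to the calibrator tissue.

    Replicates are averaged on the Ct scale per (gene, tissue) before the
    Livak formula.  The reference gene normalizes within each tissue; by
    construction every target gene has relative level 1 in the calibrator
    tissue.
    """
    means = df.groupby(["gene", "tissue"])[value_column].mean()
    if reference_gene not in means.index.get_level_values("gene"):
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    records: list[ExpressionRecord] = []
    genes = sorted(set(means.index.get_level_values("gene")) - {reference_gene})
    tissues = sorted(set(means.index.get_level_values("tissue")))
    if calibrator_tissue not in tissues:
        raise ValueError(f"calibrator tissue {calibrator_tissue!r} absent from the table")
    for gene in genes:
        ct_t_cal = means[(gene, calibrator_tissue)]
        ct_r_cal = means[(reference_gene, calibrator_tissue)]
        for tissue in tissues:
            fold = ddct_fold_change(
                means[(gene, tissue)], means[(reference_gene, tissue)], ct_t_cal, ct_r_cal
            )
            records.append(ExpressionRecord(gene, tissue, fold, "ddct"))
    return records


def expression_to_tsv(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttissue\trelative_level\tmethod\tflag\n")
        for r in records:
            flag = "undetected" if r.undetected else ""
            fh.write(
                f"{r.gene_id}\t{r.tissue}\t{r.relative_level:.6g}\t{r.method}\t{flag}\n"
            )
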