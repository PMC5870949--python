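"""Expression-table aggregation/scaling and qPCR relative quantification.

RNA-seq abundances (TPM or FPKM) arrive per transfrag isoform; gene-level
abundance sums isoforms within a transfrag, then combines multiple
transfrags annotated to the same gene by max or mean (the two summaries
are both first-class; on well-assembled data they give very similar
relative patterns). Because TPM and FPKM are relative units, cross-species
comparison is done on shares of total sodium-channel expression within
each tissue, which are invariant to any common rescaling.

qPCR relative quantification uses the 2^-ddCq method under the 100%%
doubling-efficiency assumption: dCq = Cq_target - Cq_reference per sample,
ddCq relative to a calibrator sample, fold change = 2^-ddCq.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EXPRESSION_COLUMNS = ["gene", "transfrag", "isoform", "tissue", "replicate",
                      "abundance"]
CQ_COLUMNS = ["sample", "tissue", "target", "reference", "cq_target",
              "cq_reference"]


def validate_expression_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an expression table (isoform-level TPM/FPKM rows)."""
    missing = set(EXPRESSION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    if (table["abundance"] < 0).any():
        raise ValueError("negative abundances")
    dup = table.duplicated(["transfrag", "isoform", "tissue", "replicate"])
    if dup.any():
        raise ValueError("duplicate (transfrag, isoform, tissue, replicate) rows")
    return table


def aggregate_gene_expression(table: pd.DataFrame,
                              mode: str = "sum_isoforms_then_mean"
                              ) -> pd.DataFrame:
    """Gene x tissue x replicate abundances.

    Isoform abundances are summed within each transfrag; multiple
    transfrags of one gene (assembly fragments of the same locus) are then
    combined per ``mode``: ``sum_isoforms_then_max`` or
    ``sum_isoforms_then_mean``.
    """
    if mode not in ("sum_isoforms_then_max", "sum_isoforms_then_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    validate_expression_table(table)
    per_transfrag = (
        table.groupby(["gene", "transfrag", "tissue", "replicate"],
                      as_index=False)["abundance"].sum()
    )
    combine = "max" if mode == "sum_isoforms_then_max" else "mean"
    out = (
        per_transfrag.groupby(["gene", "tissue", "replicate"],
                              as_index=False)["abundance"]
        .agg(combine)
    )
    return out


def scale_by_total_channel_expression(gene_abundances: pd.DataFrame,
                                      gene_set: list[str]) -> pd.DataFrame:
    """Per-tissue/replicate shares of a gene set's total expression.

    share_g = abundance_g / sum over the gene set, within each (tissue,
    replicate); shares sum to 1 per group. Raises if the set total is zero
    in any group.
    """
    if not gene_set:
        raise ValueError("gene_set must be nonempty")
    absent = set(gene_set) - set(gene_abundances["gene"])
    if absent:
        raise ValueError(f"genes not in table: {sorted(absent)}")
    sub = gene_abundances[gene_abundances["gene"].isin(gene_set)].copy()
    totals = sub.groupby(["tissue", "replicate"])["abundance"].transform("sum")
    if (totals == 0).any():
        bad = sub.loc[totals == 0, ["tissue", "replicate"]].drop_duplicates()
        raise ValueError(f"zero total channel expression in groups:\n{bad}")
    sub["share"] = sub["abundance"] / totals
    return sub[["gene", "tissue", "replicate", "share"]]


def validate_cq_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CQ_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Cq table missing columns {sorted(missing)}")
    if (table[["cq_target", "cq_reference"]] <= 0).any().any():
        raise ValueError("Cq values must be > 0")
    if table[["cq_target", "cq_reference"]].isna().any().any():
        raise ValueError("missing target or reference Cq measurement")
    return table


def ddcq_fold_change(cq: pd.DataFrame, calibrator: str,
                     efficiency: float = 2.0) -> pd.DataFrame:
    """Relative expression by the 2^-ddCq method.

    dCq = Cq_target - Cq_reference per sample; ddCq is taken relative to
    the calibrator sample (per target gene); fold = efficiency^-ddCq with
    efficiency fixed at 2.0 (100%% doubling) by default.
    """
    validate_cq_table(cq)
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must be > 1")
    df = cq.copy()
    df["dcq"] = df["cq_target"] - df["cq_reference"]
    out = []
    for target, grp in df.groupby("target"):
        cal = grp.loc[grp["sample"] == calibrator]
        if cal.empty:
            raise ValueError(
                f"calibrator sample {calibrator!r} absent for target {target!r}")
        cal_dcq = float(cal["dcq"].iloc[0])
        g = grp.copy()
        g["ddcq"] = g["dcq"] - cal_dcq
        g["fold_change"] = efficiency ** (-g["ddcq"])
        out.append(g)
    return pd.concat(out, ignore_index=True)[
        ["sample", "tissue", "target", "reference", "dcq", "ddcq",
         "fold_change"]]
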