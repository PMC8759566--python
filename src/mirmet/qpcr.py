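"""qPCR validation statistics: dCq against a reference miRNA and a Welch test.

Quantification cycles (Cq) are inversely related to abundance, so a target
assay is normalized to a stably expressed reference assay measured on the
same sample: dCq = mean(target replicates) - mean(reference replicates).
Lower dCq means higher target expression.  Group comparison uses Welch's
two-sided t-test on the per-sample dCq values.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .celltype import WelchResult, welch_t

__all__ = ["delta_cq", "compare_groups"]

REQUIRED_COLUMNS = {"sample_id", "group", "assay", "replicate", "cq"}


def delta_cq(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample dCq: replicate-mean target Cq minus replicate-mean reference
    Cq.

    Samples missing either assay are dropped with a warning; a single
    replicate is used as-is with a warning.  Returns a DataFrame indexed by
    sample with columns group and dcq.
    """
    missing_cols = REQUIRED_COLUMNS - set(table.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    rows = {}
    for sample, sub in table.groupby("sample_id"):
        assays = sub.groupby("assay")["cq"].agg(["mean", "count"])
        if not {"target", "reference"} <= set(assays.index):
            warnings.warn(f"sample {sample} missing an assay; dropped")
            continue
        if (assays["count"] < 2).any():
            warnings.warn(f"sample {sample}: single replicate used")
        rows[sample] = {
            "group": sub["group"].iloc[0],
            "dcq": assays.at["target", "mean"] - assays.at["reference", "mean"],
        }
    if not rows:
        raise ValueError("no sample with both assays")
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_groups(dcq_case, dcq_control) -> WelchResult:
    """Welch two-sided t-test of case vs control dCq values.

    Negative t means lower dCq in the case group, i.e. higher target
    expression there.
    """
    return welch_t(dcq_case, dcq_control)
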