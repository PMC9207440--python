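"""Relative qPCR quantification by the 2^-ddCt method.

Duplicate wells are averaged per fish x gene, each target gene is normalised
against the reference gene (dCt = Ct_target - Ct_reference), and expression is
expressed relative to the *lowest-expression* cell: the (group, sampling-time)
cell with the highest mean dCt serves as calibrator, so its fold change is
pinned at 1 and every other value is a fold change above it,
``fold = 2^-(dCt - dCt_calibrator)``.  Amplification efficiency is fixed at 2
(no efficiency correction).

The calibrator scope is configurable: ``"across_groups"`` (default) picks one
calibrator cell per gene x tissue across all experimental groups, which keeps
the three groups on one common scale; ``"within_group"`` picks one per
gene x tissue x group.  Ties on the mean dCt are broken by earliest sampling
time, then group order, so the choice is deterministic.

Non-qPCR measurements (a ``value`` column, e.g. plasma glucose in mg/dl)
bypass this module unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["collapse_replicates", "compute_fold_change", "calibrator_table"]

_KEYS = ["sample_id", "group", "tissue", "gene", "time_label", "time_h"]


def collapse_replicates(
    table: pd.DataFrame, *, spread_threshold: float = 0.5
) -> pd.DataFrame:
    """Average technical Ct replicates to one Ct per sample x gene.

    The replicate spread (max - min) is kept as a QC column ``ct_spread`` and
    records whose duplicates disagree by more than ``spread_threshold`` cycles
    (default 0.5) are flagged in ``qc_flag`` — flagged, never dropped.
    """
    if "ct" not in table.columns:
        raise ValueError("collapse_replicates expects a 'ct' column (qPCR mode)")
    bad = table["ct"].le(0) | table["ct"].gt(40) | ~np.isfinite(table["ct"])
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} Ct values outside (0, 40]; first offending sample: "
            f"{table.loc[bad, 'sample_id'].iloc[0]!r}"
        )
    g = table.groupby(_KEYS, sort=False)["ct"]
    out = g.mean().reset_index()
    spread = (g.max() - g.min()).reset_index(drop=True)
    out["ct_spread"] = spread
    out["qc_flag"] = spread > spread_threshold
    return out


def _calibrator_cell(cell_means: pd.DataFrame, group_order: list[str]) -> pd.Series:
    """Pick the lowest-expression cell: highest mean dCt, ties broken by
    earliest sampling time then by group order."""
    m = cell_means.copy()
    m["_grp_rank"] = m["group"].map({g: i for i, g in enumerate(group_order)})
    m = m.sort_values(
        ["dct_mean", "time_h", "_grp_rank"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    return m.iloc[0]


def compute_fold_change(
    table: pd.DataFrame,
    reference_gene: str,
    *,
    calibrator_scope: str = "across_groups",
    spread_threshold: float = 0.5,
) -> pd.DataFrame:
    """Compute per-fish relative mRNA abundance (fold change) by 2^-ddCt.

    Parameters
    ----------
    table
        Tidy Ct table (raw duplicates or already collapsed).
    reference_gene
        The stable normaliser gene (e.g. eef-1a1); must be measured for every
        sample.
    calibrator_scope
        ``"across_groups"``: one calibrator cell per gene x tissue (all groups
        on one scale, default) or ``"within_group"``: per gene x tissue x group.

    Returns
    -------
    DataFrame with one row per fish x gene carrying ``dct`` and ``fold``, with
    the chosen calibrators in ``df.attrs["calibrators"]`` (mapping scope key ->
    dict with group, time_label, time_h, mean dCt).  The generating scenario,
    if present on the input, is propagated.
    """
    if calibrator_scope not in ("across_groups", "within_group"):
        raise ValueError("calibrator_scope must be 'across_groups' or 'within_group'")
    collapsed = collapse_replicates(table, spread_threshold=spread_threshold)

    ref = collapsed[collapsed["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not found in table")
    ref_ct = ref.set_index(["sample_id", "tissue"])["ct"]
    targets = collapsed[collapsed["gene"] != reference_gene].copy()

    idx = pd.MultiIndex.from_frame(targets[["sample_id", "tissue"]])
    missing = ~idx.isin(ref_ct.index)
    if missing.any():
        sid, tis = targets.loc[missing, ["sample_id", "tissue"]].iloc[0]
        raise ValueError(
            f"missing reference-gene Ct for sample {sid!r} (tissue {tis!r})"
        )
    targets["dct"] = targets["ct"].to_numpy() - ref_ct.loc[idx].to_numpy()

    group_order = list(dict.fromkeys(collapsed["group"]))
    scope_cols = (
        ["tissue", "gene"] if calibrator_scope == "across_groups"
        else ["tissue", "gene", "group"]
    )
    targets = targets.reset_index(drop=True)
    calibrators: dict = {}
    folds = np.empty(len(targets))
    for key, sub in targets.groupby(scope_cols, sort=False):
        cells = (
            sub.groupby(["group", "time_label", "time_h"], sort=False)["dct"]
            .mean()
            .reset_index()
            .rename(columns={"dct": "dct_mean"})
        )
        cal = _calibrator_cell(cells, group_order)
        calibrators[key if isinstance(key, tuple) else (key,)] = {
            "group": cal["group"],
            "time_label": cal["time_label"],
            "time_h": float(cal["time_h"]),
            "dct_mean": float(cal["dct_mean"]),
        }
        folds[sub.index.to_numpy()] = 2.0 ** (
            -(sub["dct"].to_numpy() - float(cal["dct_mean"]))
        )
    targets["fold"] = folds
    out = targets[_KEYS + ["dct", "fold"] +
                  [c for c in ("ct_spread", "qc_flag") if c in targets.columns]]
    out.attrs["calibrators"] = calibrators
    out.attrs["calibrator_scope"] = calibrator_scope
    out.attrs["reference_gene"] = reference_gene
    if "scenario" in table.attrs:
        out.attrs["scenario"] = table.attrs["scenario"]
    return out


def calibrator_table(expression: pd.DataFrame) -> pd.DataFrame:
    """Tidy report of the calibrator cell chosen for each quantification scope."""
    cal = expression.attrs.get("calibrators")
    if cal is None:
        raise ValueError("no calibrator metadata on this table")
    scope_cols = (
        ["tissue", "gene"] if expression.attrs.get("calibrator_scope") == "across_groups"
        else ["tissue", "gene", "group"]
    )
    rows = [
        dict(zip(scope_cols, key)) | {f"calibrator_{k}": v for k, v in info.items()}
        for key, info in cal.items()
    ]
    return pd.DataFrame(rows)
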