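"""Per-species fold-changes with significance and saturation-binned exports.

Fold-changes are computed on class-normalized proportions, as
log2(mean(case) / mean(reference)) with a two-sided Student's t-test
(pooled variance; Welch behind a flag) on the per-sample values.  No
multiple-testing correction is applied to the headline columns — the volcano
convention is raw p — but a Benjamini–Hochberg column is carried along for
users who want it.

The saturation annotation attached to every row drives the standard
downstream views: double-bond bins (0, 1, 2, 3, >=4 on the most unsaturated
chain), the highly-unsaturated outline, and the arachidonic-acid (C20:4) and
linoleic-acid (C18:2) chain flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .nomenclature import (
    DEFAULT_PHOSPHOLIPID_CLASSES,
    annotate_saturation,
)
from .preprocess import NormalizedTable

__all__ = [
    "group_fold_changes",
    "class_proportions",
    "saturation_summary",
    "ClassProportionSummary",
]

ANNOTATION_COLUMNS = [
    "class_code",
    "max_double_bonds",
    "saturation_class",
    "highly_unsaturated",
    "contains_20_4",
    "contains_18_2",
    "contains_18_3",
    "is_phospholipid",
    "total_carbons",
]


def _bh_adjust(p: pd.Series) -> pd.Series:
    adj = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        adj[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return adj


def group_fold_changes(
    norm: NormalizedTable,
    case_group: str,
    ref_group: str,
    welch: bool = False,
    phospholipid_classes: frozenset[str] | set[str] = DEFAULT_PHOSPHOLIPID_CLASSES,
) -> pd.DataFrame:
    """Species-level log2 fold-changes of *case* over *reference*.

    Returns one row per species with ``log2_fc``, ``p_value`` (two-sided
    t-test on per-sample proportions, missing cells omitted), group means
    and sizes, a ``fc_undefined`` flag for zero reference means, a BH column
    and the full saturation annotation.

    A group with fewer than two non-missing values for a species yields a
    missing p-value (with one summary warning), never an exception.
    """
    groups = norm.groups()
    for g in (case_group, ref_group):
        if g not in groups:
            raise ValueError(f"group {g!r} not present in the table")
    case = norm.values[groups[case_group]].to_numpy(dtype=float)
    ref = norm.values[groups[ref_group]].to_numpy(dtype=float)

    mean_case = np.nanmean(np.where(np.isnan(case), np.nan, case), axis=1)
    mean_ref = np.nanmean(np.where(np.isnan(ref), np.nan, ref), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_fc = np.log2(mean_case / mean_ref)
    undefined = ~np.isfinite(log2_fc)
    log2_fc = np.where(undefined, np.nan, log2_fc)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(
            case, ref, axis=1, equal_var=not welch, nan_policy="omit"
        )
    p = np.asarray(t_res.pvalue, dtype=float)
    n_case = (~np.isnan(case)).sum(axis=1)
    n_ref = (~np.isnan(ref)).sum(axis=1)
    too_small = (n_case < 2) | (n_ref < 2)
    p = np.where(too_small, np.nan, p)
    if too_small.any():
        warnings.warn(
            f"{int(too_small.sum())} species have <2 observations in a "
            "group; p-values set missing",
            stacklevel=2,
        )

    annotations = [
        annotate_saturation(sp, phospholipid_classes) for sp in norm.species
    ]
    frame = pd.DataFrame(
        {
            "species": norm.values.index,
            "class_code": [sp.class_code for sp in norm.species],
            "log2_fc": log2_fc,
            "p_value": p,
            "group_mean_case": mean_case,
            "group_mean_ref": mean_ref,
            "n_case": n_case,
            "n_ref": n_ref,
            "fc_undefined": undefined,
            "max_double_bonds": [a.max_double_bonds for a in annotations],
            "saturation_class": [a.saturation_class for a in annotations],
            "highly_unsaturated": [a.highly_unsaturated for a in annotations],
            "contains_20_4": [a.contains_20_4 for a in annotations],
            "contains_18_2": [a.contains_18_2 for a in annotations],
            "contains_18_3": [a.contains_18_3 for a in annotations],
            "is_phospholipid": [a.is_phospholipid for a in annotations],
            "total_carbons": [sp.total_carbons for sp in norm.species],
        }
    ).set_index("species")
    frame["p_bh"] = _bh_adjust(frame["p_value"])
    frame.attrs["case_group"] = case_group
    frame.attrs["ref_group"] = ref_group
    return frame


@dataclass
class ClassProportionSummary:
    """Class-level composition: per-sample fractions, group means, t-tests."""

    per_sample: pd.DataFrame  # samples × classes, fractions of total lipid
    group_means: pd.DataFrame  # groups × classes
    tests: pd.DataFrame  # per class: t statistic and p between two groups


def class_proportions(
    norm_total: NormalizedTable,
    case_group: str | None = None,
    ref_group: str | None = None,
) -> ClassProportionSummary:
    """Per-sample lipid-class fractions of total lipid, with group contrasts.

    Requires a ``total``-normalized table so that each sample's class
    fractions sum to one.  When the two contrast groups are not named and
    the table holds exactly two groups, those are used.
    """
    if norm_total.mode != "total":
        raise ValueError(
            f"class proportions need mode='total', got {norm_total.mode!r}"
        )
    per_sample = norm_total.values.groupby(norm_total.class_codes.values).sum().T
    per_sample.index.name = "sample_id"

    groups = norm_total.groups()
    if case_group is None or ref_group is None:
        if len(groups) != 2:
            raise ValueError(
                "name case_group and ref_group explicitly when the table "
                f"has {len(groups)} groups"
            )
        ref_group, case_group = sorted(groups)
    group_means = pd.DataFrame(
        {g: per_sample.loc[ids].mean(axis=0) for g, ids in groups.items()}
    ).T

    rows = {}
    for cls in per_sample.columns:
        t, p = stats.ttest_ind(
            per_sample.loc[groups[case_group], cls],
            per_sample.loc[groups[ref_group], cls],
            equal_var=True,
        )
        rows[cls] = {"t": t, "p_value": p}
    tests = pd.DataFrame(rows).T
    tests.attrs["case_group"] = case_group
    tests.attrs["ref_group"] = ref_group
    return ClassProportionSummary(
        per_sample=per_sample, group_means=group_means, tests=tests
    )


def saturation_summary(
    rows: pd.DataFrame, fc_display_range: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Long-format volcano/heatmap export ordered for saturation display.

    Species are sorted by (class, double bonds of the most unsaturated
    chain, total chain length).  Adds the double-bond display bin
    (0/1/2/3/>=4), the heatmap outline flags (highly unsaturated excluding
    C20:4 carriers; C20:4 carriers; C18:2 carriers) and, when
    ``fc_display_range`` is given, an ``out_of_range`` flag for fold-changes
    outside it (the grey-box convention).
    """
    out = rows.copy()
    if out.empty:
        for col in ("db_bin", "outline_hu_excl_20_4", "outline_20_4",
                    "outline_18_2", "out_of_range"):
            out[col] = pd.Series(dtype=object)
        return out
    out["db_bin"] = np.where(
        out["max_double_bonds"] >= 4, "≥4", out["max_double_bonds"].astype(str)
    )
    out["outline_hu_excl_20_4"] = out["highly_unsaturated"] & ~out["contains_20_4"]
    out["outline_20_4"] = out["contains_20_4"]
    out["outline_18_2"] = out["contains_18_2"]
    if fc_display_range is not None:
        lo, hi = fc_display_range
        out["out_of_range"] = out["log2_fc"].notna() & (
            (out["log2_fc"] < lo) | (out["log2_fc"] > hi)
        )
    else:
        out["out_of_range"] = False
    return out.sort_values(
        ["class_code", "max_double_bonds", "total_carbons"],
        kind="mergesort",
    )
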