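"""The phospholipid unsaturation index and its two-way ANOVA.

The unsaturation index U of a sample is the ratio of the summed
class-normalized abundance of phospholipid species whose most unsaturated
acyl chain carries four to six double bonds over the sum for species with
zero to three, computed per sample:

    U = Σ proportions(max DB ∈ [4, 6]) / Σ proportions(max DB ∈ [0, 3])

Species with more than six double bonds on a chain (rare on a targeted
panel) are excluded from both sums and counted in the result; U is scale
invariant per sample, so any per-sample scaling of the proportions cancels.

Group structure (brain region × disease state) is tested with a two-way
ANOVA using type III sums of squares (the convention of common GUI
statistics packages for unbalanced designs), followed by per-region
disease-versus-control contrasts on the pooled residual variance with
Šídák multiplicity adjustment, and a D'Agostino–Pearson normality check per
group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .nomenclature import DEFAULT_PHOSPHOLIPID_CLASSES
from .preprocess import NormalizedTable

__all__ = ["compute_index", "index_anova", "sidak_adjust", "AnovaTable"]


def compute_index(
    norm: NormalizedTable,
    phospholipid_classes: frozenset[str] | set[str] = DEFAULT_PHOSPHOLIPID_CLASSES,
    include_total_composition: bool = False,
) -> pd.DataFrame:
    """Per-sample unsaturation index over the configured phospholipid classes.

    Missing cells contribute nothing to either sum.  Samples whose 0–3
    double-bond mass is zero get a missing index (flagged, with a warning).
    Total-composition species are excluded by default because their
    chain-level double-bond maximum is not observed.

    Returns a frame indexed by sample id with the index, both bin masses and
    the sample's group/region/induction labels; ``attrs['n_excluded_gt6']``
    counts species skipped for exceeding six double bonds.
    """
    if norm.mode != "per_class":
        raise ValueError(
            f"the unsaturation index is defined on mode='per_class' data, "
            f"got {norm.mode!r}"
        )
    max_db = np.array([sp.max_double_bonds for sp in norm.species])
    is_pl = np.array(
        [sp.class_code in phospholipid_classes for sp in norm.species]
    )
    usable = is_pl.copy()
    if not include_total_composition:
        usable &= ~np.array([sp.total_composition for sp in norm.species])

    hi = usable & (max_db >= 4) & (max_db <= 6)
    lo = usable & (max_db <= 3)
    n_excluded = int((usable & (max_db > 6)).sum())

    numerator = norm.values.loc[hi].sum(axis=0)
    denominator = norm.values.loc[lo].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        index = numerator / denominator.where(denominator > 0)
    if index.isna().any():
        warnings.warn(
            f"{int(index.isna().sum())} samples have zero 0–3 double-bond "
            "mass; index undefined",
            stacklevel=2,
        )
    out = pd.DataFrame(
        {
            "unsaturation_index": index,
            "numerator": numerator,
            "denominator": denominator,
        }
    )
    out = out.join(norm.samples[["group", "induction", "region"]])
    out.attrs["n_excluded_gt6"] = n_excluded
    return out


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Šídák multiplicity adjustment, p_adj = 1 − (1 − p)^m for m comparisons."""
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    return np.clip(1.0 - (1.0 - np.asarray(p, dtype=float)) ** m, 0.0, 1.0)[()]


@dataclass
class AnovaTable:
    """Two-way ANOVA effects, per-level post-hoc contrasts and normality."""

    effects: pd.DataFrame  # index: factor_a, factor_b, interaction; F, p, df
    posthoc: pd.DataFrame  # per level of factor_a: diff, t, p_raw, p_sidak
    normality: pd.DataFrame  # per (factor_a, factor_b) cell: statistic, p, n
    residual_df: float
    mse: float


def index_anova(
    index_df: pd.DataFrame,
    value: str = "unsaturation_index",
    factor_a: str = "region",
    factor_b: str = "group",
) -> AnovaTable:
    """Two-way ANOVA of the index across ``factor_a`` × ``factor_b``.

    Main effects and interaction use type III sums of squares with
    sum-to-zero coding, valid for unbalanced cell counts.  Post-hoc
    contrasts compare the two levels of ``factor_b`` within each level of
    ``factor_a`` on the pooled residual variance, Šídák-adjusted over the
    number of levels of ``factor_a``.  D'Agostino–Pearson normality
    statistics are reported per cell (missing when a cell has fewer than
    eight observations, the test's minimum).
    """
    data = index_df[[value, factor_a, factor_b]].dropna().copy()
    data.columns = ["y", "A", "B"]
    levels_a = sorted(data["A"].unique())
    levels_b = sorted(data["B"].unique())
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("both factors need at least two levels")
    cell_n = data.groupby(["A", "B"], sort=True).size()
    for a in levels_a:
        for b in levels_b:
            if (a, b) not in cell_n.index or cell_n.loc[(a, b)] < 2:
                raise ValueError(
                    f"cell ({factor_a}={a!r}, {factor_b}={b!r}) has fewer "
                    "than two observations"
                )

    model = ols("y ~ C(A, Sum) * C(B, Sum)", data=data).fit()
    table = anova_lm(model, typ=3)
    rename = {
        "C(A, Sum)": factor_a,
        "C(B, Sum)": factor_b,
        "C(A, Sum):C(B, Sum)": f"{factor_a}:{factor_b}",
    }
    effects = (
        table.rename(index=rename)
        .loc[list(rename.values()), ["df", "F", "PR(>F)"]]
        .rename(columns={"PR(>F)": "p_value"})
    )
    residual_df = float(table.loc["Residual", "df"])
    mse = float(table.loc["Residual", "sum_sq"] / residual_df)

    if len(levels_b) != 2:
        posthoc = pd.DataFrame(
            columns=["diff", "t", "p_raw", "p_sidak", "n_1", "n_2"]
        )
    else:
        b1, b2 = levels_b
        rows = {}
        for a in levels_a:
            y1 = data.loc[(data["A"] == a) & (data["B"] == b1), "y"]
            y2 = data.loc[(data["A"] == a) & (data["B"] == b2), "y"]
            diff = y2.mean() - y1.mean()
            se = np.sqrt(mse * (1.0 / len(y1) + 1.0 / len(y2)))
            t = diff / se
            p_raw = 2.0 * stats.t.sf(abs(t), residual_df)
            rows[a] = {
                "diff": diff,
                "t": t,
                "p_raw": p_raw,
                "p_sidak": float(sidak_adjust(p_raw, len(levels_a))),
                "n_1": len(y1),
                "n_2": len(y2),
            }
        posthoc = pd.DataFrame(rows).T
        posthoc.attrs["contrast"] = f"{b2} - {b1}"

    norm_rows = {}
    for (a, b), sub in data.groupby(["A", "B"], sort=True):
        if len(sub) >= 8:
            k2, p = stats.normaltest(sub["y"])
        else:
            k2, p = np.nan, np.nan
        norm_rows[(a, b)] = {"statistic": k2, "p_value": p, "n": len(sub)}
    normality = pd.DataFrame(norm_rows).T
    normality.index.names = [factor_a, factor_b]

    return AnovaTable(
        effects=effects,
        posthoc=posthoc,
        normality=normality,
        residual_df=residual_df,
        mse=mse,
    )
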