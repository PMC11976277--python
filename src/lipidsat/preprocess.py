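"""Loading, filtering, imputation and normalization of lipid amount tables.

The pipeline starts from a wide species × samples table of platform amounts
(one number per cell, blanks allowed) and applies, in this fixed order:

1. **Filtering** — a species is retained when it is detected (non-missing and
   strictly positive) in at least 80% of all non-blank samples *or* in at
   least 60% of the samples of some one group, *and* its mean amount over
   non-blank samples (missing counted as zero) is at least twofold the mean
   over blank samples.  Blank samples are dropped from the table afterwards.
2. **Imputation** — each remaining missing cell becomes the median of the
   non-missing values of the same species within the same sample group.
3. **Normalization** — amounts become proportions of either the sample's
   total lipid or of the sample's total within each lipid class.
4. **Centering** (optional) — every value is divided by the mean of the
   control-group samples for the same species within the same induction
   (batch), which removes multiplicative batch effects exactly.

The order matters: imputation before normalization is required because
missing values skew proportional data, and filtering must precede imputation
so that near-undetected species do not get invented group medians.
:func:`preprocess` drives the full sequence and is the only supported order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import LipidParseError, LipidSpecies, parse_species

__all__ = [
    "LipidTable",
    "FilterConfig",
    "FilterReport",
    "NormalizedTable",
    "load_table",
    "filter_species",
    "impute_missing",
    "normalize",
    "center_to_control",
    "preprocess",
]

METADATA_COLUMNS = ("group", "induction", "region", "is_blank")


@dataclass
class LipidTable:
    """Species × samples amount matrix with sample metadata.

    ``amounts`` is indexed by raw species name (rows) and sample id
    (columns); missing measurements are NaN.  ``species`` holds the parsed
    record for each row, aligned with ``amounts.index``.  ``samples`` is
    indexed by sample id with columns ``group``, ``induction``, ``region``
    and ``is_blank``.
    """

    amounts: pd.DataFrame
    species: list[LipidSpecies]
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.amounts.index.name = "species"
        self.amounts.columns.name = "sample_id"
        self.samples.index.name = "sample_id"
        if self.amounts.index.duplicated().any():
            dupes = self.amounts.index[self.amounts.index.duplicated()].tolist()
            raise ValueError(f"duplicate species names: {dupes}")
        if self.amounts.columns.duplicated().any():
            dupes = self.amounts.columns[self.amounts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if len(self.species) != len(self.amounts.index):
            raise ValueError(
                f"{len(self.species)} parsed species for "
                f"{len(self.amounts.index)} matrix rows"
            )
        missing_meta = self.amounts.columns.difference(self.samples.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata: {missing_meta.tolist()}")
        self.samples = self.samples.loc[self.amounts.columns]
        no_group = self.samples.index[
            ~self.samples["is_blank"].astype(bool) & self.samples["group"].isna()
        ]
        if len(no_group):
            raise ValueError(f"non-blank samples without a group: {no_group.tolist()}")

    @property
    def blank_ids(self) -> pd.Index:
        return self.samples.index[self.samples["is_blank"].astype(bool)]

    @property
    def nonblank_ids(self) -> pd.Index:
        return self.samples.index[~self.samples["is_blank"].astype(bool)]

    @property
    def class_codes(self) -> pd.Series:
        return pd.Series(
            [sp.class_code for sp in self.species], index=self.amounts.index
        )

    def groups(self) -> dict[str, pd.Index]:
        """Non-blank sample ids keyed by group label."""
        meta = self.samples.loc[self.nonblank_ids]
        return {g: sub.index for g, sub in meta.groupby("group", sort=True)}


@dataclass(frozen=True)
class FilterConfig:
    """Detection and blank thresholds for species filtering."""

    overall_detect_frac: float = 0.80
    group_detect_frac: float = 0.60
    blank_fold: float = 2.0

    def __post_init__(self) -> None:
        for name in ("overall_detect_frac", "group_detect_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.blank_fold <= 0:
            raise ValueError(f"blank_fold must be positive, got {self.blank_fold}")


@dataclass
class FilterReport:
    """Per-species retention verdicts and the failed criterion for drops."""

    verdicts: pd.DataFrame  # index species; columns retained, failed_criterion
    n_retained: int
    n_dropped: int

    def __post_init__(self) -> None:
        assert self.n_retained + self.n_dropped == len(self.verdicts)


@dataclass
class NormalizedTable:
    """Proportional lipid table: same shape as the input, values in [0, 1].

    ``mode`` is ``"total"`` (fractions of the sample's total lipid) or
    ``"per_class"`` (fractions of the sample's total within each lipid
    class).  ``centered`` marks tables divided by per-induction control
    means, after which values are ratios to control rather than proportions.
    """

    values: pd.DataFrame
    species: list[LipidSpecies]
    samples: pd.DataFrame
    mode: str
    centered: bool = False

    @property
    def class_codes(self) -> pd.Series:
        return pd.Series([sp.class_code for sp in self.species], index=self.values.index)

    def groups(self) -> dict[str, pd.Index]:
        return {
            g: sub.index for g, sub in self.samples.groupby("group", sort=True)
        }


def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    sep = "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, **kwargs)


def load_table(matrix_path: str | Path, metadata_path: str | Path) -> LipidTable:
    """Load an amount matrix (species rows × sample columns) plus metadata.

    The matrix file carries species names in the first column and sample ids
    in the header; empty cells become missing.  The metadata file needs a
    ``sample_id`` column plus ``group``; ``induction``, ``region`` and
    ``is_blank`` are optional and default to unlabelled / non-blank.
    """
    raw = _read_delimited(matrix_path, index_col=0)
    raw.index = raw.index.astype(str).str.strip()
    amounts = raw.apply(pd.to_numeric, errors="coerce").astype(float)
    if (amounts.to_numpy() < 0).any():
        raise ValueError(f"negative amounts in {matrix_path}")

    meta = _read_delimited(metadata_path)
    if "sample_id" not in meta.columns:
        raise ValueError(f"metadata {metadata_path} lacks a 'sample_id' column")
    meta = meta.set_index(meta["sample_id"].astype(str)).drop(columns="sample_id")
    if meta.index.duplicated().any():
        raise ValueError(
            f"duplicate sample ids in metadata: "
            f"{meta.index[meta.index.duplicated()].tolist()}"
        )
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            meta[col] = False if col == "is_blank" else None
    meta["is_blank"] = (
        meta["is_blank"].map(
            lambda v: str(v).strip().lower() in ("true", "1", "yes")
        )
        if meta["is_blank"].dtype == object
        else meta["is_blank"].fillna(False).astype(bool)
    )
    meta = meta[list(METADATA_COLUMNS)]

    unknown = amounts.columns.difference(meta.index)
    if len(unknown):
        raise ValueError(
            f"matrix samples missing from metadata: {unknown.tolist()}"
        )

    species = []
    for name in amounts.index:
        try:
            species.append(parse_species(name))
        except LipidParseError as exc:
            raise LipidParseError(f"row {name!r} of {matrix_path}: {exc}") from exc
    return LipidTable(amounts=amounts, species=species, samples=meta)


def filter_species(
    table: LipidTable, config: FilterConfig | None = None
) -> tuple[LipidTable, FilterReport]:
    """Apply the detection and blank filters; drop blanks from the output.

    Retention requires (detected in >= ``overall_detect_frac`` of all
    non-blank samples OR >= ``group_detect_frac`` of at least one group's
    samples) AND mean over non-blank samples (missing as 0) >=
    ``blank_fold`` × mean over blanks.  With no blank samples the blank rule
    passes vacuously and a warning is logged.
    """
    config = config or FilterConfig()
    nonblank = table.nonblank_ids
    if len(nonblank) == 0:
        raise ValueError("table has no non-blank samples")
    groups = table.groups()
    for g, ids in groups.items():
        if len(ids) == 0:
            raise ValueError(f"group {g!r} has no samples")

    values = table.amounts
    detected = values[nonblank].notna() & (values[nonblank] > 0)
    overall_frac = detected.mean(axis=1)
    group_frac = pd.concat(
        {g: detected[ids].mean(axis=1) for g, ids in groups.items()}, axis=1
    ).max(axis=1)
    detect_ok = (overall_frac >= config.overall_detect_frac) | (
        group_frac >= config.group_detect_frac
    )

    sample_mean = values[nonblank].fillna(0.0).mean(axis=1)
    blanks = table.blank_ids
    if len(blanks) == 0:
        warnings.warn(
            "no blank samples: blank-fold rule passes vacuously", stacklevel=2
        )
        blank_ok = pd.Series(True, index=values.index)
    else:
        blank_mean = values[blanks].fillna(0.0).mean(axis=1)
        blank_ok = sample_mean >= config.blank_fold * blank_mean

    retained = detect_ok & blank_ok
    criterion = np.where(
        retained,
        "",
        np.where(
            ~detect_ok & ~blank_ok,
            "detection;blank",
            np.where(~detect_ok, "detection", "blank"),
        ),
    )
    report = FilterReport(
        verdicts=pd.DataFrame(
            {"retained": retained, "failed_criterion": criterion},
            index=values.index,
        ),
        n_retained=int(retained.sum()),
        n_dropped=int((~retained).sum()),
    )
    kept_names = values.index[retained]
    filtered = LipidTable(
        amounts=values.loc[kept_names, nonblank].copy(),
        species=[sp for sp, keep in zip(table.species, retained) if keep],
        samples=table.samples.loc[nonblank].copy(),
    )
    return filtered, report


def impute_missing(table: LipidTable) -> LipidTable:
    """Replace missing cells by the within-group median of the same species.

    Cells in a (species, group) stratum with no observed value at all stay
    missing; a warning reports how many.  Idempotent.
    """
    values = table.amounts.copy()
    for _, ids in table.groups().items():
        block = values[ids]
        med = block.median(axis=1)  # skips NaN; NaN when all missing
        values[ids] = block.apply(lambda col: col.fillna(med))
    left_over = int(values.isna().sum().sum())
    if left_over:
        warnings.warn(
            f"{left_over} cells remain missing after imputation "
            "(entire group missing for the species)",
            stacklevel=2,
        )
    return LipidTable(amounts=values, species=list(table.species), samples=table.samples.copy())


def normalize(table: LipidTable, mode: str = "per_class") -> NormalizedTable:
    """Convert amounts to proportions of total lipid or of each lipid class.

    Missing cells are excluded from denominators and stay missing.  A sample
    (or sample-class stratum) whose observed values sum to zero raises,
    naming the offender.
    """
    if mode not in ("total", "per_class"):
        raise ValueError(f"mode must be 'total' or 'per_class', got {mode!r}")
    values = table.amounts
    if mode == "total":
        denom = values.sum(axis=0)  # NaN-skipping
        zero = denom[(denom <= 0)]
        if len(zero):
            raise ValueError(f"zero total lipid mass in sample {zero.index[0]!r}")
        out = values.div(denom, axis=1)
    else:
        out = pd.DataFrame(
            np.nan, index=values.index, columns=values.columns, dtype=float
        )
        for cls, rows in values.groupby(table.class_codes.values):
            denom = rows.sum(axis=0)
            observed = rows.notna().any(axis=0)
            bad = observed & (denom <= 0)
            if bad.any():
                raise ValueError(
                    f"zero {cls} mass in sample {denom.index[bad][0]!r}"
                )
            scaled = rows.div(denom.where(denom > 0), axis=1)
            out.loc[rows.index] = scaled
    return NormalizedTable(
        values=out,
        species=list(table.species),
        samples=table.samples.copy(),
        mode=mode,
    )


def center_to_control(
    norm: NormalizedTable, control_group: str
) -> NormalizedTable:
    """Divide every value by the per-induction control mean of its species.

    After centering, the control group's per-induction species means are
    exactly 1 and multiplicative induction (batch) effects cancel.  Samples
    without an induction label are treated as one shared batch.  An
    induction with no control samples raises; species whose control mean is
    zero (or unobserved) in a batch come out missing and a warning counts
    them.
    """
    values = norm.values.copy()
    meta = norm.samples
    induction = meta["induction"].fillna("__single__")
    n_flagged = 0
    for ind, sub in meta.groupby(induction, sort=False):
        cols = sub.index
        ctrl = cols[sub["group"] == control_group]
        if len(ctrl) == 0:
            raise ValueError(
                f"induction {ind!r} has no samples of control group "
                f"{control_group!r}"
            )
        ctrl_mean = values[ctrl].mean(axis=1)
        bad = ctrl_mean.isna() | (ctrl_mean <= 0)
        n_flagged += int(bad.sum())
        values[cols] = values[cols].div(ctrl_mean.where(~bad), axis=0)
    if n_flagged:
        warnings.warn(
            f"{n_flagged} species × induction strata had zero or missing "
            "control means; centered values flagged missing",
            stacklevel=2,
        )
    return NormalizedTable(
        values=values,
        species=list(norm.species),
        samples=norm.samples.copy(),
        mode=norm.mode,
        centered=True,
    )


@dataclass
class PreprocessResult:
    """Everything the pipeline driver produced, in processing order."""

    filtered: LipidTable
    report: FilterReport
    imputed: LipidTable
    normalized: NormalizedTable
    centered: NormalizedTable | None = None

    @property
    def final(self) -> NormalizedTable:
        return self.centered if self.centered is not None else self.normalized


def preprocess(
    table: LipidTable,
    config: FilterConfig | None = None,
    mode: str = "per_class",
    center_control: str | None = None,
) -> PreprocessResult:
    """Run filter → impute → normalize (→ center) in the only supported order."""
    filtered, report = filter_species(table, config)
    imputed = impute_missing(filtered)
    normalized = normalize(imputed, mode=mode)
    centered = (
        center_to_control(normalized, center_control)
        if center_control is not None
        else None
    )
    return PreprocessResult(
        filtered=filtered,
        report=report,
        imputed=imputed,
        normalized=normalized,
        centered=centered,
    )
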