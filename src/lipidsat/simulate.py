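"""Synthetic Lipidyzer-style lipidomes and survival data with known truth.

The generator emulates the statistical structure of a targeted lipidomics
experiment at desk scale: a panel of a few hundred species across the major
lipid classes with realistic acyl-chain compositions, log-normal baseline
abundances spanning orders of magnitude, abundance-dependent dropout
(low-abundance species go missing more often), process blanks at a small
fraction of the median signal, multiplicative induction (batch) shifts, and
— the effect of interest — a multiplicative depletion δ applied in the case
group to every species whose most unsaturated chain carries at least
``depletion_threshold`` double bonds (4 in the human-style default; 2 in fly
mode, where chains rarely exceed three double bonds).

Every random draw flows from the single config seed, so identical configs
produce identical tables, and the emitted :class:`GroundTruth` records the
per-species effect, batch factors and dropout mask for parameter-recovery
tests.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_stats import SurvivalDataset
from .nomenclature import (
    AcylChain,
    EXPECTED_CHAIN_COUNT,
    LipidSpecies,
    format_species,
)
from .preprocess import LipidTable, METADATA_COLUMNS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_lipidome",
    "generate_survival",
    "write_fixtures",
    "HUMAN_CHAIN_POOL",
    "FLY_CHAIN_POOL",
    "ftld_cohort_config",
    "fly_brain_config",
]

# Acyl-chain sampling pools: (carbons, double_bonds) -> relative weight.
# Chains with >=4 double bonds carry ~6% of the weight so that highly
# unsaturated species make up a modest (~10-15%) share of each class's mass,
# as on a real targeted panel where most species per class are di- or
# mono-unsaturated.
HUMAN_CHAIN_POOL: dict[tuple[int, int], float] = {
    (14, 0): 0.05, (16, 0): 0.15, (16, 1): 0.07,
    (18, 0): 0.13, (18, 1): 0.18, (18, 2): 0.14, (18, 3): 0.05,
    (20, 1): 0.04, (20, 2): 0.04, (20, 3): 0.09,
    (20, 4): 0.025, (20, 5): 0.010,
    (22, 4): 0.005, (22, 5): 0.005, (22, 6): 0.015,
}

# Fly membranes are dominated by C12-C18 chains with at most three double
# bonds; "fly mode" therefore also lowers the depletion threshold to 2.
FLY_CHAIN_POOL: dict[tuple[int, int], float] = {
    (12, 0): 0.05, (14, 0): 0.10, (14, 1): 0.08,
    (16, 0): 0.20, (16, 1): 0.15, (18, 0): 0.12,
    (18, 1): 0.18, (18, 2): 0.08, (18, 3): 0.04,
}

DEFAULT_CLASS_SIZES: dict[str, int] = {
    "PC": 60, "PE": 50, "PS": 30, "PI": 25,
    "LPC": 12, "LPE": 10, "SM": 20,
    "DAG": 40, "TAG": 38, "FFA": 15,
}

FLY_CLASS_SIZES: dict[str, int] = {
    "PC": 40, "PE": 40, "PS": 20, "PI": 15,
    "LPC": 8, "LPE": 6, "DAG": 25, "TAG": 30, "FFA": 9,
}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the lipidome generator; defaults are the human-style study.

    ``groups`` maps group label to samples per group (per region when
    ``regions`` is set), split as evenly as possible across ``inductions``.
    ``depletion`` multiplies case-group amounts of species at or above
    ``depletion_threshold`` double bonds, optionally only within
    ``depleted_regions``.  ``sample_unsat_sigma`` adds a per-sample
    log-normal tilt to those same high-unsaturation species, modelling
    between-individual variability in overall membrane unsaturation.
    """

    seed: int = 0
    class_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    chain_pool: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(HUMAN_CHAIN_POOL)
    )
    groups: Mapping[str, int] = field(
        default_factory=lambda: {"control": 6, "case": 6}
    )
    case_group: str = "case"
    inductions: Sequence[str] = ("I1",)
    batch_shifts: Mapping[str, float] = field(default_factory=dict)
    regions: Sequence[str] | None = None
    depleted_regions: Sequence[str] | None = None  # None -> all regions
    region_effects: Mapping[str, float] = field(default_factory=dict)
    n_blanks: int = 3
    blank_scale: float = 0.05  # blank level as a fraction of median baseline
    log_mu: float = 0.0
    log_mu_spread: float = 1.5  # sd of log baseline across species
    noise_sigma: float = 0.25  # per-cell log-normal measurement/biology noise
    sample_unsat_sigma: float = 0.0
    depletion: float = 1.0
    depletion_threshold: int = 4
    dropout_max: float = 0.25  # dropout probability floor-to-ceiling
    dropout_quantile: float = 0.05  # baseline quantile at the logistic midpoint
    dropout_width: float = 1.0  # logistic width on the log-abundance scale
    abundance_coupling: float = 0.5  # baseline ∝ (chain-combination weight)^this

    def __post_init__(self) -> None:
        if self.depletion <= 0:
            raise ValueError(f"depletion must be > 0, got {self.depletion}")
        if not 0.0 <= self.dropout_max <= 1.0:
            raise ValueError("dropout_max must lie in [0, 1]")
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("every class needs n_species > 0")
        if self.case_group not in self.groups:
            raise ValueError(
                f"case_group {self.case_group!r} absent from groups"
            )
        for (c, n) in self.chain_pool:
            if n >= c:
                raise ValueError(
                    f"impossible chain template {c}:{n} (double bonds >= carbons)"
                )


def ftld_cohort_config(seed: int = 0, depletion: float = 0.7) -> SimConfig:
    """Postmortem-cohort-style config: region × disease, unbalanced groups.

    13 control versus 45 disease samples per region, a group-specific
    depletion of highly unsaturated species, a lower cerebellar baseline for
    the same species (driving the region main effect), and a per-sample
    unsaturation tilt that dominates the index noise.  Restricting the
    depletion to the affected region is available through
    ``depleted_regions`` for sensitivity analyses.
    """
    return SimConfig(
        seed=seed,
        groups={"control": 13, "FTLD": 45},
        case_group="FTLD",
        regions=("frontal_cortex", "cerebellum"),
        region_effects={"cerebellum": 0.8},
        sample_unsat_sigma=0.15,
        depletion=depletion,
        depletion_threshold=4,
    )


def fly_brain_config(seed: int = 0, depletion: float = 1.0) -> SimConfig:
    """Fly-brain-style config: short-chain pool, PUFA threshold of 2 double
    bonds, three pooled-brain replicates per genotype."""
    return SimConfig(
        seed=seed,
        class_sizes=dict(FLY_CLASS_SIZES),
        chain_pool=dict(FLY_CHAIN_POOL),
        groups={"control": 3, "case": 3},
        depletion=depletion,
        depletion_threshold=2,
    )


@dataclass
class GroundTruth:
    """Per-species effects and per-sample factors behind a generated table."""

    deltas: pd.Series  # per species: depletion applied in the case group
    batch_factors: pd.Series  # per sample: induction multiplicative shift
    unsat_tilts: pd.Series  # per sample: tilt applied to high-DB species
    dropout: pd.DataFrame  # species × samples boolean mask of dropped cells
    config: SimConfig


def _build_panel(
    config: SimConfig, rng: np.random.Generator
) -> tuple[list[LipidSpecies], np.ndarray]:
    """Draw unique species per class from the chain pool, chains sorted.

    Returns the panel plus each species' chain-combination weight (the
    product of its chains' pool weights), which the generator couples to
    baseline abundance: species made of common chains dominate their class's
    mass, as on real panels, keeping rare highly unsaturated combinations a
    modest share of class totals.
    """
    chains = list(config.chain_pool)
    weights = np.array([config.chain_pool[c] for c in chains], dtype=float)
    weights = weights / weights.sum()
    panel: list[LipidSpecies] = []
    panel_w: list[float] = []
    for cls, n_species in config.class_sizes.items():
        n_chains = EXPECTED_CHAIN_COUNT.get(cls, 2)
        combos = list(
            itertools.combinations_with_replacement(range(len(chains)), n_chains)
        )
        combo_w = np.array(
            [math.prod(weights[i] for i in combo) for combo in combos]
        )
        combo_w = combo_w / combo_w.sum()
        if n_species > len(combos):
            raise ValueError(
                f"class {cls}: {n_species} species requested but only "
                f"{len(combos)} distinct chain combinations exist"
            )
        picks = rng.choice(len(combos), size=n_species, replace=False, p=combo_w)
        for pick in sorted(picks):
            combo = combos[pick]
            acyls = tuple(
                AcylChain(*chains[i]) for i in sorted(combo, key=lambda i: chains[i])
            )
            sp = LipidSpecies(
                raw_name="",
                class_code=cls,
                chains=acyls,
                sn_resolved=False,
            )
            panel.append(replace(sp, raw_name=format_species(sp)))
            panel_w.append(float(combo_w[pick]))
    return panel, np.asarray(panel_w)


def _sample_frame(config: SimConfig) -> pd.DataFrame:
    """Enumerate sample metadata rows for groups × regions × inductions."""
    inductions = list(config.inductions)
    regions = list(config.regions) if config.regions is not None else [None]
    rows = []
    for region in regions:
        for group, n in config.groups.items():
            for i in range(n):
                induction = inductions[i % len(inductions)]
                tag = f"_{region}" if region is not None else ""
                rows.append(
                    {
                        "sample_id": f"{group}{tag}_{i + 1}",
                        "group": group,
                        "induction": induction,
                        "region": region,
                        "is_blank": False,
                    }
                )
    for i in range(config.n_blanks):
        rows.append(
            {
                "sample_id": f"blank_{i + 1}",
                "group": None,
                "induction": inductions[i % len(inductions)],
                "region": None,
                "is_blank": True,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_lipidome(config: SimConfig) -> tuple[LipidTable, GroundTruth]:
    """Generate one lipidome table plus the ground truth that produced it.

    Amounts are drawn log-normally around per-species baselines; the case
    group's targeted species are multiplied by δ; induction shifts, region
    effects and per-sample unsaturation tilts apply multiplicatively; blanks
    sit at ``blank_scale`` × the median baseline; dropout is logistic in log
    abundance.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    panel, combo_w = _build_panel(config, rng)
    samples = _sample_frame(config)
    names = pd.Index([sp.raw_name for sp in panel], name="species")

    n_species, n_samples = len(panel), len(samples)
    max_db = np.array([sp.max_double_bonds for sp in panel])
    targeted = max_db >= config.depletion_threshold

    rarity = (combo_w / np.median(combo_w)) ** config.abundance_coupling
    baseline = rarity * np.exp(
        rng.normal(config.log_mu, config.log_mu_spread, size=n_species)
    )
    deltas = np.where(targeted, config.depletion, 1.0)

    is_blank = samples["is_blank"].to_numpy(dtype=bool)
    group = samples["group"].to_numpy(dtype=object)
    region = samples["region"].to_numpy(dtype=object)
    induction = samples["induction"].to_numpy(dtype=object)

    batch = np.array(
        [config.batch_shifts.get(b, 1.0) for b in induction], dtype=float
    )
    tilts = np.exp(
        rng.normal(0.0, config.sample_unsat_sigma, size=n_samples)
        if config.sample_unsat_sigma > 0
        else np.zeros(n_samples)
    )
    region_factor = np.array(
        [
            config.region_effects.get(r, 1.0) if r is not None else 1.0
            for r in region
        ],
        dtype=float,
    )
    depleted_here = np.array(
        [
            g == config.case_group
            and (
                config.depleted_regions is None
                or r in set(config.depleted_regions)
            )
            for g, r in zip(group, region)
        ],
        dtype=bool,
    )

    noise = np.exp(rng.normal(0.0, config.noise_sigma, size=(n_species, n_samples)))
    amounts = baseline[:, None] * noise * batch[None, :]
    # effects acting only on high-unsaturation species
    hi = targeted[:, None]
    amounts = np.where(hi, amounts * tilts[None, :] * region_factor[None, :], amounts)
    amounts = np.where(
        hi & depleted_here[None, :], amounts * config.depletion, amounts
    )
    # blanks: flat low-level signal replacing the biological values
    blank_level = config.blank_scale * float(np.median(baseline))
    blank_noise = np.exp(
        rng.normal(0.0, config.noise_sigma, size=(n_species, n_samples))
    )
    amounts = np.where(is_blank[None, :], blank_level * blank_noise, amounts)

    # abundance-dependent dropout: logistic, decreasing in log amount
    log_mid = np.quantile(
        np.log(baseline), config.dropout_quantile
    )
    with np.errstate(over="ignore"):
        p_drop = config.dropout_max / (
            1.0 + np.exp((np.log(amounts) - log_mid) / config.dropout_width)
        )
    dropped = rng.uniform(size=amounts.shape) < p_drop
    amounts = np.where(dropped, np.nan, amounts)

    table = LipidTable(
        amounts=pd.DataFrame(amounts, index=names, columns=samples.index),
        species=panel,
        samples=samples,
    )
    truth = GroundTruth(
        deltas=pd.Series(deltas, index=names, name="delta"),
        batch_factors=pd.Series(batch, index=samples.index, name="batch_factor"),
        unsat_tilts=pd.Series(tilts, index=samples.index, name="unsat_tilt"),
        dropout=pd.DataFrame(dropped, index=names, columns=samples.index),
        config=config,
    )
    return table, truth


def generate_survival(
    n_per_group: int,
    control_median: float,
    effect: float = 1.0,
    seed: int = 0,
    distribution: str = "exponential",
    weibull_shape: float = 2.0,
) -> tuple[SurvivalDataset, SurvivalDataset]:
    """Discrete-day survival data for a control and a treated group.

    Event days are ceilings of continuous exponential (default) or Weibull
    draws whose continuous median equals ``control_median``; the treated
    group's hazard is scaled by ``effect`` (a hazard ratio below 1 extends
    survival: for the exponential, treated median = control median /
    effect).
    """
    if n_per_group <= 0 or control_median <= 0 or effect <= 0:
        raise ValueError("n_per_group, control_median and effect must be positive")
    rng = np.random.default_rng(seed)

    def _draw(hazard_scale: float) -> np.ndarray:
        if distribution == "exponential":
            rate = math.log(2.0) / control_median * hazard_scale
            t = rng.exponential(1.0 / rate, size=n_per_group)
        elif distribution == "weibull":
            scale = control_median / math.log(2.0) ** (1.0 / weibull_shape)
            scale = scale * hazard_scale ** (-1.0 / weibull_shape)
            t = scale * rng.weibull(weibull_shape, size=n_per_group)
        else:
            raise ValueError(f"unknown distribution {distribution!r}")
        return np.maximum(np.ceil(t), 1.0)

    control = SurvivalDataset(days=_draw(1.0), group="control")
    treated = SurvivalDataset(days=_draw(effect), group="treated")
    return control, treated


def write_fixtures(
    table: LipidTable, truth: GroundTruth, directory: str | Path
) -> dict[str, Path]:
    """Write matrix.csv + metadata.csv in the dialect ``load_table`` reads,
    plus truth.json; returns the paths keyed by role."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    matrix_path = directory / "matrix.csv"
    metadata_path = directory / "metadata.csv"
    truth_path = directory / "truth.json"

    table.amounts.to_csv(matrix_path, index_label="species")
    meta = table.samples.reset_index()[["sample_id", *METADATA_COLUMNS]]
    meta.to_csv(metadata_path, index=False)

    payload = {
        "seed": truth.config.seed,
        "depletion": truth.config.depletion,
        "depletion_threshold": truth.config.depletion_threshold,
        "deltas": {k: float(v) for k, v in truth.deltas.items()},
        "batch_factors": {
            k: float(v) for k, v in truth.batch_factors.items()
        },
    }
    truth_path.write_text(json.dumps(payload, indent=1))
    return {"matrix": matrix_path, "metadata": metadata_path, "truth": truth_path}
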