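import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lipidsat as L

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_lipid_table(data, samples):
    """Build a LipidTable from {species_name: values} and
    (sample_id, group, induction, region, is_blank) tuples."""
    meta = pd.DataFrame(
        samples,
        columns=["sample_id", "group", "induction", "region", "is_blank"],
    ).set_index("sample_id")
    amounts = pd.DataFrame(
        {name: pd.array(vals, dtype=float) for name, vals in data.items()},
        index=meta.index,
    ).T
    species = [L.parse_species(name) for name in amounts.index]
    return L.LipidTable(amounts=amounts, species=species, samples=meta)


def two_group_samples(n_a=5, n_b=5, n_blank=2):
    rows = [(f"A{i+1}", "A", "I1", None, False) for i in range(n_a)]
    rows += [(f"B{i+1}", "B", "I1", None, False) for i in range(n_b)]
    rows += [(f"BL{i+1}", None, "I1", None, True) for i in range(n_blank)]
    return rows


@pytest.fixture
def toy_filter_table():
    """Ten species crafted so every filtering rule fires at least once.

    Returns the table plus the by-hand verdicts: retained flag and, for
    drops, which criterion failed.
    """
    x = None  # missing cell
    data = {
        # detected everywhere, blanks silent -> retained
        "PC(16:0_18:1)": [10, 10, 10, 10, 10, 10, 10, 10, 10, 10, 0, 0],
        # detected 9/10 >= 80% -> retained
        "PC(18:0_20:4)": [8, 8, 8, 8, x, 8, 8, 8, 8, 8, 0, 0],
        # 7/10 < 80% but all of group A -> retained via the 60% group rule
        "PE(16:0_18:1)": [5, 5, 5, 5, 5, 5, 5, x, x, x, 0, 0],
        # 5/10 overall, exactly 3/5 = 60% of group A -> retained (boundary)
        "PE(18:1_18:2)": [4, 4, 4, x, x, x, x, 4, 4, x, 0, 0],
        # 4/10 overall, 40% in each group -> dropped on detection
        "PS(16:0_22:6)": [3, 3, x, x, x, 3, 3, x, x, x, 0, 0],
        # well detected but mean 1.9 < 2 x blank mean 1.0 -> dropped on blank
        "PI(16:0_20:3)": [1.9] * 10 + [1.0, 1.0],
        # mean exactly 2 x blank mean -> retained (>= comparison)
        "SM(18:0_16:0)": [2.0] * 10 + [1.0, 1.0],
        # sparse and below the blank bar -> both criteria fail
        "LPC(18:1)": [0.5, 0.4, x, x, x, 0.3, x, x, x, x, 0.5, 0.5],
        # zeros are not detections: 4/5 of group A detected -> retained
        "TAG(16:0_18:1_18:2)": [6, 6, 6, 6, 0, 0, 0, 0, 6, 6, 0, 0],
        # detected in 2/10 only -> dropped on detection
        "FFA(20:4)": [1, x, x, x, x, 1, x, x, x, x, 0, 0],
    }
    expected = {
        "PC(16:0_18:1)": (True, ""),
        "PC(18:0_20:4)": (True, ""),
        "PE(16:0_18:1)": (True, ""),
        "PE(18:1_18:2)": (True, ""),
        "PS(16:0_22:6)": (False, "detection"),
        "PI(16:0_20:3)": (False, "blank"),
        "SM(18:0_16:0)": (True, ""),
        "LPC(18:1)": (False, "detection;blank"),
        "TAG(16:0_18:1_18:2)": (True, ""),
        "FFA(20:4)": (False, "detection"),
    }
    return make_lipid_table(data, two_group_samples()), expected


@pytest.fixture(scope="session")
def depleted_run():
    """One standard depletion simulation (delta=0.5) through the pipeline."""
    table, truth = L.generate_lipidome(L.SimConfig(seed=42, depletion=0.5))
    result = L.preprocess(table)
    rows = L.group_fold_changes(result.final, "case", "control")
    return table, truth, result, rows


def make_normalized(values, samples, mode="per_class"):
    """NormalizedTable straight from a values dict (no pipeline)."""
    table = make_lipid_table(values, samples)
    return L.NormalizedTable(
        values=table.amounts,
        species=table.species,
        samples=table.samples,
        mode=mode,
    )
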