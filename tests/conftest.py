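import numpy as np
import pandas as pd
import pytest

from shockmetab import MetabolomicsDataset, PlantedEffect, SimulationConfig


def make_dataset(values, animals, timepoints, groups=None, compartment="serum",
                 names=None, urine_output=None, units="mM", kind="raw"):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if names is None:
        names = [f"met{j + 1:03d}" for j in range(p)]
    if groups is None:
        groups = ["CPF" if a.startswith("CPF") else "FS" for a in animals]
    meta = pd.DataFrame({"animal_id": list(animals), "group": list(groups),
                         "compartment": compartment, "timepoint": list(timepoints)})
    if urine_output is not None:
        meta["urine_output"] = urine_output
    return MetabolomicsDataset(values=values, metabolite_names=names,
                               sample_meta=meta, units=units, kind=kind)


@pytest.fixture
def toy_dataset():
    """4 samples (2 animals x 2 timepoints), 2 metabolites."""
    return make_dataset(
        values=[[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]],
        animals=["CPF01", "CPF01", "FS01", "FS01"],
        timepoints=["B", "S45", "B", "S45"])


@pytest.fixture
def two_group_config():
    """Small complete-followup study with one strong serum baseline effect."""
    return SimulationConfig(
        n_per_group=10, panel_sizes={"serum": 12},
        planted_effects=[PlantedEffect("serum", "B", 0, 3.0)],
        dropout={"CPF": 0.0, "FS": 0.0}, seed=11)


def separable_xy(n_per_class=12, p=6, gap=6.0, seed=0):
    """Linearly separable two-class matrix for CV sanity checks."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_class, p))
    X[:n_per_class, 0] += gap
    y = np.array(["CPF"] * n_per_class + ["FS"] * n_per_class)
    return X, y
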