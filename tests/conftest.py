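import numpy as np
import pandas as pd
import pytest

from tipca import (
    CompartmentSet,
    KineticsConfig,
    MediatorPanel,
    TimecourseDataset,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_cfg() -> KineticsConfig:
    return KineticsConfig()


@pytest.fixture(scope="session")
def wt_dataset(default_cfg):
    """One default synthetic dataset shared across read-only tests."""
    ds, truth = simulate_dataset(default_cfg, seed=11)
    return ds, truth


def make_dataset(values, mediators=("m1", "m2"), compartments=("plasma",),
                 times=(0.0,), genotype="WT"):
    """Small hand-built dataset: values[mouse][time][compartment][mediator].

    ``values`` is a dict {mouse_id: {time: {(mediator, compartment): conc}}}.
    """
    rows = []
    for mouse, by_time in values.items():
        for t, cells in by_time.items():
            for (m, c), v in cells.items():
                rows.append({"mouse_id": mouse, "genotype": genotype,
                             "time_h": float(t), "compartment": c,
                             "mediator": m, "concentration": v})
    return TimecourseDataset(
        pd.DataFrame(rows),
        panel=MediatorPanel(tuple(mediators)),
        compartments=CompartmentSet(tuple(compartments),
                                    plasma_label=compartments[0]),
        sampling_times=tuple(sorted({0.0, *map(float, times)})),
    )


@pytest.fixture
def two_var_dataset():
    """Four mice at t=0, two perfectly correlated mediators in plasma."""
    vals = {}
    for i, x in enumerate([1.0, 2.0, 3.0, 4.0]):
        vals[f"m{i}"] = {0.0: {("m1", "plasma"): x, ("m2", "plasma"): 2 * x + 1}}
    return make_dataset(vals)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
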