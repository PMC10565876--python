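import numpy as np
import pandas as pd
import pytest

from pulsedcaf.io_formats import ExperimentDesign, IntensityTable


@pytest.fixture
def two_condition_design() -> ExperimentDesign:
    """4 + 4 light-channel samples at a single timepoint."""
    rows = []
    for cond, role in (("DCAF", "test"), ("BirA", "reference")):
        for rep in range(1, 5):
            rows.append(
                {
                    "sample_id": f"{cond}_r{rep}",
                    "condition": cond,
                    "replicate": rep,
                    "timepoint_h": 16.0,
                    "channel": "light",
                    "role": role,
                }
            )
    return ExperimentDesign(pd.DataFrame(rows))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_table(values: np.ndarray, samples: list[str], proteins: list[str] | None = None) -> IntensityTable:
    values = np.asarray(values, dtype=float)
    if proteins is None:
        proteins = [f"P{i + 1:03d}" for i in range(values.shape[0])]
    return IntensityTable(pd.DataFrame(values, index=proteins, columns=samples))


@pytest.fixture
def protein_groups_text() -> str:
    """Minimal 3-row proteinGroups dialect with one reverse hit and one zero."""
    header = "\t".join(
        [
            "Majority protein IDs",
            "Gene names",
            "Unique peptides",
            "Reverse",
            "Potential contaminant",
            "Only identified by site",
            "Intensity L s1",
            "Intensity H s1",
            "Intensity L s2",
            "Intensity H s2",
        ]
    )
    rows = [
        "P1;P1b\tGENE1\t5\t\t\t\t1000\t2000\t1500\t2500",
        "P2\tGENE2\t3\t+\t\t\t800\t1600\t900\t1800",
        "P3\tGENE3\t2\t\t\t\t0\t500\t600\t700",
    ]
    return header + "\n" + "\n".join(rows) + "\n"


@pytest.fixture
def pulldown_design() -> ExperimentDesign:
    """Paired heavy/light design: one run per replicate carrying both channels."""
    rows = []
    for rep in (1, 2):
        sid = f"s{rep}"
        for ch in ("light", "heavy"):
            rows.append(
                {
                    "sample_id": sid,
                    "condition": "pulldown",
                    "replicate": rep,
                    "timepoint_h": 0.0,
                    "channel": ch,
                    "role": "test",
                }
            )
    return ExperimentDesign(pd.DataFrame(rows))
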