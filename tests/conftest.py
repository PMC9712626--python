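import numpy as np
import pandas as pd
import pytest

from irtax.synthetic import SimConfig, default_design
from irtax.types import PIRMatrix, SampleSheet


@pytest.fixture(scope="session")
def design() -> SampleSheet:
    return default_design()


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Reduced problem sizes for fast unit tests."""
    return SimConfig(seed=42, n_introns_per_group=30, noise_sd=5.0, n_genes=400)


@pytest.fixture()
def tiny_sheet() -> SampleSheet:
    """2 conditions x 2 clones x both fractions (8 samples)."""
    rows = []
    for frac in ("nucleus", "cytoplasm"):
        for div in (7, 14):
            for clone, gt, pt in (("c1", "control", "p1"), ("m1", "mutant", "p2")):
                rows.append(
                    {
                        "sample_id": f"{frac[:3]}{div}_{clone}",
                        "fraction": frac,
                        "div_day": div,
                        "genotype": gt,
                        "clone_id": clone,
                        "patient_id": pt,
                    }
                )
    return SampleSheet(pd.DataFrame(rows))


def make_pir(values, sheet: SampleSheet, intron_ids=None) -> PIRMatrix:
    values = np.asarray(values, dtype=float)
    intron_ids = intron_ids or [f"intron{i}" for i in range(values.shape[0])]
    return PIRMatrix(pd.DataFrame(values, index=intron_ids, columns=sheet.sample_ids), sheet)


@pytest.fixture()
def pir_factory():
    return make_pir
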