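import numpy as np
import pandas as pd
import pytest

from methcord import (MethylationMatrix, SampleSheet, SimulationConfig,
                      batch_correct, generate_dataset)


@pytest.fixture(scope="session")
def planted_data():
    """Default study conditions at a modest number of sites: 12 subjects,
    two batches, 10% planted SMPs and 10% planted DMPs."""
    return generate_dataset(SimulationConfig(n_sites=2000, seed=11))


@pytest.fixture(scope="session")
def corrected_m(planted_data):
    """Batch-corrected M-values of the planted dataset."""
    return batch_correct(planted_data.mvalues, planted_data.sheet)


@pytest.fixture(scope="session")
def null_data():
    """All-null dataset without a batch effect (clean exchangeability null)."""
    return generate_dataset(SimulationConfig(
        n_sites=2000, frac_smp=0.0, frac_dmp=0.0, batch_shift=0.0, seed=23))


@pytest.fixture
def tiny_sheet():
    """Three matched pairs, single batch."""
    rows = []
    for j, age in zip(range(1, 4), (70.0, 75.0, 80.0)):
        for tissue in ("bone", "blood"):
            rows.append({"sample_id": f"S{j}_{tissue}", "subject_id": f"S{j}",
                         "tissue": tissue, "batch": "B1", "age": age})
    return SampleSheet(pd.DataFrame(rows))


def paired_matrix(bone_rows, blood_rows, sheet, domain):
    """Build a matrix from separate per-tissue arrays (sites x subjects)."""
    bone_ids, blood_ids = sheet.paired_samples()
    bone = np.asarray(bone_rows, float)
    blood = np.asarray(blood_rows, float)
    idx = [f"cg{i:04d}" for i in range(len(bone))]
    frame = pd.concat([
        pd.DataFrame(bone, index=idx, columns=bone_ids),
        pd.DataFrame(blood, index=idx, columns=blood_ids),
    ], axis=1)
    return MethylationMatrix(frame, domain)
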