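import numpy as np
import pytest

from ffproteo.cohort import (AbundanceDataset, CohortConfig, SampleRecord,
                             simulate_cohort)


@pytest.fixture(scope="session")
def small_cohort() -> AbundanceDataset:
    """24 patients, 8 proteins, mild noise; reused across read-only tests."""
    cfg = CohortConfig(n_pcos_patients=12, n_control_patients=12,
                       n_proteins=8, patient_sd=0.1, fluid_sd=0.1,
                       repeat_sd=0.1, seed=42)
    return simulate_cohort(cfg)


@pytest.fixture
def tiny_dataset() -> AbundanceDataset:
    """Hand-built 6-row, 3-protein dataset (2 patients x 1 fluid x 3 repeats)."""
    rows = [
        SampleRecord("P1", "pcos", "F1", 1),
        SampleRecord("P1", "pcos", "F1", 2),
        SampleRecord("P1", "pcos", "F1", 3),
        SampleRecord("C1", "control", "F2", 1),
        SampleRecord("C1", "control", "F2", 2),
        SampleRecord("C1", "control", "F2", 3),
    ]
    rng = np.random.default_rng(0)
    return AbundanceDataset(intensities=rng.lognormal(10, 0.2, size=(6, 3)),
                            rows=rows, protein_ids=["A", "B", "C"])


def separable_records(n_per_class: int):
    """One patient per row, perfectly separable by feature 0."""
    records, values, labels = [], [], []
    rng = np.random.default_rng(3)
    for i in range(n_per_class):
        records.append(SampleRecord(f"P{i}", "pcos", f"FP{i}", 1))
        values.append([1.0 + rng.random(), rng.random()])
        labels.append("pcos")
    for i in range(n_per_class):
        records.append(SampleRecord(f"C{i}", "control", f"FC{i}", 1))
        values.append([-1.0 - rng.random(), rng.random()])
        labels.append("control")
    return np.array(values), np.array(labels), records
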