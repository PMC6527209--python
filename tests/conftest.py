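import numpy as np
import pandas as pd
import pytest

from aerodx import (
    AbundanceTable,
    SampleMetadata,
    SyntheticCohortSpec,
    generate_cohort,
    pairwise_distances,
    to_relative_abundance,
)


@pytest.fixture
def tiny_table():
    """3 OTUs x 4 samples, two OTUs sharing a genus."""
    data = pd.DataFrame(
        {
            "S1": [4, 6, 0],
            "S2": [2, 2, 6],
            "S3": [0, 5, 5],
            "S4": [10, 0, 0],
        },
        index=["OTU_A", "OTU_B", "OTU_C"],
    )
    taxonomy = [
        "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
        "Bacteria;Firmicutes;Bacilli;Lactobacillales;Streptococcaceae;Streptococcus",
        "Bacteria;Proteobacteria;Gamma;Pseudomonadales;Moraxellaceae;",
    ]
    return AbundanceTable(data, taxonomy, mode="counts")


@pytest.fixture
def tiny_metadata():
    rows = [
        ("S1", "P1", "lung", "B1", "aspirator"),
        ("S2", "P1", "oropharynx", "B1", "aspirator"),
        ("S3", "P2", "lung", "B1", "non_aspirator"),
        ("S4", "P2", "oropharynx", "B1", "non_aspirator"),
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "site", "batch", "aspiration_status"],
    ).set_index("sample_id")
    return SampleMetadata(df)


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale synthetic cohort with planted exchange and aspiration."""
    spec = SyntheticCohortSpec(seed=1)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_rel(default_cohort):
    table, _, _ = default_cohort
    return to_relative_abundance(table)


@pytest.fixture(scope="session")
def default_jsd(default_cohort, default_rel):
    return pairwise_distances(default_rel, "jsd")


def make_person_effect_cohort(n_patients=12, n_otus=60, noise=50.0, depth=5000, seed=0):
    """Cohort where each patient's two sites share a patient-specific
    community: the classic person-over-site structure."""
    rng = np.random.default_rng(seed)
    patients = [f"Q{i}" for i in range(n_patients)]
    otus = [f"O{j}" for j in range(n_otus)]
    columns, rows = {}, []
    for p in patients:
        base = rng.dirichlet(np.full(n_otus, 0.3))
        for site in ("lung", "gastric"):
            comp = rng.dirichlet(noise * base + 1e-9)
            sid = f"{p}-{site}"
            columns[sid] = rng.multinomial(depth, comp)
            rows.append((sid, p, site, "B1", "untested"))
    table = AbundanceTable(pd.DataFrame(columns, index=otus), mode="counts")
    meta = SampleMetadata(
        pd.DataFrame(
            rows,
            columns=["sample_id", "patient_id", "site", "batch", "aspiration_status"],
        ).set_index("sample_id")
    )
    return table, meta


def make_iid_cohort(n_patients=12, n_otus=60, depth=5000, seed=0):
    """Cohort where every sample (both sites, all patients) is an i.i.d.
    draw from one shared composition: no person effect, no site effect."""
    rng = np.random.default_rng(seed)
    shared = rng.dirichlet(np.full(n_otus, 1.0))
    patients = [f"Q{i}" for i in range(n_patients)]
    otus = [f"O{j}" for j in range(n_otus)]
    columns, rows = {}, []
    for p in patients:
        for site in ("lung", "gastric"):
            sid = f"{p}-{site}"
            columns[sid] = rng.multinomial(depth, shared)
            rows.append((sid, p, site, "B1", "untested"))
    table = AbundanceTable(pd.DataFrame(columns, index=otus), mode="counts")
    meta = SampleMetadata(
        pd.DataFrame(
            rows,
            columns=["sample_id", "patient_id", "site", "batch", "aspiration_status"],
        ).set_index("sample_id")
    )
    return table, meta
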