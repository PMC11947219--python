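import pandas as pd
import pytest

from antoni.synthetic import (
    CoClusterSpec,
    PopulationSpec,
    TissueSpec,
    generate_roi,
    simulate_study,
)


def csr_roi(seed, density_a=100.0, density_b=100.0, extra=None):
    """One 1 mm^2 ROI with CSR populations A and B (plus optional extras)."""
    pops = [
        PopulationSpec("A", "Other", density_a, {"M": 1.0}),
        PopulationSpec("B", "Other", density_b, {"M": 1.0}),
    ] + (extra or [])
    return generate_roi(TissueSpec(populations=pops, seed=seed, roi_id=f"csr{seed}"))


def cocluster_roi(seed, strength=2.0, density=100.0):
    """ROI with a planted co-clustered (A, B) pair plus CSR background."""
    pops = [
        PopulationSpec("A", "Other", density, {"M": 1.0}),
        PopulationSpec("B", "Other", density, {"M": 1.0}),
        PopulationSpec("C", "Other", 2 * density, {"M": 1.0}),
    ]
    spec = TissueSpec(
        populations=pops,
        planted_pairs=(CoClusterSpec("A", "B", strength=strength),),
        seed=seed,
        roi_id=f"cc{seed}",
    )
    return generate_roi(spec)


@pytest.fixture(scope="session")
def small_study():
    """A 4-case, 2-ROI-per-case synthetic study (shared, read-only)."""
    cells, clinical = simulate_study(n_cases=4, rois_per_case=2, seed=7)
    return cells, clinical


@pytest.fixture()
def toy_cells():
    """Five hand-placed cells of two types for exhaustive checks."""
    return pd.DataFrame(
        {
            "cell_id": [1, 2, 3, 4, 5],
            "roi_id": "toy",
            "case_id": "c1",
            "region": "AntoniA",
            "population": ["A", "A", "B", "B", "B"],
            "x_um": [10.0, 50.0, 15.0, 80.0, 52.0],
            "y_um": [10.0, 50.0, 12.0, 80.0, 58.0],
        }
    )
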