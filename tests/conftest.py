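import numpy as np
import pandas as pd
import pytest

import speceff as se


@pytest.fixture(scope="session")
def small_cohort():
    """A 16-sample cohort at study scale, without rendered chromatograms."""
    chroms, table, truth = se.simulate_cohort(seed=42, with_chromatograms=False)
    return table, truth


@pytest.fixture(scope="session")
def cohort_with_chroms():
    """A reduced cohort with rendered chromatograms for fingerprint tests."""
    chroms, table, truth = se.simulate_cohort(
        n_per_class={"YJH": 3, "JH": 3},
        common_count=8,
        class_extra_peaks={"YJH": 3, "JH": 1},
        seed=7,
        chromatogram_noise_sd=0.2,
    )
    return chroms, table, truth


@pytest.fixture()
def toy_feature_table():
    """A hand-built two-group feature table with known zero patterns/scores."""
    samples = [f"a{i}" for i in range(1, 5)] + [f"b{i}" for i in range(1, 5)]
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=samples)
    # F1: 75% zeros in both groups -> removed by the missingness rule
    # F2: 75% zeros in A, none in B -> kept (all_groups), removed (any_group)
    # F3: exactly 50% zeros in both groups -> retained (strict exceedance)
    # F4: complete, but id score 35 -> removed by the score filter
    data = {
        "F1": [0, 0, 0, 5, 0, 0, 0, 8],
        "F2": [0, 0, 0, 4, 1, 2, 3, 5],
        "F3": [0, 0, 4, 4, 0, 0, 9, 9],
        "F4": [1, 2, 3, 4, 6, 7, 8, 9],
    }
    intensities = pd.DataFrame(data, index=samples, dtype=float)
    scores = pd.Series({"F1": 50.0, "F2": 40.0, "F3": 36.0, "F4": 35.0})
    return se.FeatureTable(intensities=intensities, groups=groups, id_score=scores)
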