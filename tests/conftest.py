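import numpy as np
import pandas as pd
import pytest

from mirnet.design import StudyDesign, SEVEN_COMPARISONS
from mirnet.normalize import CountMatrix
from mirnet.selection import ProfileTable


@pytest.fixture(scope="session")
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture
def small_counts(design) -> CountMatrix:
    rng = np.random.default_rng(42)
    features = [f"f{i}" for i in range(30)]
    counts = pd.DataFrame(
        rng.poisson(100, size=(30, len(design.sample_ids))),
        index=features, columns=design.sample_ids,
    )
    return CountMatrix(counts, design)


def make_profiles(rows: dict[str, dict[str, float]],
                  log2fc_min: float = 1.0) -> ProfileTable:
    """Build a ProfileTable from per-feature {comparison: log2fc} dicts.

    Directions are derived from the fold changes alone (|lfc| >= min is
    a significant call), which is what hand-constructed cases need.
    """
    lfc = pd.DataFrame(
        {lab: {fid: row.get(lab, 0.0) for fid, row in rows.items()}
         for lab in SEVEN_COMPARISONS}
    )
    direction = lfc.apply(
        lambda col: np.where(
            col >= log2fc_min, "up",
            np.where(col <= -log2fc_min, "down", "ns"),
        )
    )
    direction = pd.DataFrame(direction, index=lfc.index, columns=lfc.columns)
    return ProfileTable(direction, lfc)
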