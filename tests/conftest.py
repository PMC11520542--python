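import numpy as np
import pandas as pd
import pytest

from butyroscope import CommunityProfile, PipelineConfig


@pytest.fixture
def tiny_profile() -> CommunityProfile:
    """3 samples x 4 taxa, all Bacteria, hand-checkable numbers."""
    counts = pd.DataFrame(
        [[10, 5, 0, 5], [8, 8, 4, 0], [0, 12, 6, 2]],
        index=["s1", "s2", "s3"],
        columns=["t1", "t2", "t3", "t4"],
    )
    taxonomy = pd.DataFrame(
        {
            "Kingdom": ["Bacteria"] * 4,
            "Phylum": ["Firmicutes", "Firmicutes", "Bacteroidota", "Bacteroidota"],
            "Class": ["C1", "C1", "C2", "C2"],
            "Order": ["O1", "O1", "O2", "O2"],
            "Family": ["F1", "F1", "F2", "F2"],
            "Genus": ["G1", "G1", "G2", None],
            "Species": ["sp1", "sp2", "sp3", None],
        },
        index=["t1", "t2", "t3", "t4"],
    )
    meta = pd.DataFrame(
        {
            "group": ["A", "A", "B"],
            "timepoint": ["D30"] * 3,
            "diet": ["chow"] * 3,
        },
        index=["s1", "s2", "s3"],
    )
    return CommunityProfile(counts=counts, taxonomy=taxonomy, sample_meta=meta)


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231004)
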