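"""Small shared helpers for the test suite (independent of the package
implementation wherever they serve as oracles)."""

import numpy as np
import pandas as pd

from butyroscope import CommunityProfile


def bray_pair(x, y) -> float:
    """Direct Bray-Curtis formula for one pair of vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.abs(x - y).sum() / (x + y).sum()


def two_group_profile(counts_a, counts_b, taxa=None):
    counts_a, counts_b = np.atleast_2d(counts_a), np.atleast_2d(counts_b)
    rows = np.vstack([counts_a, counts_b])
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    samples = [f"a{i}" for i in range(len(counts_a))] + [
        f"b{i}" for i in range(len(counts_b))
    ]
    counts = pd.DataFrame(rows, index=samples, columns=taxa)
    tax = pd.DataFrame(
        {"Kingdom": "Bacteria", "Species": [f"sp_{t}" for t in taxa]}, index=taxa
    )
    groups = ["A"] * len(counts_a) + ["B"] * len(counts_b)
    meta = pd.DataFrame({"group": groups}, index=samples)
    return CommunityProfile(counts=counts, taxonomy=tax, sample_meta=meta), groups
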