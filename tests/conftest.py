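import numpy as np
import pandas as pd
import pytest

from cagdyn.expression import SampleMeta
from cagdyn.instability import PeakTrace


@pytest.fixture
def worked_trace() -> PeakTrace:
    """Modal 600@111 with expansions 300@112 and 100@113 (index 0.5)."""
    return PeakTrace("worked", {111: 600.0, 112: 300.0, 113: 100.0})


@pytest.fixture
def toy_meta() -> SampleMeta:
    rows = []
    for group, htt, hdac in [
        ("WT_WT", "WT", "WT"),
        ("WT_KO", "WT", "KO"),
        ("Q111_WT", "Q111", "WT"),
        ("Q111_KO", "Q111", "KO"),
    ]:
        for j in range(3):
            rows.append(
                {
                    "sample_id": f"{group}_s{j + 1:02d}",
                    "htt_genotype": htt,
                    "hdac_genotype": hdac,
                    "sex": "M" if j % 2 == 0 else "F",
                    "batch": "b1",
                }
            )
    return SampleMeta(pd.DataFrame(rows))


def random_trace(rng: np.random.Generator) -> PeakTrace:
    """Random well-formed trace with a unique modal peak."""
    n_peaks = int(rng.integers(1, 10))
    lengths = rng.choice(np.arange(90, 140), size=n_peaks, replace=False)
    heights = rng.uniform(1.0, 1000.0, size=n_peaks)
    return PeakTrace(
        "rand", dict(zip(lengths.tolist(), heights.tolist()))
    )
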