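import numpy as np
import pandas as pd
import pytest

from chromdyn import diffacc
from chromdyn.io import CountMatrix
from chromdyn.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset42():
    """The default synthetic dataset at seed 42, shared across tests."""
    return generate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def diff42(dataset42):
    """The differential-accessibility stage run on dataset42."""
    ds = dataset42
    factors = diffacc.estimate_size_factors(ds.counts)
    norm = diffacc.normalize(ds.counts, factors)
    pairwise = diffacc.all_pairwise(ds.counts, factors)
    intrinsic = diffacc.intrinsic_scores(norm, ds.counts.sample_meta)
    selection = diffacc.select_differential_peaks(pairwise, intrinsic)
    return {
        "factors": factors,
        "norm": norm,
        "pairwise": pairwise,
        "intrinsic": intrinsic,
        "selection": selection,
    }


def make_counts(values, days, reps=2):
    """Build a CountMatrix from an array shaped (peaks, len(days)*reps)."""
    values = np.asarray(values)
    names = [f"d{d}_R{r}" for d in days for r in range(1, reps + 1)]
    meta = pd.DataFrame(
        {
            "sample": names,
            "timepoint": [d for d in days for _ in range(reps)],
            "replicate": [f"R{r}" for _ in days for r in range(1, reps + 1)],
        }
    ).set_index("sample")
    df = pd.DataFrame(
        values, index=[f"peak_{i:04d}" for i in range(values.shape[0])], columns=names
    )
    return CountMatrix(values=df.astype(np.int64), sample_meta=meta)
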