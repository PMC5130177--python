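import numpy as np
import pandas as pd
import pytest

from metresponse import SampleDesign


@pytest.fixture
def three_condition_design():
    """Builder for a triplicate three-condition sample sheet."""

    def build(reps: int = 3, conditions=("NT", "MET", "METCC")):
        sample_ids, cond, rep = [], [], []
        for c in conditions:
            for r in range(1, reps + 1):
                sample_ids.append(f"{c}_{r}")
                cond.append(c)
                rep.append(r)
        return SampleDesign(
            pd.DataFrame(
                {"condition": cond, "replicate": rep},
                index=pd.Index(sample_ids, name="sample_id"),
            )
        )

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def random_interval_frame(rng, n, genome=1000, max_len=60, chroms=("chr1",)):
    """Random small interval sets for oracle comparisons."""
    starts = rng.integers(0, genome - max_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    return pd.DataFrame(
        {
            "chrom": rng.choice(list(chroms), size=n),
            "start": starts,
            "end": starts + lengths,
        }
    )
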