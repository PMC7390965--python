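import numpy as np
import pandas as pd
import pytest

from ribote.counts import CountMatrix
from ribote.simulate import SimConfig
from ribote.transcripts import TranscriptModel


@pytest.fixture
def toy_models():
    """Two genes with the 50/300/50 geometry used in positional examples."""
    return [
        TranscriptModel("gA", "gA_T1", 50, 300, 50),
        TranscriptModel("gB", "gB_T1", 50, 300, 50),
    ]


def make_count_matrix(counts: np.ndarray, times, n_reps=1, genes=None, size_factors=None):
    """Assemble a CountMatrix from a dense array with standard library order.

    Columns are ordered rpf then rna, by time then replicate, matching
    the simulator's library naming.
    """
    libs, assay, time, rep = [], [], [], []
    for a in ("rpf", "rna"):
        for t in times:
            for r in range(1, n_reps + 1):
                libs.append(f"{a}_t{t}_r{r}")
                assay.append(a)
                time.append(t)
                rep.append(r)
    counts = np.atleast_2d(counts)
    if genes is None:
        genes = [f"g{i}" for i in range(counts.shape[0])]
    frame = pd.DataFrame(counts, index=genes, columns=libs)
    samples = pd.DataFrame({"assay": assay, "time": time, "replicate": rep}, index=libs)
    cm = CountMatrix(frame, samples)
    if size_factors is not None:
        cm.size_factors = pd.Series(size_factors, index=libs, name="size_factor")
    return cm


@pytest.fixture
def small_config():
    """Desk-scale two-time-point design used by recovery-style tests."""
    return SimConfig(
        n_genes=200,
        times=(0, 12),
        lib_depth=200_000.0,
        sigma_pair=0.05,
        lib_size_sd=0.1,
        seed=7,
    )
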