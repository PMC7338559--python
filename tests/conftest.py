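import numpy as np
import pytest
from hypothesis import settings

from assemblyscape import CommunityTable, SampleFrame, read_newick

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def three_tip_tree(tmp_path):
    """((A:1,B:1):1,C:2); — d(A,B)=2, d(A,C)=d(B,C)=4."""
    p = tmp_path / "tree.nwk"
    p.write_text("((A:1,B:1):1,C:2);\n")
    return read_newick(p)


@pytest.fixture
def toy_table():
    """3 samples x 4 OTUs with known totals."""
    counts = np.array([[5, 0, 2, 1],
                       [0, 3, 3, 0],
                       [1, 1, 1, 1]])
    return CommunityTable(["s1", "s2", "s3"], ["A", "B", "C", "D"], counts)


@pytest.fixture
def toy_frame():
    import pandas as pd
    data = pd.DataFrame(
        {"x": [0.0, 3.0, 0.0], "y": [0.0, 4.0, 1.0],
         "occasion": [1, 1, 2], "date": [100.0, 100.0, 280.0],
         "moisture": [0.2, 0.5, 0.35]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"))
    return SampleFrame(data)


def neutral_table(n_samples=30, n_otus=300, depth=1000, sad_sigma=2.0, seed=11):
    """Samples drawn iid multinomial from one lognormal regional pool."""
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(0.0, sad_sigma, n_otus)
    pool = raw / raw.sum()
    counts = rng.multinomial(depth, pool, size=n_samples)
    return CommunityTable([f"S{i:03d}" for i in range(n_samples)],
                          [f"OTU_{j:04d}" for j in range(n_otus)], counts), pool
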