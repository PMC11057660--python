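import numpy as np
import pytest
from hypothesis import settings

from clonodyn import Clonotype, RepertoireSample, SampleMeta

settings.register_profile("suite", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def make_sample():
    """Factory: build a RepertoireSample from counts (and optional keys/metadata)."""

    def _make(counts, keys=None, sample_id="s1", key_scheme="cdr3aa", **meta_kwargs):
        counts = list(counts)
        if keys is None:
            # valid CDR3-like keys, unique, length 8: C + 6 letters + F
            keys = [f"CAS{i:04d}F".replace("0", "A").replace("1", "S").replace("2", "G")
                    .replace("3", "T").replace("4", "N").replace("5", "E")
                    .replace("6", "R").replace("7", "L").replace("8", "W").replace("9", "Y")
                    for i in range(len(counts))]
        clonotypes = [
            Clonotype(cdr3_aa=k, count=int(n), v_gene="TRBV1", j_gene="TRBJ1-1")
            for k, n in zip(keys, counts)
        ]
        meta = SampleMeta(sample_id=sample_id, **meta_kwargs)
        return RepertoireSample(meta, clonotypes, key_scheme=key_scheme)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_counts(rng, max_clones=50, max_total=500):
    """Random clone-count vector for oracle comparisons."""
    s = int(rng.integers(1, max_clones + 1))
    counts = rng.integers(1, max(2, max_total // s), size=s)
    return counts.tolist()
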