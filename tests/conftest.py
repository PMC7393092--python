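import numpy as np
import pytest

from epifine.blocks import SummaryStatRecord
from epifine.features import FeatureTensor


def make_record(snp_id="rs1", chrom="1", pos=100, p=1e-5):
    return SummaryStatRecord(snp_id, chrom, pos, p)


def make_tensor(values, mask=None, labels=None, weights=None, chroms=None,
                feature_names=None, categories=None):
    """Build a FeatureTensor from a (B, N, M) array with sensible defaults."""
    values = np.asarray(values, dtype=np.uint8)
    b, n, m = values.shape
    if mask is None:
        mask = np.ones((b, n), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    values = values * mask[:, :, None]
    feature_names = feature_names or [f"F{i:03d}" for i in range(m)]
    return FeatureTensor(
        block_ids=[f"block_{i + 1:04d}" for i in range(b)],
        snp_ids=[[f"b{i}s{j}" if mask[i, j] else "" for j in range(n)] for i in range(b)],
        chroms=list(chroms) if chroms is not None else [str(i % 22 + 1) for i in range(b)],
        values=values,
        mask=mask,
        lead_mask=np.zeros((b, n), dtype=bool),
        feature_names=feature_names,
        feature_categories=list(categories) if categories else ["neural_DHS"] * m,
        labels=np.asarray(labels) if labels is not None else np.ones(b, dtype=int),
        weights=np.asarray(weights, dtype=float) if weights is not None else np.full(b, 2.0),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def random_tensor(rng):
    """Random 12-block tensor with ragged masks for contract tests."""
    b, n, m = 12, 8, 15
    mask = np.zeros((b, n), dtype=bool)
    for i in range(b):
        mask[i, : rng.integers(1, n + 1)] = True
    values = (rng.random((b, n, m)) < 0.3).astype(np.uint8)
    return make_tensor(values, mask=mask)
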