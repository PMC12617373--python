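import numpy as np
import pytest
from hypothesis import settings

from fsatool import EnrichmentMap, default_scheme

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def scheme():
    return default_scheme()


def make_emap(
    flags: np.ndarray,
    scheme=None,
    query: str | None = None,
    info: np.ndarray | None = None,
    diff_norm: np.ndarray | None = None,
    alpha: float = 0.01,
) -> EnrichmentMap:
    """Build an EnrichmentMap with prescribed enrichment flags.

    Flagged cells get p = alpha/2, unflagged p = 0.5; filter inputs default
    to uniform scores so every position is retained.
    """
    scheme = scheme or default_scheme()
    flags = np.asarray(flags, dtype=bool)
    L, K = flags.shape
    assert K == scheme.n_classes
    p = np.where(flags, alpha / 2.0, 0.5)
    return EnrichmentMap(
        query=query or "A" * L,
        scheme=scheme,
        U=np.zeros((L, K)),
        p=p,
        enriched_raw=flags,
        info=np.ones(L) if info is None else np.asarray(info, float),
        diff_norm=np.ones(L) if diff_norm is None else np.asarray(diff_norm, float),
        alpha=alpha,
        sample_mode="member",
        alternative="greater",
    )
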