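import numpy as np
import pytest

from domhier import Sociomatrix


def build_matrix(labels, entries, **kw):
    """Sociomatrix from a {(actor, recipient): count} dict."""
    idx = {lbl: k for k, lbl in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for (a, b), c in entries.items():
        counts[idx[a], idx[b]] = c
    return Sociomatrix(tuple(labels), counts, **kw)


def linear_matrix(n, wins=5):
    """Complete unidirectional transitive matrix: i beats j for i < j."""
    counts = np.full((n, n), wins, dtype=np.int64)
    counts[np.tril_indices(n)] = 0
    return Sociomatrix(tuple(chr(65 + k) for k in range(n)), counts)


@pytest.fixture
def three_dyad_matrix():
    # A->B=2, B->A=1 (two-way); A-C unknown; B->C=3 (one-way)
    return build_matrix("ABC", {("A", "B"): 2, ("B", "A"): 1, ("B", "C"): 3})


@pytest.fixture
def rng():
    return np.random.default_rng(20150826)
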