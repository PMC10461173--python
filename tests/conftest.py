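import numpy as np
import pytest

from lesionmatch import LabelVolume, MatchConfig, PhantomSpec
from lesionmatch.registration import RegistrationConfig
from lesionmatch.synthetic import generate_phantom_pair


def random_graph_pair(rng, n_max=12, flip=3):
    """Two random valid graphs over identical node sets, differing in ~flip edges."""
    from lesionmatch import build_graph

    n1 = rng.integers(1, n_max + 1)
    n2 = rng.integers(1, n_max + 1)
    idx1 = list(range(1, n1 + 1))
    idx2 = list(range(1, n2 + 1))

    def random_matches():
        m = set()
        for i in idx1:
            if rng.random() < 0.7:
                m.add((i, int(rng.choice(idx2))))
        return m

    g_a = build_graph(idx1, idx2, random_matches())
    g_b = build_graph(idx1, idx2, random_matches())
    return g_a, g_b


def brute_force_assignment(matrix):
    """Exhaustive search over all partial one-to-one assignments.

    Cells with zero value are forbidden.  Returns (best_total, best_pairs)
    where ties on total are broken toward the lexicographically smallest
    sorted pair tuple.  Independent of the production solver.
    """
    m = np.asarray(matrix, dtype=float)
    n_rows, n_cols = m.shape
    best = [-1.0, None]

    def recurse(row, used_cols, pairs, total):
        if row == n_rows:
            key = tuple(sorted(pairs))
            if total > best[0] + 1e-12 or (
                abs(total - best[0]) <= 1e-12 and key < best[1]
            ):
                best[0], best[1] = total, key
            return
        recurse(row + 1, used_cols, pairs, total)  # leave row unassigned
        for col in range(n_cols):
            if col not in used_cols and m[row, col] > 0:
                recurse(
                    row + 1, used_cols | {col}, pairs + [(row, col)],
                    total + m[row, col],
                )

    recurse(0, frozenset(), [], 0.0)
    return best[0], set(best[1])


@pytest.fixture(scope="session")
def small_volume():
    """A 12x12x12 label volume with two well-separated lesions."""
    arr = np.zeros((12, 12, 12), dtype=np.int32)
    arr[2:4, 2:4, 2:4] = 1
    arr[8:11, 8:11, 8:11] = 2
    return LabelVolume(arr, spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def field_config():
    """Matcher configuration using a supplied displacement field."""
    return MatchConfig(registration=RegistrationConfig(mode="field"))


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom pair (20 lesions, 12 mm deformation)."""
    return generate_phantom_pair(PhantomSpec(seed=7))
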