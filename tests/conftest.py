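import itertools

import numpy as np
import pytest

from hybridra import make_toy_pair
from hybridra.fixtures import write_toy_pair


@pytest.fixture(scope="session")
def toy_warburg():
    return make_toy_pair("warburg", seed=0)


@pytest.fixture(scope="session")
def toy_control():
    return make_toy_pair("control", seed=0)


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Toy pair written to disk once per session (exercises the writers)."""
    d = tmp_path_factory.mktemp("toy_files")
    pair = make_toy_pair("warburg", seed=0)
    write_toy_pair(pair, d)
    return pair


def vertex_enumeration_max(S, lb, ub, c, tol=1e-7):
    """Independent LP oracle: maximize c'v s.t. S v = 0, lb <= v <= ub by
    enumerating candidate basic solutions (every subset of variables
    pinned to a bound, remaining ones solved from the balance equations).

    Exponential; intended for LPs with at most ~10 reactions.  Returns the
    optimal objective value, or None when no feasible vertex exists.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    best = None
    for size in range(n + 1):
        for fixed in itertools.combinations(range(n), size):
            free = [i for i in range(n) if i not in fixed]
            for bounds in itertools.product(*[(lb[i], ub[i]) for i in fixed]):
                v = np.zeros(n)
                v[list(fixed)] = bounds
                if free:
                    sol, *_ = np.linalg.lstsq(S[:, free],
                                              -S[:, list(fixed)] @ np.array(bounds),
                                              rcond=None)
                    v[free] = sol
                if np.max(np.abs(S @ v)) > tol if m else False:
                    continue
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                val = float(c @ v)
                if best is None or val > best:
                    best = val
    return best
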