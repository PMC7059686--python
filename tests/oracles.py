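"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (explicit
projections, literal textbook definitions, closed-testing enumeration)
and share no code path with the package implementation.
"""

import numpy as np


# ---------------------------------------------------------------------------
# sequential sum of squares via nested least-squares projections
# ---------------------------------------------------------------------------

def _dummy_columns(labels):
    levels = list(dict.fromkeys(labels))
    return [np.asarray([1.0 if l == lev else 0.0 for l in labels]) for lev in levels[1:]]


def sequential_ss_oracle(y, continuous, categorical):
    """Type-I SS by explicit nested model comparisons.

    Parameters
    ----------
    y : 1-D response
    continuous : dict name -> 1-D covariate values (entered first, in order)
    categorical : dict name -> 1-D level labels (entered after, in order)

    Returns (ss_per_term, residual_ss, total_ss).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    cols = [np.ones(n)]

    def rss(columns):
        X = np.column_stack(columns)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    prev = rss(cols)
    total = prev
    ss = {}
    for name, x in continuous.items():
        cols.append(np.asarray(x, dtype=float))
        cur = rss(cols)
        ss[name] = prev - cur
        prev = cur
    for name, labels in categorical.items():
        cols.extend(_dummy_columns(labels))
        cur = rss(cols)
        ss[name] = prev - cur
        prev = cur
    return ss, prev, total


# ---------------------------------------------------------------------------
# literal-definition p-value adjustments
# ---------------------------------------------------------------------------

def adjust_oracle(p, method):
    """Textbook formulas for the six adjustments (step-up/step-down forms)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    out = np.empty(n)
    if method == "bonferroni":
        return np.minimum(1.0, n * p)
    if method == "holm":
        adj = np.minimum(1.0, (n - np.arange(n)) * ps)
        adj = np.maximum.accumulate(adj)                     # step-down
    elif method == "hochberg":
        adj = np.minimum(1.0, (n - np.arange(n)) * ps)
        adj = np.minimum.accumulate(adj[::-1])[::-1]          # step-up
    elif method == "BH":
        adj = np.minimum(1.0, n / (np.arange(n) + 1.0) * ps)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
    elif method == "BY":
        c = np.sum(1.0 / (np.arange(n) + 1.0))
        adj = np.minimum(1.0, c * n / (np.arange(n) + 1.0) * ps)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
    elif method == "hommel":
        return hommel_closed_testing(p)
    else:
        raise ValueError(method)
    out[order] = adj
    return out


_MASK_CACHE = {}


def _subset_masks(n):
    if n not in _MASK_CACHE:
        n_sub = (1 << n) - 1
        _MASK_CACHE[n] = np.array(
            [[(s >> i) & 1 for i in range(n)] for s in range(1, n_sub + 1)], dtype=bool
        )
    return _MASK_CACHE[n]


def hommel_closed_testing(p):
    """Hommel adjusted p-values by explicit closed testing (n <= ~12).

    adj_i = max over all subsets S containing i of the Simes p-value of S,
    Simes(S) = min_k |S| * p_(k:S) / k.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    masks = _subset_masks(n)
    sizes = masks.sum(axis=1)
    ranks = np.cumsum(masks, axis=1)
    with np.errstate(divide="ignore"):
        vals = np.where(masks, sizes[:, None] * ps[None, :] / ranks, np.inf)
    simes = vals.min(axis=1)
    adj_sorted = np.array(
        [np.minimum(1.0, simes[masks[:, i]].max()) for i in range(n)]
    )
    out = np.empty(n)
    out[order] = adj_sorted
    return out


# ---------------------------------------------------------------------------
# random small designs for oracle-equivalence checks
# ---------------------------------------------------------------------------

def random_small_design(rng):
    """A random 1-2-factor (optionally +covariate) design with full rank."""
    while True:
        n = int(rng.integers(6, 13))
        n_cat = int(rng.integers(1, 3))
        categorical = {}
        for v in range(n_cat):
            k = int(rng.integers(2, 4))
            labels = [f"L{v}{rng.integers(0, k)}" for _ in range(n)]
            categorical[f"C{v}"] = labels
        continuous = {}
        if rng.uniform() < 0.5:
            continuous["X"] = rng.normal(size=n).tolist()
        # reject degenerate / rank-deficient draws
        ok = all(len(set(lab)) >= 2 for lab in categorical.values())
        p = 1 + len(continuous) + sum(len(set(l)) - 1 for l in categorical.values())
        if not ok or p >= n:
            continue
        cols = [np.ones(n)]
        for x in continuous.values():
            cols.append(np.asarray(x))
        for lab in categorical.values():
            cols.extend(_dummy_columns(lab))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            continue
        y = rng.normal(size=n)
        return y, continuous, categorical
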