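"""Sequence-based tests of demographic stability.

Tajima's D contrasts the pairwise-difference estimate of theta with the
segregating-sites estimate; Ramos-Onsins & Rozas' R2 compares singleton
counts per sequence with half the mean pairwise difference; Harpending's
raggedness rg quantifies the jaggedness of the mismatch distribution.
Significance for all three comes from constant-size neutral coalescent
simulation conditioned on the observed number of segregating sites
(fixed-S mutation placement, the convention of the standard sequence
packages; a theta-conditioned mode is available for sensitivity analysis).
"""

from __future__ import annotations

import numpy as np

from .alignment import complete_deletion
from .datatypes import SequenceAlignment, TestResult, as_rng
from .synth import unit_tree


def _binary_site_matrix(aln: SequenceAlignment) -> np.ndarray:
    """(n, S) bool minor-state indicator over complete-deletion sites.

    Only the variable columns are returned; multi-allelic columns are
    expanded into one indicator per non-major state (infinite-sites reading
    of a finite alignment).
    """
    mat = complete_deletion(aln)
    cols = []
    for j in range(mat.shape[1]):
        states, counts = np.unique(mat[:, j], return_counts=True)
        if len(states) < 2:
            continue
        major = states[np.argmax(counts)]
        for s in states:
            if s == major:
                continue
            cols.append(mat[:, j] == s)
    if not cols:
        return np.zeros((mat.shape[0], 0), dtype=bool)
    return np.stack(cols, axis=1)


def _stats_from_matrix(X: np.ndarray) -> tuple[float, int, np.ndarray]:
    """(k, S, per-pair difference counts) from a derived-state matrix."""
    n, S = X.shape
    counts = X.sum(axis=0)
    pair_diffs = counts * (n - counts)
    k = float(pair_diffs.sum()) / (n * (n - 1) / 2)
    return k, S, counts


_TAJIMA_CACHE: dict[int, tuple[float, ...]] = {}


def tajima_constants(n: int) -> tuple[float, float, float, float]:
    """(a1, e1, e2, b1-unused placeholder) constants of Tajima (1989)."""
    if n in _TAJIMA_CACHE:
        return _TAJIMA_CACHE[n]
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    _TAJIMA_CACHE[n] = (a1, e1, e2, 0.0)
    return _TAJIMA_CACHE[n]


def tajimas_d(aln: SequenceAlignment) -> TestResult:
    """Tajima's D = (k - S/a1) / sqrt(e1 S + e2 S (S-1)).

    Undefined (flagged) when there is no segregating site.
    """
    X = _binary_site_matrix(aln)
    k, S, _ = _stats_from_matrix(X)
    n = aln.n
    if S == 0:
        return TestResult(
            name="tajimas_D",
            statistic=float("nan"),
            p_value=None,
            method="analytic",
            flags=["undefined: S=0"],
        )
    a1, e1, e2, _ = tajima_constants(n)
    d = (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    return TestResult(
        name="tajimas_D",
        statistic=float(d),
        p_value=None,
        method="analytic",
        extras={"k": k, "S": S, "n": n},
    )


def r2_statistic(aln: SequenceAlignment) -> TestResult:
    """Ramos-Onsins & Rozas R2.

    R2 = sqrt((1/n) sum_i (U_i - k/2)^2) / S with U_i the number of
    singleton mutations carried by sequence i (sites whose minor state
    occurs exactly once, attributed to the carrier of the minor state).
    """
    X = _binary_site_matrix(aln)
    k, S, counts = _stats_from_matrix(X)
    n = aln.n
    if S == 0:
        return TestResult(
            name="R2",
            statistic=float("nan"),
            p_value=None,
            method="analytic",
            flags=["undefined: S=0"],
        )
    u = _singletons_per_sequence(X, counts, n)
    r2 = float(np.sqrt(((u - k / 2.0) ** 2).mean()) / S)
    return TestResult(
        name="R2",
        statistic=r2,
        p_value=None,
        method="analytic",
        extras={"k": k, "S": S, "n": n, "U": u.tolist()},
    )


def _singletons_per_sequence(
    X: np.ndarray, counts: np.ndarray, n: int
) -> np.ndarray:
    """U_i: singleton mutations carried by each sequence.

    A site with derived count 1 is carried by its single derived sequence;
    derived count n-1 means the minor (ancestral) state is the singleton,
    carried by the one sequence lacking the derived state.
    """
    u = np.zeros(n)
    derived_single = counts == 1
    if derived_single.any():
        u += X[:, derived_single].sum(axis=1)
    anc_single = counts == n - 1
    if anc_single.any():
        u += (~X[:, anc_single]).sum(axis=1)
    return u


def mismatch_raggedness(
    aln: SequenceAlignment,
) -> tuple[np.ndarray, float]:
    """Mismatch distribution and Harpending's raggedness rg.

    Classes run from 0 to the maximum observed pairwise difference (no
    padding beyond the maximum); rg = sum_{i=1}^{dmax} (x_i - x_{i-1})^2 on
    the class frequencies.
    """
    if aln.n < 3:
        raise ValueError("need >= 3 sequences")
    X = _binary_site_matrix(aln)
    d = _pairwise_difference_counts(X)
    return _mismatch_rg(d)


def _pairwise_difference_counts(X: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    iu = np.triu_indices(n, 1)
    diffs = (X[iu[0]] != X[iu[1]]).sum(axis=1)
    return diffs


def _mismatch_rg(diffs: np.ndarray) -> tuple[np.ndarray, float]:
    dmax = int(diffs.max(initial=0))
    freqs = np.bincount(diffs, minlength=dmax + 1) / diffs.size
    rg = float(((freqs[1:] - freqs[:-1]) ** 2).sum()) if dmax >= 1 else 0.0
    return freqs, rg


# ---------------------------------------------------------------------------
# Coalescent significance
# ---------------------------------------------------------------------------


def simulate_fixed_s(
    n: int, S: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, S) derived-state matrix from a constant-size coalescent genealogy
    with exactly S mutations placed multinomially by branch length."""
    tree = unit_tree(n, rng)
    bl = tree.branch_lengths()
    branches = rng.choice(tree.n_nodes, size=S, p=bl / bl.sum())
    return tree.leaf_matrix()[branches, :n].T


def _stat_from_sim(X: np.ndarray, which: str) -> float:
    n = X.shape[0]
    k, S, counts = _stats_from_matrix(X)
    if which == "D":
        a1, e1, e2, _ = tajima_constants(n)
        return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))
    if which == "R2":
        # in simulated data the derived state is known; singleton = minor
        # state carried once, matching the estimator on real alignments
        u = _singletons_per_sequence(X, counts, n)
        return float(np.sqrt(((u - k / 2.0) ** 2).mean()) / S)
    if which == "rg":
        return _mismatch_rg(_pairwise_difference_counts(X))[1]
    raise ValueError(f"unknown statistic {which!r}")


def coalescent_null_sample(
    which: str,
    n: int,
    s_obs: int,
    reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null sample of a statistic under fixed-S neutral simulation."""
    if s_obs <= 0:
        raise ValueError("S must be >= 1 for coalescent significance")
    return np.array(
        [_stat_from_sim(simulate_fixed_s(n, s_obs, rng), which) for _ in range(reps)]
    )


def coalescent_pvalue(
    which: str,
    observed: float,
    n: int,
    s_obs: int,
    reps: int = 1000,
    seed: int | None = None,
    tail: str = "upper",
    null_cache: dict | None = None,
) -> TestResult:
    """p-value of D, R2 or rg against the fixed-S neutral coalescent.

    tail: 'upper' (decline-oriented, the convention used for D and R2 in
    declining populations), 'lower', or 'two-sided' (D only, doubled
    smaller tail).  ``null_cache`` keyed by (which, n, S, reps) lets
    calibration loops reuse null samples.
    """
    cache = null_cache if null_cache is not None else {}
    key = (which, n, s_obs, reps)
    if key not in cache:
        cache[key] = coalescent_null_sample(which, n, s_obs, reps, as_rng(seed))
    null = cache[key]
    upper = (1 + int((null >= observed - 1e-12).sum())) / (reps + 1)
    lower = (1 + int((null <= observed + 1e-12).sum())) / (reps + 1)
    if tail == "upper":
        p = upper
    elif tail == "lower":
        p = lower
    elif tail == "two-sided":
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return TestResult(
        name=f"{which}_coalescent",
        statistic=float(observed),
        p_value=float(p),
        method="coalescent",
        n_reps=reps,
        seed=seed,
        extras={"tail": tail, "n": n, "S": s_obs},
    )
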