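"""Circular statistics: the Mardia–Watson–Wheeler (uniform-scores) test.

The k-sample uniform-scores test asks whether k samples of angles come from
the same circular distribution.  Pooled angles are replaced by their circular
ranks β_i = 2π R_i / N, and the statistic

    W = 2 Σ_j (C_j² + S_j²) / n_j,   C_j = Σ cos β_i,  S_j = Σ sin β_i over group j

is asymptotically χ² with 2(k−1) degrees of freedom under the null.  Because
W depends on the pooled angles only through their circular order, any strictly
monotone re-parameterisation of the angles — in particular mapping process
angles folded to [0°, 90°] onto the full circle by ×4 — leaves W unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ParameterError
from .interaction import AngleSample

__all__ = ["MWWResult", "mww_test", "TieWarning"]

#: largest number of k=2 label assignments enumerated by the exact method
_EXACT_ENUMERATION_LIMIT = 500_000


class TieWarning(UserWarning):
    """Raised when heavy ties degrade the asymptotic null of the rank test."""


@dataclass(frozen=True)
class MWWResult:
    """Outcome of the uniform-scores test."""

    W: float
    k: int
    df: int
    p_value: float
    method: Literal["asymptotic", "permutation", "exact"]
    n_per_group: tuple[int, ...]
    n_permutations: int | None = None
    tie_fraction: float = 0.0


def _uniform_scores(pooled_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Circular-rank cosines/sines of pooled angles and the tie fraction."""
    n = pooled_deg.size
    ranks = stats.rankdata(pooled_deg, method="average")
    beta = 2.0 * np.pi * ranks / n
    tie_fraction = 1.0 - np.unique(pooled_deg).size / n
    return np.cos(beta), np.sin(beta), tie_fraction


def _w_statistic(cos_b: np.ndarray, sin_b: np.ndarray, group_slices: list[slice]) -> float:
    w = 0.0
    for sl in group_slices:
        c = cos_b[sl].sum()
        s = sin_b[sl].sum()
        w += (c * c + s * s) / (sl.stop - sl.start)
    return 2.0 * w


def mww_test(
    samples: Sequence[AngleSample] | Sequence[np.ndarray],
    method: Literal["auto", "asymptotic", "permutation", "exact"] = "auto",
    n_permutations: int = 9999,
    seed: int | np.random.Generator | None = None,
    fold_quarter_to_circle: bool = True,
) -> MWWResult:
    """k-sample Mardia–Watson–Wheeler test on angle samples.

    Parameters
    ----------
    samples
        Two or more angle samples (``AngleSample`` or plain arrays of degrees).
        With ``fold_quarter_to_circle`` (default) the angles are expected to be
        folded to [0°, 90°] and are mapped onto the full circle by ×4 before
        ranking — the composition of the usual axial doubling, applied twice
        for quarter-circle data.  Since the map is strictly monotone on
        [0, 90], the ranks and hence W are identical either way; the flag
        exists to make the circular interpretation explicit and to validate
        the input range.  Set it to False for angles already on the circle.
    method
        ``asymptotic`` uses the χ²(2(k−1)) null; ``permutation`` shuffles
        group labels ``n_permutations`` times (p reported with the +1
        correction, so it is never exactly 0); ``exact`` enumerates every
        label assignment (k = 2 only, small samples); ``auto`` picks
        permutation when any group has fewer than 10 angles, else asymptotic.
    seed
        Seeds the permutation shuffles.

    Notes
    -----
    Average ranks are used on ties.  When more than 10% of the pooled angles
    are tied a :class:`TieWarning` is emitted because the asymptotic null
    degrades; the permutation method is preferred then.
    """
    arrays = [
        np.asarray(s.angles_deg if isinstance(s, AngleSample) else s, dtype=float)
        for s in samples
    ]
    k = len(arrays)
    if k < 2:
        raise ParameterError("the test needs at least 2 groups")
    sizes = tuple(a.size for a in arrays)
    if any(n < 2 for n in sizes):
        raise ParameterError("every group needs at least 2 angles")
    if fold_quarter_to_circle:
        pooled = np.concatenate(arrays)
        if pooled.min() < 0 or pooled.max() > 90:
            raise ParameterError(
                "angles outside [0, 90] with fold_quarter_to_circle=True; pass "
                "fold_quarter_to_circle=False for angles already on the circle"
            )
        pooled = (pooled * 4.0) % 360.0
    else:
        pooled = np.concatenate(arrays) % 360.0
    if np.unique(pooled).size == 1:
        raise DegenerateDataError("all pooled angles identical; ranks are degenerate")

    cos_b, sin_b, tie_fraction = _uniform_scores(pooled)
    if tie_fraction > 0.10:
        warnings.warn(
            f"{tie_fraction:.0%} of pooled angles are tied; the asymptotic null "
            "degrades — prefer method='permutation'",
            TieWarning,
            stacklevel=2,
        )

    bounds = np.cumsum((0,) + sizes)
    group_slices = [slice(int(bounds[j]), int(bounds[j + 1])) for j in range(k)]
    w_obs = _w_statistic(cos_b, sin_b, group_slices)
    df = 2 * (k - 1)

    if method == "auto":
        method = "permutation" if any(n < 10 for n in sizes) else "asymptotic"

    if method == "asymptotic":
        p = float(stats.chi2.sf(w_obs, df))
        return MWWResult(w_obs, k, df, p, "asymptotic", sizes, None, tie_fraction)

    if method == "permutation":
        if n_permutations < 1:
            raise ParameterError("n_permutations must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        n = pooled.size
        count = 0
        # vectorised label shuffles in blocks to bound memory
        block = max(1, min(n_permutations, 4_000_000 // max(n, 1)))
        done = 0
        while done < n_permutations:
            b = min(block, n_permutations - done)
            idx = rng.random((b, n)).argsort(axis=1)
            wb = np.zeros(b)
            for sl in group_slices:
                cols = idx[:, sl]
                c = cos_b[cols].sum(axis=1)
                s = sin_b[cols].sum(axis=1)
                wb += (c * c + s * s) / (sl.stop - sl.start)
            wb *= 2.0
            count += int((wb >= w_obs - 1e-12).sum())
            done += b
        p = (1 + count) / (1 + n_permutations)
        return MWWResult(w_obs, k, df, p, "permutation", sizes, n_permutations, tie_fraction)

    if method == "exact":
        if k != 2:
            raise ParameterError("exact enumeration is implemented for k = 2 only")
        n = pooled.size
        n1 = sizes[0]
        total = comb(n, n1)
        if total > _EXACT_ENUMERATION_LIMIT:
            raise ParameterError(
                f"exact enumeration over {total} assignments exceeds the limit; "
                "use method='permutation'"
            )
        count = 0
        for chosen in combinations(range(n), n1):
            sel = np.zeros(n, dtype=bool)
            sel[list(chosen)] = True
            c1, s1 = cos_b[sel].sum(), sin_b[sel].sum()
            c2, s2 = cos_b[~sel].sum(), sin_b[~sel].sum()
            w = 2.0 * ((c1 * c1 + s1 * s1) / n1 + (c2 * c2 + s2 * s2) / (n - n1))
            if w >= w_obs - 1e-12:
                count += 1
        p = count / total
        return MWWResult(w_obs, k, df, p, "exact", sizes, total, tie_fraction)

    raise ParameterError(f"unknown method {method!r}")
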