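"""Paired permutation (sign-flip symmetry) tests between taxa.

Two taxa evaluated on the same wingspan grid give paired index series
(x_i, y_i).  Under the null hypothesis of exchangeable performance the
paired differences d_i = x_i - y_i are symmetric about zero, so every
sign pattern of the d_i is equally likely.  The test statistic is the
mean paired difference; the two-sided p-value is the proportion of
sign-flip assignments whose |mean| reaches the observed one (the
observed arrangement included).  For n <= 20 pairs all 2^n assignments
are enumerated exactly; otherwise a seeded Monte-Carlo sample with
add-one correction is used.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

EXACT_LIMIT = 20  # enumerate all 2^n sign patterns up to this n


class PermutationError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationResult:
    taxon_pair: tuple[str, str]
    index: str
    n: int
    statistic: float        # observed mean paired difference
    p_value: float
    mode: Literal["exact", "monte_carlo"]
    n_permutations: int
    seed: int | None
    degenerate: bool = False  # all paired differences were zero

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def paired_permutation_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "monte_carlo"] = "auto",
    n_perm: int = 100_000,
    seed: int = 0,
    taxon_pair: tuple[str, str] = ("x", "y"),
    index: str = "",
    grid: Sequence[float] | None = None,
    grid_y: Sequence[float] | None = None,
) -> PermutationResult:
    """Two-sided sign-flip test on the mean paired difference.

    If grids are supplied for both series they must match exactly
    (pairing is at identical wingspans only; no interpolation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PermutationError("series must be 1-D and of equal length")
    if grid is not None and grid_y is not None:
        if len(grid) != len(grid_y) or not np.allclose(grid, grid_y, rtol=0, atol=1e-12):
            raise PermutationError("wingspan grids do not match; cannot pair")
    n = x.size
    if n < 2:
        raise PermutationError("need at least 2 pairs")
    d = x - y
    T = abs(d.mean())
    if np.all(d == 0):
        return PermutationResult(
            taxon_pair=taxon_pair, index=index, n=n, statistic=0.0,
            p_value=1.0, mode="exact", n_permutations=2**n if n <= EXACT_LIMIT else 0,
            seed=None, degenerate=True,
        )
    if mode == "auto":
        mode = "exact" if n <= EXACT_LIMIT else "monte_carlo"

    if mode == "exact":
        if n > EXACT_LIMIT:
            raise PermutationError(f"exact enumeration limited to n <= {EXACT_LIMIT}")
        signs = np.array(list(itertools.product((1.0, -1.0), repeat=n)))
        T_null = np.abs(signs @ d) / n
        # >= with a relative tolerance so the observed arrangement counts
        p = float(np.mean(T_null >= T - 1e-12 * max(1.0, T)))
        return PermutationResult(
            taxon_pair=taxon_pair, index=index, n=n, statistic=float(d.mean()),
            p_value=p, mode="exact", n_permutations=2**n, seed=None,
        )

    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    T_null = np.abs(signs @ d) / n
    hits = int(np.sum(T_null >= T - 1e-12 * max(1.0, T)))
    p = (hits + 1) / (n_perm + 1)  # add-one: observed arrangement included
    return PermutationResult(
        taxon_pair=taxon_pair, index=index, n=n, statistic=float(d.mean()),
        p_value=float(p), mode="monte_carlo", n_permutations=n_perm, seed=seed,
    )


def pairwise_matrix(
    series: Mapping[str, Sequence[float]],
    index: str,
    mode: Literal["auto", "exact", "monte_carlo"] = "auto",
    n_perm: int = 100_000,
    seed: int = 0,
):
    """Symmetric DataFrame of pairwise p-values for one performance index."""
    import pandas as pd

    taxa = list(series)
    M = pd.DataFrame(np.nan, index=taxa, columns=taxa)
    for i, a in enumerate(taxa):
        M.loc[a, a] = 1.0
        for b in taxa[i + 1:]:
            res = paired_permutation_test(
                series[a], series[b], mode=mode, n_perm=n_perm, seed=seed,
                taxon_pair=(a, b), index=index,
            )
            M.loc[a, b] = M.loc[b, a] = res.p_value
    M.index.name = "taxon"
    return M
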