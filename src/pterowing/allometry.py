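"""Multivariate growth allometry from specimen tables.

The allometric coefficient (AC) of a dimension is its log-log growth
exponent relative to overall size.  With p dimensions measured on n
specimens, the multivariate estimate is read off the first principal
component of the covariance matrix of natural-log measurements: if u is
the first unit eigenvector (oriented with positive mean), the Jolicoeur
coefficients are

    AC_i = u_i * sqrt(p),

so that perfect isometry (all dimensions growing in proportion) gives
AC_i = 1 for every i.  AC > 1 is positive allometry (the part grows
faster than overall size), AC < 1 negative allometry.

Fossil tables are incomplete, so the log matrix is first completed by an
iterative rank-1 EM scheme (growth data are dominated by a single latent
size axis, which is exactly the rank-1 model).  One-tailed 95% bounds
come from a nonparametric specimen bootstrap: for a point AC below 1 the
95th percentile of replicates is reported as an upper bound (is the
dimension *significantly* below isometry?), and symmetrically above 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .specimens import DimensionConfig, SpecimenTable

Side = Literal["upper", "lower"]
Klass = Literal["+", "-", "="]

#: Rendered classes: "+" positive allometry, "-" negative, "=" isometry.
KLASSES = ("+", "-", "=")


class AllometryError(ValueError):
    """Estimation impossible (too few specimens, degenerate dimension...)."""


@dataclass(frozen=True)
class ImputationReport:
    cells_imputed: int
    iterations: int
    converged: bool
    final_change: float


@dataclass(frozen=True)
class DimensionAllometry:
    """Allometry record for a single skeletal dimension."""

    dimension: str
    ac: float
    bound: float
    bound_side: Side
    klass: Klass


@dataclass(frozen=True)
class AllometryResult:
    """Per-taxon multivariate allometry with bootstrap bounds."""

    taxon: str
    records: tuple[DimensionAllometry, ...]
    p_used: int
    n_used: int
    seed: int
    B: int

    @property
    def ac(self) -> dict[str, float]:
        return {r.dimension: r.ac for r in self.records}

    @property
    def klass(self) -> dict[str, str]:
        return {r.dimension: r.klass for r in self.records}

    def __getitem__(self, dimension: str) -> DimensionAllometry:
        for r in self.records:
            if r.dimension == dimension:
                return r
        raise KeyError(dimension)


def log_matrix(
    table: SpecimenTable, config: DimensionConfig
) -> tuple[list[str], list[str], np.ndarray]:
    """(specimen ids, analysis dimensions, natural-log matrix with NaN).

    Rows with no present cell among the analysis dimensions are dropped;
    dimensions with no data at all are dropped (they cannot enter the
    PCA).  When ``combine_wp34`` is set, the merged cell is the summed
    length of WP3 and WP4 and is present only if both are.
    """
    dims = list(config.analysis_dimensions)
    ids: list[str] = []
    rows: list[list[float]] = []
    for sp in table.specimens:
        vals: list[float] = []
        for d in dims:
            if d == "wp3_4":
                a, b = sp.get("wp3"), sp.get("wp4")
                v = a + b if (a is not None and b is not None) else None
            else:
                v = sp.get(d)
            vals.append(np.nan if v is None else np.log(v))
        if np.isfinite(vals).any():
            ids.append(sp.specimen_id)
            rows.append(vals)
    X = np.asarray(rows, dtype=float)
    if X.size == 0:
        raise AllometryError(f"no usable specimens in {table.taxon}")
    keep = ~np.all(np.isnan(X), axis=0)
    dims = [d for d, k in zip(dims, keep) if k]
    return ids, dims, X[:, keep]


def impute_log_missing(
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 500,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, ImputationReport]:
    """Complete a log-measurement matrix by iterative rank-1 EM.

    Absent cells are initialised at column means (or at ``initial`` for a
    warm start), then alternately re-estimated from the best rank-1
    approximation of the column-centred matrix until the largest update
    falls below ``tol`` or ``max_iter`` is reached.  Present cells are
    never modified.  Non-convergence is reported, not raised.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise AllometryError("imputation needs a 2-D matrix with >= 3 rows")
    miss = np.isnan(X)
    if np.any(miss.all(axis=0)):
        raise AllometryError("a column has no present cell")
    if np.any(miss.all(axis=1)):
        raise AllometryError("a row has no present cell")
    n_missing = int(miss.sum())
    if n_missing == 0:
        return X.copy(), ImputationReport(0, 0, True, 0.0)

    W = X.copy()
    if initial is not None:
        W[miss] = np.asarray(initial, dtype=float)[miss]
    else:
        col_means = np.nanmean(X, axis=0)
        W[miss] = np.broadcast_to(col_means, X.shape)[miss]

    change = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        mu = W.mean(axis=0)
        C = W - mu
        # best rank-1 reconstruction of the centred matrix
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        R = mu + s[0] * np.outer(U[:, 0], Vt[0])
        change = float(np.max(np.abs(R[miss] - W[miss])))
        W[miss] = R[miss]
        if change < tol:
            return W, ImputationReport(n_missing, it, True, change)
    return W, ImputationReport(n_missing, it, False, change)


def _ac_from_matrix(
    X: np.ndarray,
    dims: Sequence[str],
    normalization: str,
    initial: np.ndarray | None = None,
) -> tuple[np.ndarray, ImputationReport]:
    if X.shape[0] < 3:
        raise AllometryError(
            f"need >= 3 usable specimens, got {X.shape[0]}"
        )
    for j, d in enumerate(dims):
        present = X[~np.isnan(X[:, j]), j]
        if present.size >= 2 and np.ptp(present) == 0.0:
            raise AllometryError(f"zero-variance dimension {d!r}")
    W, report = impute_log_missing(X, initial=initial)
    C = np.cov(W, rowvar=False, ddof=1)
    if not np.all(np.isfinite(C)):
        raise AllometryError("covariance matrix not finite")
    evals, evecs = np.linalg.eigh(C)
    u = evecs[:, -1]
    if evals[-1] <= 0:
        raise AllometryError("degenerate covariance (no size variation)")
    if u.mean() < 0:
        u = -u
    p = len(dims)
    if normalization == "sqrt_p":
        ac = u * np.sqrt(p)
    elif normalization == "sum":
        ac = p * u / u.sum()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if np.any(ac <= 0):
        raise AllometryError(
            "first eigenvector has non-positive loadings; measurements do "
            "not share a common size axis"
        )
    return ac, report


def estimate_allometry(
    table: SpecimenTable,
    config: DimensionConfig | None = None,
    normalization: str = "sqrt_p",
) -> dict[str, float]:
    """Point allometric coefficients for every analysed dimension.

    ``normalization`` selects the gauge: ``"sqrt_p"`` (Jolicoeur,
    AC_i = u_i sqrt(p), default) or ``"sum"`` (AC_i = p u_i / sum(u)).
    Both reduce to all-ones under isometry.
    """
    config = config or DimensionConfig()
    _, dims, X = log_matrix(table, config)
    ac, _ = _ac_from_matrix(X, dims, normalization)
    return dict(zip(dims, ac))


def bootstrap_bound(
    table: SpecimenTable,
    config: DimensionConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    normalization: str = "sqrt_p",
) -> dict[str, tuple[float, Side]]:
    """One-tailed (1 - alpha) bootstrap bound per dimension.

    Specimens are resampled with replacement B times and the AC vector
    re-estimated per replicate (type-7 percentile method).  Replicates
    degenerate under resampling (e.g. an all-absent column) are
    discarded; more than 10% discards raises.
    """
    config = config or DimensionConfig()
    _, dims, X = log_matrix(table, config)
    point, _ = _ac_from_matrix(X, dims, normalization)
    # warm start replicate imputations from the full-data completion
    W_full, _ = impute_log_missing(X)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    reps: list[np.ndarray] = []
    discarded = 0
    while len(reps) < B:
        idx = rng.integers(0, n, n)
        try:
            ac, _ = _ac_from_matrix(
                X[idx], dims, normalization, initial=W_full[idx]
            )
        except AllometryError:
            discarded += 1
            if discarded > 0.1 * B:
                raise AllometryError(
                    f"more than 10% of bootstrap replicates degenerate "
                    f"({discarded} discards)"
                )
            continue
        reps.append(ac)
    R = np.vstack(reps)
    out: dict[str, tuple[float, Side]] = {}
    for j, d in enumerate(dims):
        if point[j] < 1.0:
            out[d] = (float(np.quantile(R[:, j], 1 - alpha)), "upper")
        else:  # AC exactly 1 also reports an upper-side bound
            if point[j] == 1.0:
                out[d] = (float(np.quantile(R[:, j], 1 - alpha)), "upper")
            else:
                out[d] = (float(np.quantile(R[:, j], alpha)), "lower")
    return out


def classify_allometry(ac: float, bound: float, bound_side: Side) -> Klass:
    """Classify allometry from a point AC and its one-tailed bound.

    "-" iff the upper bound is below 1 (significantly negative), "+" iff
    the lower bound is above 1 (significantly positive), "=" otherwise.
    """
    if bound_side == "upper" and bound < 1.0:
        return "-"
    if bound_side == "lower" and bound > 1.0:
        return "+"
    return "="


def analyze_taxon(
    table: SpecimenTable,
    config: DimensionConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    normalization: str = "sqrt_p",
) -> AllometryResult:
    """Full per-taxon analysis: point ACs, bounds and classes."""
    config = config or DimensionConfig()
    _, dims, X = log_matrix(table, config)
    ac, _ = _ac_from_matrix(X, dims, normalization)
    bounds = bootstrap_bound(
        table, config, B=B, seed=seed, alpha=alpha, normalization=normalization
    )
    records = []
    for j, d in enumerate(dims):
        b, side = bounds[d]
        records.append(
            DimensionAllometry(
                dimension=d,
                ac=float(ac[j]),
                bound=b,
                bound_side=side,
                klass=classify_allometry(float(ac[j]), b, side),
            )
        )
    return AllometryResult(
        taxon=table.taxon,
        records=tuple(records),
        p_used=len(dims),
        n_used=X.shape[0],
        seed=seed,
        B=B,
    )


def results_frame(results: Sequence[AllometryResult]):
    """Wide summary table: one row per taxon, AC/CI/A triplets per dimension."""
    import pandas as pd

    rows = {}
    for res in results:
        row: dict[str, object] = {"n": res.n_used, "B": res.B, "seed": res.seed}
        for r in res.records:
            row[f"{r.dimension}_AC"] = round(r.ac, 4)
            mark = "<" if r.bound_side == "upper" else ">"
            row[f"{r.dimension}_CI"] = f"{mark}{r.bound:.4f}"
            row[f"{r.dimension}_A"] = r.klass
        rows[res.taxon] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "taxon"
    return df
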