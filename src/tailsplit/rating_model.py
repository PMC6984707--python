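"""Dirichlet-multinomial model of observed ratings given gold-standard scores.

The empirical stage of the analysis.  Inter-rater data consist of integer
Alda scores (0-10) assigned by many raters to 12 standardized case
vignettes, each with a consensus "gold standard" score.  Counting how
often observed score i co-occurs with gold score k gives, per gold score,
a multinomial count vector n^(k).  Placing a symmetric Dirichlet prior with
concentration alpha on the multinomial parameters and taking the MAP
estimate yields a smoothed conditional distribution over observed scores:

    theta_i = max(0, alpha + n_i - 1) / sum_j max(0, alpha + n_j - 1)

alpha acts as a-priori observation noise: as it grows, the conditionals
flatten and mutual information with the gold standard decays to zero.

The same machinery applies after dichotomizing at a threshold tau
(responder iff score >= tau), with a 2-cell Dirichlet concentration xi.
Pairing xi = 11*alpha/2 equalizes the total prior pseudo-count mass
between the 11-category and 2-category representations, so the raw and
binary mutual-information curves can be compared on a single noise axis.
The quantity of interest is the crossover: the noise level beyond which
the dichotomized representation retains *more* mutual information about
the gold standard than the raw scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

N_SCORES = 11  # Alda scores 0..10
#: Consensus (Halifax) gold-standard scores of the 12 study vignettes.
GOLD_STANDARD = (8, 9, 6, 7, 9, 3, 5, 9, 3, 9, 5, 1)
#: Conventional responder threshold for the total Alda score.
DEFAULT_TAU = 7


class DegenerateDistributionError(ValueError):
    """All MAP numerators clamped to zero; the conditional is undefined."""


class UnsupportedImputationError(ValueError):
    """A missing gold score has no observed/previously-imputed neighbour."""


# ---------------------------------------------------------------------------
# Rating matrices and count tables
# ---------------------------------------------------------------------------

@dataclass
class RatingMatrix:
    """Integer ratings per (rater, vignette) with gold-standard scores.

    ``scores`` is float-valued so missing cells can be NaN; all non-missing
    entries are integers in [0, 10].
    """

    scores: np.ndarray               # (n_raters, n_vignettes), NaN = missing
    gold_standard: np.ndarray        # (n_vignettes,) int
    vignette_ids: Sequence[str]
    site_labels: Optional[Sequence[str]] = None
    n_dropped_cells: int = 0

    @property
    def n_raters(self) -> int:
        return self.scores.shape[0]

    @property
    def n_vignettes(self) -> int:
        return self.scores.shape[1]

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.gold_standard = np.asarray(self.gold_standard, dtype=int)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D (raters x vignettes) array")
        if self.gold_standard.shape[0] != self.scores.shape[1]:
            raise ValueError("gold_standard length must equal the number of vignettes")
        finite = self.scores[np.isfinite(self.scores)]
        if finite.size and (
            (finite < 0).any() or (finite > 10).any()
            or not np.allclose(finite, np.round(finite))
        ):
            raise ValueError("all ratings must be integers in [0, 10]")
        if ((self.gold_standard < 0) | (self.gold_standard > 10)).any():
            raise ValueError("gold-standard scores must lie in [0, 10]")
        self.n_dropped_cells = int(np.isnan(self.scores).sum())


@dataclass
class CountTableSet:
    """Per-gold-score vectors of observed-score counts.

    ``counts[k, i]`` is the number of (rater, vignette) pairs in which a
    vignette with gold score k received observed score i.  Rows for gold
    scores never observed are zero until :func:`impute_missing_counts`
    fills them (fractional values allowed after imputation).
    """

    counts: np.ndarray                           # (11, 11) float
    observed: np.ndarray                         # (11,) bool, gold score seen in data
    imputed: np.ndarray = field(default=None)    # (11,) bool

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.counts.shape != (N_SCORES, N_SCORES):
            raise ValueError("counts must be 11 x 11")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.imputed is None:
            self.imputed = np.zeros(N_SCORES, dtype=bool)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def read_ratings(path, gold: Sequence[int] = GOLD_STANDARD) -> RatingMatrix:
    """Load a rating CSV into a validated :class:`RatingMatrix`.

    Expected schema: a header row of vignette identifiers, one row per
    rater, and an optional leading ``site`` column.  Cells are integer
    scores 0-10 or blank (blank cells are dropped from downstream counts,
    never imputed).
    """
    df = pd.read_csv(path)
    site_labels = None
    first = str(df.columns[0]).strip().lower()
    if first in ("site", "rater", "rater_id"):
        site_labels = df.iloc[:, 0].astype(str).tolist()
        df = df.iloc[:, 1:]
    gold = np.asarray(gold, dtype=int)
    if df.shape[1] != gold.shape[0]:
        raise ValueError(
            f"schema error: expected {gold.shape[0]} vignette columns, "
            f"found {df.shape[1]} in {path}"
        )
    values = df.to_numpy(dtype=float)
    bad = np.isfinite(values) & (
        (values < 0) | (values > 10) | (values != np.round(values))
    )
    if bad.any():
        r, c = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"invalid score {values[r, c]!r} at rater row {r}, "
            f"column {df.columns[c]!r}: scores must be integers in [0, 10]"
        )
    return RatingMatrix(
        scores=values,
        gold_standard=gold,
        vignette_ids=[str(c) for c in df.columns],
        site_labels=site_labels,
    )


def write_ratings(matrix: RatingMatrix, path) -> None:
    """Write a rating matrix in the CSV schema accepted by :func:`read_ratings`."""
    df = pd.DataFrame(matrix.scores, columns=list(matrix.vignette_ids))
    # keep integer formatting for non-missing cells
    df = df.astype("Int64")
    if matrix.site_labels is not None:
        df.insert(0, "site", list(matrix.site_labels))
    df.to_csv(path, index=False)


def build_count_tables(ratings: RatingMatrix) -> CountTableSet:
    """Tally observed scores against gold scores: counts[k, i] = #(gold k, rated i)."""
    counts = np.zeros((N_SCORES, N_SCORES))
    for v in range(ratings.n_vignettes):
        k = int(ratings.gold_standard[v])
        col = ratings.scores[:, v]
        col = col[np.isfinite(col)].astype(int)
        np.add.at(counts[k], col, 1)
    observed = np.zeros(N_SCORES, dtype=bool)
    observed[np.unique(ratings.gold_standard)] = True
    return CountTableSet(counts=counts, observed=observed)


def impute_missing_counts(tables: CountTableSet) -> CountTableSet:
    """Fill count vectors for gold scores with no vignette.

    Boundary scores copy their inner neighbour (n^(0) <- n^(1),
    n^(10) <- n^(9)); an interior missing score takes the element-wise mean
    of its two neighbours.  Interior scores are filled in ascending order;
    a missing score whose required neighbour is neither observed nor
    already imputed raises :class:`UnsupportedImputationError` rather than
    chain-imputing silently.
    """
    counts = tables.counts.copy()
    have = tables.observed.copy()
    imputed = np.zeros(N_SCORES, dtype=bool)
    if not have.any():
        raise UnsupportedImputationError("no gold score was observed at all")
    for k in range(N_SCORES):
        if have[k]:
            continue
        if k == 0:
            if not have[1]:
                raise UnsupportedImputationError("gold 0 missing and gold 1 unavailable")
            counts[0] = counts[1]
        elif k == N_SCORES - 1:
            if not have[k - 1]:
                raise UnsupportedImputationError("gold 10 missing and gold 9 unavailable")
            counts[k] = counts[k - 1]
        else:
            if not (have[k - 1] and have[k + 1]):
                raise UnsupportedImputationError(
                    f"gold {k} missing and a neighbour is also unavailable; "
                    "only isolated interior gaps are supported"
                )
            counts[k] = 0.5 * (counts[k - 1] + counts[k + 1])
        have[k] = True
        imputed[k] = True
    return CountTableSet(counts=counts, observed=tables.observed.copy(), imputed=imputed)


# ---------------------------------------------------------------------------
# MAP smoothing and joint distributions
# ---------------------------------------------------------------------------

def map_conditional(counts: np.ndarray, alpha: float) -> np.ndarray:
    """MAP estimate of a multinomial under a symmetric Dirichlet(alpha) prior.

    theta_i proportional to max(0, alpha + n_i - 1).  The clamp at zero is
    the simplex-boundary MAP solution needed when alpha < 1 and some cell
    count is zero (the smoothing sweep starts at alpha = 0).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    num = np.maximum(0.0, alpha + counts - 1.0)
    denom = num.sum()
    if denom <= 0:
        raise DegenerateDistributionError(
            f"all MAP numerators clamped to zero (alpha={alpha}); "
            "the conditional distribution is undefined"
        )
    return num / denom


def map_binary(binary_counts: np.ndarray, xi: float) -> np.ndarray:
    """MAP estimate for the dichotomized 2-cell counts under Dirichlet(xi)."""
    binary_counts = np.asarray(binary_counts, dtype=float)
    if binary_counts.shape != (2,):
        raise ValueError("binary_counts must have exactly 2 cells")
    return map_conditional(binary_counts, xi)


def dichotomize_counts(tables: CountTableSet, tau: int) -> np.ndarray:
    """Collapse the 11x11 count tables to 2x2 at threshold tau.

    Returns ``c[k_bin, i_bin]`` with bin 1 = score >= tau on both the gold
    (rows) and observed (columns) axes.  Grand totals are preserved.
    """
    if not (0 < tau <= 10):
        raise ValueError(f"tau must be in (0, 10], got {tau}")
    n = tables.counts
    lo, hi = slice(0, tau), slice(tau, N_SCORES)
    return np.array([
        [n[lo, lo].sum(), n[lo, hi].sum()],
        [n[hi, lo].sum(), n[hi, hi].sum()],
    ])


def joint_raw(conditionals: np.ndarray) -> np.ndarray:
    """11x11 joint p(gold, observed) under a uniform 1/11 prior on gold."""
    conditionals = np.asarray(conditionals, dtype=float)
    if conditionals.shape != (N_SCORES, N_SCORES):
        raise ValueError("expected an 11 x 11 array of conditionals")
    return conditionals / N_SCORES


def joint_binary(conditionals: np.ndarray, tau: int = DEFAULT_TAU) -> np.ndarray:
    """2x2 joint p(gold class, observed class).

    The class prior follows from the uniform prior over the 11 scores:
    p(responder) = (11 - tau)/11, i.e. (7/11, 4/11) at tau = 7.
    """
    conditionals = np.asarray(conditionals, dtype=float)
    if conditionals.shape != (2, 2):
        raise ValueError("expected a 2 x 2 array of conditionals")
    prior = np.array([tau / N_SCORES, (N_SCORES - tau) / N_SCORES])
    return conditionals * prior[:, None]


def discrete_mi(joint: np.ndarray) -> float:
    """Mutual information (nats) of a discrete joint distribution.

    Terms with zero joint mass contribute zero.
    """
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"joint must sum to 1, got {total}")
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = joint * np.log(joint / (px * py))
    return float(np.nansum(terms))


# ---------------------------------------------------------------------------
# MI curves over the prior-noise axis and crossover detection
# ---------------------------------------------------------------------------

def xi_for_alpha(alpha: float) -> float:
    """Binary concentration with total prior mass equal to the raw scale's.

    11 cells of mass alpha match 2 cells of mass xi when xi = 11 alpha / 2.
    """
    return N_SCORES * alpha / 2.0


@dataclass
class MICurve:
    alpha_grid: np.ndarray
    mi_raw: np.ndarray
    mi_binary: np.ndarray
    tau: int
    crossover_alpha: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "alpha": self.alpha_grid,
            "xi": xi_for_alpha(self.alpha_grid),
            "mi_raw": self.mi_raw,
            "mi_binary": self.mi_binary,
        })


def mi_raw_at(tables: CountTableSet, alpha: float) -> float:
    conds = np.stack([map_conditional(tables.counts[k], alpha) for k in range(N_SCORES)])
    return discrete_mi(joint_raw(conds))


def mi_binary_at(tables: CountTableSet, xi: float, tau: int = DEFAULT_TAU) -> float:
    c = dichotomize_counts(tables, tau)
    conds = np.stack([map_binary(c[k], xi) for k in range(2)])
    return discrete_mi(joint_binary(conds, tau))


def mi_curves(
    tables: CountTableSet,
    alpha_grid: Sequence[float],
    tau: int = DEFAULT_TAU,
    find_crossover: bool = True,
) -> MICurve:
    """Raw and dichotomized MI along an ascending grid of prior noise alpha.

    The binary concentration is tied to the raw one by xi = 11 alpha / 2 so
    both representations carry the same total prior pseudo-count mass.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.ndim != 1 or (np.diff(alpha_grid) <= 0).any():
        raise ValueError("alpha_grid must be 1-D and strictly ascending")
    try:
        mi_r = np.array([mi_raw_at(tables, a) for a in alpha_grid])
        mi_b = np.array([mi_binary_at(tables, xi_for_alpha(a), tau) for a in alpha_grid])
    except DegenerateDistributionError as err:
        raise DegenerateDistributionError(f"{err} (while sweeping alpha_grid)") from err
    cross = crossover_alpha(tables, tau) if find_crossover else None
    return MICurve(alpha_grid, mi_r, mi_b, tau, cross)


def crossover_alpha(
    tables: CountTableSet,
    tau: int = DEFAULT_TAU,
    alpha_min: float = 0.5,
    alpha_max: float = 100.0,
    n_scan: int = 400,
    tol: float = 1e-3,
) -> Optional[float]:
    """Smallest alpha where the dichotomized MI overtakes the raw MI.

    Scans a dense grid on [alpha_min, alpha_max] for the first sign change
    of mi_binary - mi_raw from <= 0 to > 0, then refines it by bisection to
    within ``tol``.  Returns None when no such crossing exists on the
    bracket (a valid outcome: with symmetric reliability the dichotomized
    representation may never win).
    """

    def gap(a: float) -> float:
        return mi_binary_at(tables, xi_for_alpha(a), tau) - mi_raw_at(tables, a)

    grid = np.geomspace(alpha_min, alpha_max, n_scan)
    g = np.array([gap(a) for a in grid])
    idx = np.flatnonzero((g[:-1] <= 0) & (g[1:] > 0))
    if idx.size == 0:
        return None
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if gap(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
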