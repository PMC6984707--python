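"""Analytic statistical power of continuous vs dichotomized association tests.

For a continuous paired sample the association test is Pearson's
correlation; its power at two-sided level alpha follows from Fisher's
Z-transform zeta(rho) = arctanh(rho), whose sampling distribution is
approximately normal with standard deviation 1/sqrt(n - 3):

    power = Phi( sqrt(n - 3) * |zeta(rho_hat)| - Phi^{-1}(1 - alpha/2) ).

For a dichotomized sample the test is Fisher's exact test on the 2x2
contingency table.  Conditional on both margins, the count in the
(x < tau, y < tau) cell follows Fisher's noncentral hypergeometric
distribution with odds-ratio parameter eta; eta = 1 gives the null.
Power is computed analytically by locating the null's rejection region
through its survival function and evaluating the alternative's survival
function there, with eta estimated from the data by the sample odds
ratio (Haldane-Anscombe 0.5 correction on zero cells).  Because the
distribution is discrete, the inverse survival function is taken
conservatively (smallest support value t with S(t) <= q), which keeps
the size of the test at or below alpha.

The experiment sweeps both tests over the generator grid (asymmetry
beta, background noise omega, diagonal spread sigma) with a median-split
and a tail-split threshold, replicated over independent datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_reliability import GeneratorParams, SyntheticDataset, sample_dataset


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts with rows = x-class (< tau / >= tau), cols = y-class."""

    a: int  # x < tau,  y < tau
    b: int  # x < tau,  y >= tau
    c: int  # x >= tau, y < tau
    d: int  # x >= tau, y >= tau

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0 or int(cell) != cell:
                raise ValueError("cells must be non-negative integers")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self):
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self):
        return (self.a + self.c, self.b + self.d)


@dataclass
class PowerResult:
    method: str                 # "pearson" | "fisher-exact"
    power: float
    effect: float               # rho_hat or eta_hat
    alpha_level: float
    tau: Optional[float] = None


def fisher_z(rho: float) -> float:
    """Fisher's variance-stabilizing Z-transform, 0.5*log((1+rho)/(1-rho))."""
    rho = float(rho)
    if not -1.0 < rho < 1.0:
        raise ValueError(f"rho must lie strictly inside (-1, 1), got {rho}")
    return float(np.arctanh(rho))


def pearson_power(
    rho_hat: float,
    n: int,
    alpha_level: float = 0.05,
    scaled: bool = True,
) -> PowerResult:
    """Analytic power of the two-sided Pearson correlation test.

    ``scaled=True`` (default) applies the sqrt(n - 3) factor of the
    standard Fisher-Z normal approximation, making power grow with the
    sample size; ``scaled=False`` evaluates Phi(|zeta| - z_{1-alpha/2})
    without it, for auditability against formulations that omit the
    factor (under which power is independent of n).
    """
    if n < 4:
        raise ValueError("need n >= 4 for the Fisher-Z approximation")
    z = abs(fisher_z(rho_hat))
    if scaled:
        z *= np.sqrt(n - 3)
    power = float(stats.norm.cdf(z - stats.norm.ppf(1 - alpha_level / 2)))
    return PowerResult(method="pearson", power=power, effect=rho_hat,
                       alpha_level=alpha_level)


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio a*d/(b*c), Haldane-Anscombe corrected on zero cells."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def _nchg(table: ContingencyTable, eta: float):
    """Fisher noncentral hypergeometric for the (x<tau, y<tau) cell count.

    Margins fixed at the table's; scipy parameterization is
    (M=population, n=successes, N=draws) with the y<tau column as the
    success class and the x<tau row as the sample drawn.
    """
    M = table.total
    n_succ = table.a + table.c   # y < tau
    n_draw = table.a + table.b   # x < tau
    return stats.nchypergeom_fisher(M, n_succ, n_draw, eta)


def _support(table: ContingencyTable):
    n_succ = table.a + table.c
    n_draw = table.a + table.b
    lo = max(0, n_succ + n_draw - table.total)
    hi = min(n_succ, n_draw)
    return np.arange(lo, hi + 1)


def _inverse_survival(dist, support: np.ndarray, q: float) -> int:
    """Smallest support value t with S(t) <= q (conservative discrete ISF)."""
    sf = dist.sf(support)
    idx = np.flatnonzero(sf <= q)
    # sf at the top of the support is 0 <= q, so idx is never empty
    return int(support[idx[0]])


def fisher_exact_power(
    table: ContingencyTable,
    alpha_level: float = 0.05,
    eta_hat: Optional[float] = None,
) -> PowerResult:
    """Analytic power of the two-sided Fisher exact test at the table's margins.

    The null rejection region is located via the central hypergeometric's
    survival function at alpha/2 in the tail indicated by the estimated
    odds ratio; power is the alternative (noncentral, eta = eta_hat)
    distribution's mass in that region.
    """
    if min(*table.row_margins, *table.col_margins) == 0:
        raise ValueError("undefined test: a margin of the table is zero")
    if eta_hat is None:
        eta_hat = odds_ratio(table)
    null = _nchg(table, 1.0)
    alt = _nchg(table, eta_hat)
    support = _support(table)
    if eta_hat >= 1.0:
        # reject in the upper tail: X > t with null survival mass <= alpha/2
        t = _inverse_survival(null, support, alpha_level / 2)
        power = float(alt.sf(t))
    else:
        # reject in the lower tail: X < t, where S_0(t) first drops to or
        # below 1 - alpha/2, so the null mass below t is < alpha/2
        t = _inverse_survival(null, support, 1 - alpha_level / 2)
        power = float(1.0 - alt.sf(t - 1))
    return PowerResult(method="fisher-exact", power=power, effect=eta_hat,
                       alpha_level=alpha_level)


def dichotomize_dataset(dataset: SyntheticDataset, tau: float) -> ContingencyTable:
    """Bin a continuous paired sample into the 2x2 table at threshold tau."""
    if not 0 < tau < 10:
        raise ValueError(f"tau must lie strictly inside (0, 10), got {tau}")
    x_lo = dataset.x < tau
    y_lo = dataset.y < tau
    return ContingencyTable(
        a=int(np.sum(x_lo & y_lo)),
        b=int(np.sum(x_lo & ~y_lo)),
        c=int(np.sum(~x_lo & y_lo)),
        d=int(np.sum(~x_lo & ~y_lo)),
    )


@dataclass
class PowerExperimentResult:
    runs: pd.DataFrame     # beta, omega, sigma, method, tau, run, power
    summary: pd.DataFrame  # per cell: mean, ci half-width
    n_runs: int


def power_experiment(
    betas: Sequence[int] = (0, 1),
    omegas: Sequence[float] = (0.3, 0.5, 0.7),
    sigmas: Sequence[float] = tuple(range(1, 21)),
    taus: Sequence[float] = (3, 5),
    runs: int = 100,
    n: int = 750,
    seed: int = 0,
    alpha_level: float = 0.05,
    scaled: bool = True,
) -> PowerExperimentResult:
    """Power of Pearson vs Fisher-exact tests over the generator grid.

    For every (beta, omega, sigma) cell and run, one dataset of ``n``
    points is simulated; the Pearson power is computed from its sample
    correlation and the Fisher power from its 2x2 table at each
    dichotomization threshold in ``taus``.  Deterministic for a fixed
    master seed.
    """
    if runs < 2:
        raise ValueError("need at least 2 runs for a confidence interval")
    ss = np.random.SeedSequence(seed)
    rows = []
    for beta in betas:
        for omega in omegas:
            for sigma in sigmas:
                for run, child in enumerate(ss.spawn(runs)):
                    (s1,) = child.generate_state(1) % (2 ** 31)
                    data = sample_dataset(GeneratorParams(
                        beta=beta, omega=omega, sigma=sigma, n=n, seed=int(s1)))
                    rho = float(np.corrcoef(data.x, data.y)[0, 1])
                    rows.append({
                        "beta": beta, "omega": omega, "sigma": sigma,
                        "method": "pearson", "tau": np.nan, "run": run,
                        "power": pearson_power(rho, n, alpha_level, scaled).power,
                    })
                    for tau in taus:
                        tab = dichotomize_dataset(data, tau)
                        rows.append({
                            "beta": beta, "omega": omega, "sigma": sigma,
                            "method": "fisher-exact", "tau": tau, "run": run,
                            "power": fisher_exact_power(tab, alpha_level).power,
                        })
    df = pd.DataFrame(rows)
    grp = df.groupby(["beta", "omega", "sigma", "method", "tau"],
                     as_index=False, dropna=False)
    summary = grp.agg(power_mean=("power", "mean"), power_sd=("power", "std"))
    summary["power_ci"] = 1.96 * summary["power_sd"] / np.sqrt(runs)
    return PowerExperimentResult(runs=df, summary=summary, n_runs=runs)
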