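"""Synthetic generators for (ground truth, observed) agreement data.

Two kinds of synthetic data drive the theoretical experiments:

1. Continuous paired samples on [0, 10] x [0, 10].  Ground truth x is
   uniform; the observation is a mixture of a noisy diagonal and pure
   uniform background noise,

       y = omega * f(x) + (1 - omega) * Uniform(0, 10),

   where omega controls coupling to the truth.  The diagonal term adds
   uniform noise U(-sigma, sigma) around y = x.  In the *symmetric*
   condition (beta = 0) the noise width is constant in x and the pooled
   sample is rescaled back into [0, 10].  In the *asymmetric* condition
   (beta = 1) the noise is scaled by the logistic factor
   1 / (1 + exp(-0.75 x + 5)), so observations agree tightly with the
   truth at the low end of the scale and poorly at the high end, and
   out-of-range points are reflected at the interval bounds.

2. Discrete rating-matrix fixtures emulating the inter-rater study:
   integer ratings normally dispersed around each vignette's gold score,
   with a smaller standard deviation for gold scores >= 7 than below —
   the asymmetric-reliability signature seen in the real data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rating_model import GOLD_STANDARD, DEFAULT_TAU, RatingMatrix

SCALE_LO, SCALE_HI = 0.0, 10.0


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the continuous agreement generator."""

    beta: int = 0        # 0 = symmetric spread, 1 = asymmetric (logistic) spread
    omega: float = 1.0   # coupling to ground truth; 0 = pure background noise
    sigma: float = 0.0   # half-width of the uniform diagonal noise
    n: int = 750         # samples per dataset
    seed: int = 0

    def __post_init__(self):
        if self.beta not in (0, 1):
            raise ValueError(f"beta must be 0 or 1, got {self.beta}")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must lie in [0, 1], got {self.omega}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.n < 2:
            raise ValueError(f"n must be at least 2, got {self.n}")


@dataclass
class SyntheticDataset:
    x: np.ndarray
    y: np.ndarray
    params: GeneratorParams

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")


def reflect_into_interval(value, lower: float, upper: float):
    """Fold values into [lower, upper] by mirror reflection at the bounds.

    Idempotent on in-range values; accepts scalars or arrays.
    """
    if not lower < upper:
        raise ValueError("require lower < upper")
    width = upper - lower
    w = np.mod(np.asarray(value, dtype=float) - lower, 2.0 * width)
    folded = lower + (width - np.abs(w - width))
    return float(folded) if np.isscalar(value) else folded


def rescale_into_interval(values, lower: float, upper: float) -> np.ndarray:
    """Affine map sending the sample (min, max) onto (lower, upper)."""
    values = np.asarray(values, dtype=float)
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        raise ValueError("cannot rescale a constant sequence")
    return lower + (values - vmin) * (upper - lower) / (vmax - vmin)


def logistic_asymmetry(x) -> np.ndarray:
    """Noise-scaling profile 1/(1 + exp(-0.75 x + 5)).

    Near zero at the low end of the scale (reliable observations) and
    close to one at the high end (noisy observations).
    """
    return 1.0 / (1.0 + np.exp(-0.75 * np.asarray(x, dtype=float) + 5.0))


def sample_dataset(params: GeneratorParams) -> SyntheticDataset:
    """Draw one synthetic agreement dataset.

    Ground truth x ~ Uniform(0, 10).  The diagonal term is
    x + U(-sigma, sigma), with the noise multiplied by the logistic
    asymmetry profile when beta = 1.  The asymmetric branch reflects
    out-of-range values back into [0, 10]; the symmetric branch rescales
    the pooled noisy sample into [0, 10] whenever it strays outside
    (rescaling is the identity for an in-range sample, e.g. at sigma = 0).
    Finally y mixes the diagonal term with uniform background noise by
    weight omega.  Fixed seed -> bit-identical dataset.
    """
    rng = np.random.default_rng(params.seed)
    x = rng.uniform(SCALE_LO, SCALE_HI, params.n)
    noise = rng.uniform(-params.sigma, params.sigma, params.n)
    background = rng.uniform(SCALE_LO, SCALE_HI, params.n)
    if params.beta == 1:
        f = reflect_into_interval(x + noise * logistic_asymmetry(x), SCALE_LO, SCALE_HI)
    else:
        f = x + noise
        if f.min() < SCALE_LO or f.max() > SCALE_HI:
            f = rescale_into_interval(f, SCALE_LO, SCALE_HI)
    y = params.omega * f + (1.0 - params.omega) * background
    return SyntheticDataset(x=x, y=y, params=params)


def grid_dataset(points_per_axis: int) -> SyntheticDataset:
    """Full Cartesian grid of regularly spaced points over [0, 10]^2.

    Grid coordinates are independent by construction, so any mutual
    information estimator should report (approximately) zero on this
    input; it serves as the sanity check for the MI machinery.
    """
    if points_per_axis < 2:
        raise ValueError("points_per_axis must be at least 2")
    axis = np.linspace(SCALE_LO, SCALE_HI, points_per_axis)
    gx, gy = np.meshgrid(axis, axis)
    params = GeneratorParams(beta=0, omega=1.0, sigma=0.0, n=points_per_axis ** 2, seed=0)
    return SyntheticDataset(x=gx.ravel(), y=gy.ravel(), params=params)


def generate_rating_fixture(
    gold=GOLD_STANDARD,
    n_raters: int = 59,
    sd_low: float = 2.0,
    sd_high: float = 0.8,
    seed: int = 0,
    tau: int = DEFAULT_TAU,
) -> RatingMatrix:
    """Synthetic inter-rater matrix with asymmetric reliability.

    Each rating is drawn from a normal centred on the vignette's gold
    score — standard deviation ``sd_high`` for gold scores >= tau and
    ``sd_low`` below — rounded to the nearest integer and clipped to
    [0, 10].  With sd_high < sd_low this emulates the study data's tighter
    agreement on clear lithium responders.  Setting sd_high = sd_low gives
    a symmetric-reliability control matrix.
    """
    if sd_low <= 0 or sd_high <= 0:
        raise ValueError("sd_low and sd_high must be positive")
    gold = np.asarray(gold, dtype=int)
    rng = np.random.default_rng(seed)
    sds = np.where(gold >= tau, sd_high, sd_low)
    raw = rng.normal(loc=gold, scale=sds, size=(n_raters, gold.size))
    scores = np.clip(np.round(raw), 0, 10)
    return RatingMatrix(
        scores=scores,
        gold_standard=gold,
        vignette_ids=[f"v{j + 1}" for j in range(gold.size)],
    )
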