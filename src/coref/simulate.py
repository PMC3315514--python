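"""Synthetic data with a known coreferentiality structure.

The generator builds Gaussian test variables and reference data as linear
mixtures, so that the strength and mechanism of coreferentiality are under
explicit control:

* ``x1`` is Gaussian(0, sigma); ``x2 = r_x * x1 + sqrt(1 - r_x^2) * e``
  gives an exact population correlation ``r_x`` between the test pair.
* each reference column mixes the test variables and fresh Gaussian noise
  with a signed weight ``w_i`` drawn from a linear gradient running from
  ``-2 * delta`` to ``+2 * delta`` across the k columns, so the *average
  absolute* degree of determination is approximately ``delta``.  The same
  weight multiplies both test variables in a column — without this
  alignment the two correlation profiles would be uncorrelated in
  expectation and no coreferentiality could exist at any delta.

Generation modes
----------------
``both_informative``
    ``Y_i = w_i*x1 + w_i*x2 + (1 - 2|w_i|)*E_i`` — genuine coreferentiality.
``bystander``
    ``Y_i = w_i*x1 + (1 - |w_i|)*E_i`` — only x1 drives Y; any apparent
    coreferentiality of x2 is inherited through r_x.
``null``
    ``Y_i = E_i`` — Y independent of both test variables.

Contamination options append pure-noise columns and/or the test variables
themselves to Y, emulating uninformative or pathologically self-referential
reference data.

The noise coefficient is one minus the summed absolute signal weights
(mirroring the mixing convention ``x2 = d*x1 + (1-d)*e`` used by the
bivariate baseline), which restricts ``delta`` to [0, 0.25) in
``both_informative`` mode.  The base scale ``sigma`` (default 10) cancels
out of every correlation-based statistic downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import TestPair, ReferenceSet, MIN_REFERENCE_VARS, MIN_SAMPLES
from .exceptions import DimensionError, ParameterError

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "MODES",
    "gradient_weights",
    "simulate_pair",
    "simulate_dataset",
    "simulate_bivariate_baseline",
]

MODES = ("both_informative", "bystander", "null")

#: default base standard deviation of all Gaussian variables
DEFAULT_SIGMA = 10.0


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for one synthetic dataset.

    Parameters
    ----------
    n : sample size (>= 4).
    k : number of gradient-weighted reference variables (>= 3; default 130).
    delta : average absolute degree of determination of the reference data
        by each test variable, in [0, 0.25).  0 means uninformative Y.
    r_x : target population correlation of x1 and x2, in [0, 0.95].
    mode : one of ``both_informative`` / ``bystander`` / ``null``.
    n_noise_vars : number of appended i.i.d. Gaussian noise columns.
    include_x1_in_y, include_x2_in_y : append the test variable itself as
        an extra reference column (a correlation outlier in Y).
    sigma : base standard deviation of all Gaussian draws (default 10).
    seed : RNG seed; same spec (including seed) reproduces the dataset
        bit for bit.
    """

    n: int
    k: int = 130
    delta: float = 0.0
    r_x: float = 0.0
    mode: str = "both_informative"
    n_noise_vars: int = 0
    include_x1_in_y: bool = False
    include_x2_in_y: bool = False
    sigma: float = DEFAULT_SIGMA
    seed: int | None = None

    def __post_init__(self):
        if self.n < MIN_SAMPLES:
            raise DimensionError(f"n must be >= {MIN_SAMPLES}, got {self.n}")
        if self.k < MIN_REFERENCE_VARS:
            raise DimensionError(f"k must be >= {MIN_REFERENCE_VARS}, got {self.k}")
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if not 0.0 <= self.delta <= 0.25:
            raise ParameterError(
                f"delta must lie in [0, 0.25] under the mixing convention, "
                f"got {self.delta}"
            )
        if not 0.0 <= self.r_x <= 0.95:
            raise ParameterError(f"r_x must lie in [0, 0.95], got {self.r_x}")
        if self.n_noise_vars < 0:
            raise ParameterError(f"n_noise_vars must be >= 0, got {self.n_noise_vars}")
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")

    def with_seed(self, seed) -> "SimulationSpec":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SimulatedDataset:
    """One realized synthetic dataset plus its generating record."""

    pair: TestPair
    Y: ReferenceSet
    weights: np.ndarray = field(repr=False)
    spec: SimulationSpec = None


def gradient_weights(k: int, delta: float) -> np.ndarray:
    """Signed determination weights on a linear gradient -2*delta..+2*delta.

    ``w_i = -2*delta + 4*delta*(i-1)/(k-1)`` for i = 1..k, endpoints
    inclusive.  The weights sum to zero and their mean absolute value is
    within ``2*delta/(k-1)`` of ``delta``.
    """
    if k < MIN_REFERENCE_VARS:
        raise DimensionError(f"k must be >= {MIN_REFERENCE_VARS}, got {k}")
    if delta < 0:
        raise ParameterError(f"delta must be >= 0, got {delta}")
    return np.linspace(-2.0 * delta, 2.0 * delta, k)


def simulate_pair(n: int, r_x: float = 0.0, sigma: float = DEFAULT_SIGMA,
                  seed=None) -> TestPair:
    """Gaussian test pair with exact population correlation ``r_x``.

    ``x1 ~ N(0, sigma^2)``; ``x2 = r_x*x1 + sqrt(1 - r_x^2)*e`` with
    independent ``e ~ N(0, sigma^2)``, so that var(x2) = sigma^2 and
    corr(x1, x2) = r_x exactly in the population.
    """
    if n < MIN_SAMPLES:
        raise DimensionError(f"n must be >= {MIN_SAMPLES}, got {n}")
    if abs(r_x) >= 1.0:
        raise ParameterError(f"|r_x| must be < 1, got {r_x}")
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0.0, sigma, n)
    e = rng.normal(0.0, sigma, n)
    x2 = r_x * x1 + math.sqrt(1.0 - r_x * r_x) * e
    return TestPair(x1=x1, x2=x2)


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Generate a dataset according to ``spec``.

    Draw order is fixed (pair, per-column noise E, contamination noise) so
    that a spec with the same seed reproduces the dataset exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n, k, sigma = spec.n, spec.k, spec.sigma

    x1 = rng.normal(0.0, sigma, n)
    e_pair = rng.normal(0.0, sigma, n)
    x2 = spec.r_x * x1 + math.sqrt(1.0 - spec.r_x**2) * e_pair
    pair = TestPair(x1=x1, x2=x2)

    w = gradient_weights(k, spec.delta)
    E = rng.normal(0.0, sigma, (n, k))
    absw = np.abs(w)
    if spec.mode == "both_informative":
        noise_coef = 1.0 - 2.0 * absw
        if np.any(noise_coef <= 0.0):
            raise ParameterError(
                "delta too large: a noise coefficient 1 - 2|w_i| is non-positive"
            )
        Y = w * x1[:, None] + w * x2[:, None] + noise_coef * E
    elif spec.mode == "bystander":
        noise_coef = 1.0 - absw
        if np.any(noise_coef <= 0.0):
            raise ParameterError(
                "delta too large: a noise coefficient 1 - |w_i| is non-positive"
            )
        Y = w * x1[:, None] + noise_coef * E
    else:  # null: Y independent of the pair regardless of delta
        Y = E

    cols = [Y]
    labels = [f"Y{i + 1:03d}" for i in range(k)]
    if spec.n_noise_vars > 0:
        cols.append(rng.normal(0.0, sigma, (n, spec.n_noise_vars)))
        labels += [f"N{i + 1:03d}" for i in range(spec.n_noise_vars)]
    if spec.include_x1_in_y:
        cols.append(x1[:, None])
        labels.append("X1_in_Y")
    if spec.include_x2_in_y:
        cols.append(x2[:, None])
        labels.append("X2_in_Y")
    full = np.hstack(cols) if len(cols) > 1 else Y

    return SimulatedDataset(
        pair=pair,
        Y=ReferenceSet(y=full, labels=tuple(labels)),
        weights=w,
        spec=spec,
    )


def simulate_bivariate_baseline(n: int, delta: float,
                                sigma: float = DEFAULT_SIGMA,
                                seed=None) -> TestPair:
    """Directly dependent pair for the bivariate-regression baseline.

    ``x1 ~ N(0, sigma^2)``; ``x2 = delta*x1 + (1 - delta)*e`` — the literal
    delta-mixing convention, *not* rescaled to unit variance, so the
    resulting correlation is ``delta / sqrt(delta^2 + (1-delta)^2)``.
    """
    if n < MIN_SAMPLES:
        raise DimensionError(f"n must be >= {MIN_SAMPLES}, got {n}")
    if not 0.0 <= delta < 1.0:
        raise ParameterError(f"delta must lie in [0, 1), got {delta}")
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0.0, sigma, n)
    e = rng.normal(0.0, sigma, n)
    x2 = delta * x1 + (1.0 - delta) * e
    return TestPair(x1=x1, x2=x2)
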