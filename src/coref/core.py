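"""The coreferentiality coefficient and its permutation significance test.

Coreferentiality measures whether two test variables ``x1`` and ``x2``
parallel each other in their correlations with a shared multivariate
reference data set ``Y`` (N samples x k reference variables).  The
coefficient of coreferentiality ``R_C`` is the Pearson correlation of the
two k-length *correlation profiles*

    r1 = (corr(x1, Y_1), ..., corr(x1, Y_k))
    r2 = (corr(x2, Y_1), ..., corr(x2, Y_k))

Under the null hypothesis of no nonrandom association between the test
variables and ``Y``, ``R_C`` fluctuates around a value ``R_C0`` that is in
general *not* zero — for directly correlated test variables it approaches
their direct correlation ``R(x1, x2)``.  Significance is therefore assessed
by a randomization test in which ``x1`` and ``x2`` are reshuffled *jointly*
(the same sample permutation applied to both) against the fixed ``Y``,
which preserves both ``R(x1, x2)`` and the internal correlation structure
of ``Y``.  The empiric two-tailed p-value is the proportion of permutations
whose ``|R_C|`` reaches or exceeds the observed ``|R_C|``.

The module also provides a bystander-control diagnostic: it asks whether an
observed coreferentiality could be explained by ``x2`` merely echoing
``x1`` through their direct correlation, by re-testing against artificial
secondary variables built to correlate with ``x1`` and with nothing else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import DegenerateDataError, DimensionError, ParameterError

__all__ = [
    "TestPair",
    "ReferenceSet",
    "CorrelationProfile",
    "CoreferentialityResult",
    "correlation_profile",
    "coreferentiality_coefficient",
    "permutation_test",
    "bystander_control_test",
    "MIN_SAMPLES",
    "MIN_REFERENCE_VARS",
    "EXHAUSTIVE_MAX_N",
    "AUTO_EXHAUSTIVE_MAX_N",
]

MIN_SAMPLES = 4
MIN_REFERENCE_VARS = 3
#: largest N for which full enumeration of N! joint permutations is allowed
EXHAUSTIVE_MAX_N = 8
#: in ``exhaustive="auto"`` mode, enumerate when N is at most this
AUTO_EXHAUSTIVE_MAX_N = 6

# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise DimensionError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise DegenerateDataError(
            f"{name} contains a missing or non-finite value at index {bad}"
        )
    if arr.std() == 0.0:
        raise DegenerateDataError(f"{name} has zero variance")
    return arr


def _as_reference_matrix(Y, n_expected: int | None = None):
    """Coerce Y to an (N, k) float matrix plus column labels, validating."""
    if isinstance(Y, ReferenceSet):
        if n_expected is not None and Y.n != n_expected:
            raise DimensionError(
                f"reference data has {Y.n} rows but the test variables have "
                f"{n_expected} samples"
            )
        return Y.y, list(Y.labels)
    if isinstance(Y, pd.DataFrame):
        labels = [str(c) for c in Y.columns]
        mat = Y.to_numpy(dtype=float)
    else:
        mat = np.asarray(Y, dtype=float)
        if mat.ndim != 2:
            raise DimensionError(
                f"reference data must be a 2-D matrix, got shape {mat.shape}"
            )
        labels = [f"Y{i + 1:03d}" for i in range(mat.shape[1])]
    n, k = mat.shape
    if k < MIN_REFERENCE_VARS:
        raise DimensionError(
            f"need at least {MIN_REFERENCE_VARS} reference variables, got {k}: "
            "the correlation of two shorter profiles is degenerate"
        )
    if n < MIN_SAMPLES:
        raise DimensionError(f"need at least {MIN_SAMPLES} samples, got {n}")
    if n_expected is not None and n != n_expected:
        raise DimensionError(
            f"reference data has {n} rows but the test variables have "
            f"{n_expected} samples"
        )
    finite = np.isfinite(mat)
    if not finite.all():
        r, c = np.argwhere(~finite)[0]
        raise DegenerateDataError(
            f"reference column {labels[c]!r} has a missing or non-finite "
            f"value in row {int(r)}"
        )
    sds = mat.std(axis=0)
    if np.any(sds == 0.0):
        c = int(np.flatnonzero(sds == 0.0)[0])
        raise DegenerateDataError(f"reference column {labels[c]!r} has zero variance")
    return mat, labels


def _standardize(a: np.ndarray, axis: int = 0) -> np.ndarray:
    a = a - a.mean(axis=axis, keepdims=True)
    return a / a.std(axis=axis, keepdims=True)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = math.sqrt(float(a @ a) * float(b @ b))
    if den == 0.0:
        raise DegenerateDataError("correlation undefined: a vector is constant")
    return float(a @ b) / den


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of A and B (both m x k)."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", A, B)
    den = np.sqrt(np.einsum("ij,ij->i", A, A) * np.einsum("ij,ij->i", B, B))
    out = np.zeros_like(num)
    ok = den > 0.0
    out[ok] = num[ok] / den[ok]
    return out


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestPair:
    """The two hypothesis-defined test variables, sampled on the same units.

    Both vectors must be finite, non-constant and of equal length N >= 4,
    in identical sample order.
    """

    __test__ = False  # not a pytest collection target despite the name

    x1: np.ndarray
    x2: np.ndarray

    def __post_init__(self):
        x1 = _as_vector(self.x1, "x1")
        x2 = _as_vector(self.x2, "x2")
        if len(x1) != len(x2):
            raise DimensionError(
                f"x1 and x2 differ in length ({len(x1)} vs {len(x2)})"
            )
        if len(x1) < MIN_SAMPLES:
            raise DimensionError(
                f"need at least {MIN_SAMPLES} samples, got {len(x1)}"
            )
        object.__setattr__(self, "x1", x1)
        object.__setattr__(self, "x2", x2)

    @property
    def n(self) -> int:
        return len(self.x1)


@dataclass(frozen=True)
class ReferenceSet:
    """The N x k reference matrix Y with column labels.

    Rows are samples (ordered as in the :class:`TestPair`); columns are
    reference variables.  Every column must be finite with positive
    variance, and k >= 3.
    """

    y: np.ndarray
    labels: tuple = ()

    def __post_init__(self):
        mat, labels = _as_reference_matrix(
            self.y if not isinstance(self.y, ReferenceSet) else self.y.y
        )
        if self.labels:
            if len(self.labels) != mat.shape[1]:
                raise DimensionError(
                    f"{len(self.labels)} labels for {mat.shape[1]} columns"
                )
            labels = [str(c) for c in self.labels]
        object.__setattr__(self, "y", mat)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k(self) -> int:
        return self.y.shape[1]


@dataclass(frozen=True)
class CorrelationProfile:
    """The k-vector of Pearson correlations of one test variable with each
    reference column, in column order."""

    r: np.ndarray
    source: str = ""

    def __post_init__(self):
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)

    def __len__(self) -> int:
        return len(self.r)


@dataclass(frozen=True)
class CoreferentialityResult:
    """Outcome of one permutation test of coreferentiality.

    Attributes
    ----------
    r_c : observed coefficient of coreferentiality.
    p_value : two-tailed empiric p from the permutation null.
    n_perm : number of permutations used (N! in exhaustive mode).
    null_rc : the permutation null distribution of R_C.
    r_x1x2 : observed direct Pearson correlation of x1 and x2.  The null
        mean of R_C approaches this value, not zero, when Y is
        uninformative.
    seed : RNG seed used (None in exhaustive mode).
    exhaustive : whether all N! permutations were enumerated.
    counting : p-value counting rule ("plus_one" or "literal").
    """

    r_c: float
    p_value: float
    n_perm: int
    r_x1x2: float
    seed: int | None
    null_rc: np.ndarray = field(repr=False)
    exhaustive: bool = False
    counting: str = "plus_one"

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_rc))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_rc, ddof=1))

    def null_quantile(self, q) -> float:
        return float(np.quantile(self.null_rc, q))

    def summary(self) -> dict:
        """JSON-serializable summary of the test."""
        return {
            "r_c": self.r_c,
            "p_value": self.p_value,
            "n_perm": int(self.n_perm),
            "r_x1x2": self.r_x1x2,
            "seed": self.seed,
            "exhaustive": bool(self.exhaustive),
            "counting": self.counting,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_q025": self.null_quantile(0.025),
            "null_q975": self.null_quantile(0.975),
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _coerce_pair(pair, x2=None) -> TestPair:
    if isinstance(pair, TestPair):
        return pair
    return TestPair(np.asarray(pair, dtype=float), np.asarray(x2, dtype=float))


def correlation_profile(x, Y, source: str = "") -> CorrelationProfile:
    """Pearson correlations of ``x`` against every column of ``Y``.

    Parameters
    ----------
    x : 1-D numeric vector of length N.
    Y : reference data — :class:`ReferenceSet`, DataFrame, or (N, k) array.
    source : optional tag recording which test variable the profile
        belongs to.
    """
    x = _as_vector(x, "x")
    mat, _ = _as_reference_matrix(Y, n_expected=len(x))
    xz = _standardize(x)
    yz = _standardize(mat, axis=0)
    r = (xz @ yz) / len(x)
    return CorrelationProfile(r=r, source=source)


def coreferentiality_coefficient(pair, Y, x2=None) -> float:
    """The coefficient of coreferentiality R_C of a test pair against Y.

    R_C is the Pearson correlation of the two correlation profiles.  Raises
    :class:`DegenerateDataError` if either profile is constant (e.g. all
    reference columns identical).

    Accepts either ``coreferentiality_coefficient(pair, Y)`` with a
    :class:`TestPair`, or ``coreferentiality_coefficient(x1, Y, x2)``.
    """
    pair = _coerce_pair(pair, x2)
    p1 = correlation_profile(pair.x1, Y, source="x1").r
    p2 = correlation_profile(pair.x2, Y, source="x2").r
    if p1.std() == 0.0 or p2.std() == 0.0:
        raise DegenerateDataError(
            "a correlation profile is constant; R_C is undefined"
        )
    return _pearson(p1, p2)


def _prepare(pair: TestPair, Y, spearman: bool):
    """Validate and (optionally rank-transform then) standardize inputs."""
    mat, _ = _as_reference_matrix(Y, n_expected=pair.n)
    x1, x2 = pair.x1, pair.x2
    if spearman:
        # a joint permutation permutes ranks with values, so ranking once
        # up front commutes with the reshuffling scheme
        x1 = rankdata(x1)
        x2 = rankdata(x2)
        mat = np.apply_along_axis(rankdata, 0, mat)
    n = pair.n
    x1z = _standardize(x1)
    x2z = _standardize(x2)
    yz = _standardize(mat, axis=0)
    p1 = (x1z @ yz) / n
    p2 = (x2z @ yz) / n
    if p1.std() == 0.0 or p2.std() == 0.0:
        raise DegenerateDataError(
            "a correlation profile is constant; R_C is undefined"
        )
    return x1z, x2z, yz, p1, p2


def _null_rc_for_index_matrix(idx, x1z, x2z, yz):
    n = len(x1z)
    P1 = (x1z[idx] @ yz) / n
    P2 = (x2z[idx] @ yz) / n
    return _rowwise_pearson(P1, P2)


def permutation_test(
    pair,
    Y,
    x2=None,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool | str = "auto",
    spearman: bool = False,
    counting: str = "plus_one",
) -> CoreferentialityResult:
    """Two-tailed permutation test of coreferentiality.

    The null distribution is generated by reshuffling ``x1`` and ``x2``
    *jointly* — the same random sample permutation applied to both — against
    the reference data left in place.  This preserves the direct correlation
    ``R(x1, x2)`` and the internal structure of ``Y``, so the test is
    specific for the X–Y association and robust to correlated test
    variables.

    Parameters
    ----------
    pair, Y, x2 : inputs as in :func:`coreferentiality_coefficient`.
    n_perm : number of Monte-Carlo permutations (ignored in exhaustive
        mode).  Draws are uniform with replacement; the identity
        permutation may occur.
    seed : RNG seed; identical seed and inputs give bit-identical results.
    exhaustive : ``True`` enumerates all N! joint permutations (allowed for
        N <= 8); ``"auto"`` enumerates when N <= 6, otherwise Monte Carlo;
        ``False`` forces Monte Carlo.
    spearman : use rank (Spearman) correlations throughout instead of the
        default Pearson.
    counting : ``"plus_one"`` (default) computes
        ``p = (1 + #{|R_C_perm| >= |R_C_obs|}) / (n_perm + 1)``, the
        standard randomization correction that guarantees p > 0;
        ``"literal"`` computes the plain strict-exceedance proportion
        ``#{|R_C_perm| > |R_C_obs|} / n_perm``.  In exhaustive mode the p
        is always the exact proportion ``#{|R_C_perm| >= |R_C_obs|} / N!``
        (the identity permutation makes it strictly positive).
    """
    pair = _coerce_pair(pair, x2)
    if counting not in ("plus_one", "literal"):
        raise ParameterError(f"unknown counting rule {counting!r}")
    if exhaustive not in (True, False, "auto"):
        raise ParameterError(f"exhaustive must be True, False or 'auto', got {exhaustive!r}")
    n = pair.n

    use_exhaustive = (
        exhaustive is True or (exhaustive == "auto" and n <= AUTO_EXHAUSTIVE_MAX_N)
    )
    if exhaustive is True and n > EXHAUSTIVE_MAX_N:
        raise ParameterError(
            f"exhaustive enumeration limited to N <= {EXHAUSTIVE_MAX_N}, got N = {n}"
        )
    if not use_exhaustive and n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")

    x1z, x2z, yz, p1, p2 = _prepare(pair, Y, spearman)
    r_c = _pearson(p1, p2)
    r_x1x2 = _pearson(x1z, x2z)

    if use_exhaustive:
        idx = np.array(list(_iter_permutations(range(n))), dtype=np.intp)
        null_rc = _null_rc_for_index_matrix(idx, x1z, x2z, yz)
        n_eff = len(null_rc)
        p = float(np.count_nonzero(np.abs(null_rc) >= abs(r_c) - 1e-12)) / n_eff
        return CoreferentialityResult(
            r_c=r_c, p_value=p, n_perm=n_eff, r_x1x2=r_x1x2, seed=None,
            null_rc=null_rc, exhaustive=True, counting=counting,
        )

    rng = np.random.default_rng(seed)
    idx = np.tile(np.arange(n, dtype=np.intp), (n_perm, 1))
    idx = rng.permuted(idx, axis=1)
    null_rc = _null_rc_for_index_matrix(idx, x1z, x2z, yz)
    if counting == "plus_one":
        hits = int(np.count_nonzero(np.abs(null_rc) >= abs(r_c) - 1e-12))
        p = (1.0 + hits) / (n_perm + 1.0)
    else:
        p = float(np.count_nonzero(np.abs(null_rc) > abs(r_c))) / n_perm
    return CoreferentialityResult(
        r_c=r_c, p_value=p, n_perm=n_perm, r_x1x2=r_x1x2, seed=seed,
        null_rc=null_rc, exhaustive=False, counting=counting,
    )


def bystander_control_test(
    pair,
    Y,
    observed: CoreferentialityResult | float,
    n_sim: int = 1000,
    seed: int | None = None,
    x2=None,
) -> float:
    """Diagnostic for 'bystander' coreferentiality.

    Apparent coreferentiality can arise when only ``x1`` drives the
    reference data and ``x2`` merely correlates with ``x1``.  This control
    replaces ``x2`` by artificial secondary test variables built to be
    correlated *only* with ``x1``::

        x2' = r * z1 + sqrt(1 - r^2) * e

    with ``r`` the observed ``r(x1, x2)``, ``z1`` the standardized ``x1``
    and ``e`` fresh standard Gaussian noise, and asks how often such a pure
    bystander reaches the observed ``|R_C|``.  A small return value means
    the observed coreferentiality is *not* explained by ``x2`` echoing
    ``x1``.

    Returns the add-one-corrected fraction
    ``(1 + #{|R_C_sim| >= |R_C_obs|}) / (n_sim + 1)``, always in (0, 1].
    """
    pair = _coerce_pair(pair, x2)
    if n_sim < 1:
        raise ParameterError(f"n_sim must be >= 1, got {n_sim}")
    obs_rc = observed.r_c if isinstance(observed, CoreferentialityResult) else float(observed)
    x1z, x2z, yz, p1, p2 = _prepare(pair, Y, spearman=False)
    r = _pearson(x1z, x2z)
    if abs(r) >= 1.0:
        raise DegenerateDataError(
            "|r(x1, x2)| >= 1: a pure-bystander surrogate cannot be built"
        )
    n = pair.n
    rng = np.random.default_rng(seed)
    e = rng.standard_normal((n_sim, n))
    x2p = r * x1z + math.sqrt(1.0 - r * r) * e
    x2p = x2p - x2p.mean(axis=1, keepdims=True)
    x2p = x2p / x2p.std(axis=1, keepdims=True)
    P2 = (x2p @ yz) / n
    P1 = np.broadcast_to(p1, P2.shape)
    sim_rc = _rowwise_pearson(np.ascontiguousarray(P1), P2)
    hits = int(np.count_nonzero(np.abs(sim_rc) >= abs(obs_rc) - 1e-12))
    return (1.0 + hits) / (n_sim + 1.0)
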