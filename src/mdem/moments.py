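"""Incremental bookkeeping of raw powered sums and central moments.

A class of points is summarized by its cardinality ``N`` and the powered
sums ``S_l = sum_i x_i^l`` for ``l = 1..L_max``, kept per attribute.  These
are sufficient statistics for every population central moment up to order
``L_max``: with raw moments ``E[X^l] = S_l / N`` and mean ``mu = S_1 / N``,

    mu_n = sum_{k=0}^{n} C(n, k) * E[X^{n-k}] * (-mu)^k .

Absorbing one point updates every ``S_l`` in constant time, so moments are
maintained in one pass without revisiting stored points.  A closed-form
identity gives the absorbed moment directly from the pre-absorption state:
with ``delta = x - mean``, ``h = delta / (N + 1)``,

    mu_n(N+1) = 1/(N+1) * [ sum_{k=0}^{n} C(n,k) * N * mu_{n-k}(N) * (-h)^k
                            + (delta * N / (N+1))^n ] ,

using the conventions ``mu_0 = 1`` and ``mu_1 = 0``.

All moments here are population moments (divide by N, never N - 1).
Deriving central moments from powered sums cancels catastrophically on
large-magnitude data; the classification pipeline therefore scales
attributes to [0, 1] first, and on unscaled data the derivation carries
only a 1e-6 relative-error contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb

__all__ = [
    "ClassMomentState",
    "ClosedFormDisplacement",
    "empty_state",
    "absorb_point",
    "derive_moments",
    "mean_displacement_closed_form",
    "central_moment_update_closed_form",
    "closed_form_displacement",
]


@dataclass(frozen=True)
class ClassMomentState:
    """Sufficient statistics of one class: cardinality and powered sums.

    Parameters
    ----------
    count : int
        Number of points absorbed so far.
    powered_sums : ndarray, shape (L_max, n_attr)
        ``powered_sums[l - 1, k]`` holds ``sum_i x_{i,k}^l``.
    order : int
        The moment order this state is used to classify with (1 = mean).
    """

    count: int
    powered_sums: np.ndarray
    order: int = 1

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.order < 1:
            raise ValueError("order must be >= 1")
        ps = np.asarray(self.powered_sums, dtype=float)
        if ps.ndim != 2:
            raise ValueError("powered_sums must be 2-D (L_max, n_attr)")
        if ps.shape[0] < self.order:
            raise ValueError(
                f"powered_sums tracks orders 1..{ps.shape[0]} "
                f"but the state's classification order is {self.order}"
            )
        object.__setattr__(self, "powered_sums", ps)

    @property
    def n_attributes(self) -> int:
        return self.powered_sums.shape[1]

    @property
    def max_order(self) -> int:
        return self.powered_sums.shape[0]

    @property
    def mean(self) -> np.ndarray:
        """First raw moment per attribute; requires count >= 1."""
        if self.count == 0:
            raise ValueError("mean of an empty class is undefined")
        return self.powered_sums[0] / self.count

    @property
    def central_moment(self) -> np.ndarray:
        """The order-n population central moment per attribute."""
        return derive_moments(self, self.order)


@dataclass(frozen=True)
class ClosedFormDisplacement:
    """Per-attribute closed-form shift of mean and order-n central moment.

    ``delta`` is the deviation of the incoming point from the current mean,
    ``h = delta / (N + 1)`` the mean-shift increment; ``mean_shift`` equals
    ``h`` exactly and ``moment_shift`` is ``mu_n(N+1) - mu_n(N)``.
    """

    delta: np.ndarray
    h: np.ndarray
    mean_shift: np.ndarray
    moment_shift: np.ndarray
    order: int = field(default=2)


def empty_state(n_attributes: int, order: int = 1, max_order: int | None = None) -> ClassMomentState:
    """A state with no points. ``max_order`` defaults to max(order, 4)."""
    if max_order is None:
        max_order = max(order, 4)
    if max_order < order:
        raise ValueError("max_order must be >= order")
    return ClassMomentState(
        count=0,
        powered_sums=np.zeros((max_order, n_attributes)),
        order=order,
    )


def _check_point(state: ClassMomentState, x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != state.n_attributes:
        raise ValueError(
            f"attribute-count mismatch: state has {state.n_attributes} "
            f"attributes, point has {x.shape[0]}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("point has non-finite attribute values")
    return x


def absorb_point(state: ClassMomentState, x) -> ClassMomentState:
    """Absorb one point, returning a new state (the input is not mutated).

    Copy-on-write supports pseudo-inclusion: scoring a candidate class
    absorbs into a throwaway state and committing simply replaces the
    stored one, with no rollback bookkeeping.
    """
    x = _check_point(state, x)
    orders = np.arange(1, state.max_order + 1)
    new_sums = state.powered_sums + x[None, :] ** orders[:, None]
    return ClassMomentState(count=state.count + 1, powered_sums=new_sums, order=state.order)


def derive_moments(state: ClassMomentState, n: int) -> np.ndarray:
    """Population n-th central moment per attribute, from powered sums.

    Expands E[(X - mu)^n] binomially over raw moments E[X^l] = S_l / count.
    The divisor is ``count`` (population convention) throughout.
    """
    if state.count == 0:
        raise ValueError("cannot derive moments of an empty class")
    if n < 1:
        raise ValueError("moment order must be >= 1")
    if n > state.max_order:
        raise ValueError(
            f"order {n} exceeds the tracked maximum {state.max_order}; "
            "rebuild the state with a larger max_order"
        )
    raw = state.powered_sums / state.count  # raw[l-1] = E[X^l]
    mu = raw[0]
    # E[X^0] = 1 joins the table so the k = n term is C(n,n) * 1 * (-mu)^n.
    raw0 = np.vstack([np.ones(state.n_attributes), raw])
    out = np.zeros(state.n_attributes)
    for k in range(n + 1):
        out += comb(n, k, exact=True) * raw0[n - k] * (-mu) ** k
    return out


def mean_displacement_closed_form(state: ClassMomentState, x) -> np.ndarray:
    """Mean shift caused by absorbing ``x``: (x - mean) / (count + 1)."""
    if state.count == 0:
        raise ValueError("mean displacement of an empty class is undefined")
    x = _check_point(state, x)
    return (x - state.mean) / (state.count + 1)


def central_moment_update_closed_form(state: ClassMomentState, x, n: int) -> np.ndarray:
    """Order-n central moment after absorbing ``x``, without re-absorbing.

    Evaluates the closed-form identity stated in the module docstring;
    agrees with ``derive_moments(absorb_point(state, x), n)`` to 1e-9
    relative tolerance on [0, 1]-scaled data.
    """
    if state.count == 0:
        raise ValueError("closed-form update of an empty class is undefined")
    if n < 1:
        raise ValueError("moment order must be >= 1")
    x = _check_point(state, x)
    N = state.count
    delta = x - state.mean
    h = delta / (N + 1)
    # mu_0 = 1, mu_1 = 0 by convention; mu_2..mu_n from the powered sums.
    mus = [np.ones_like(delta), np.zeros_like(delta)]
    for m in range(2, n + 1):
        mus.append(derive_moments(state, m))
    acc = np.zeros_like(delta)
    for k in range(n + 1):
        acc += comb(n, k, exact=True) * N * mus[n - k] * (-h) ** k
    tail = (delta * N / (N + 1)) ** n
    return (acc + tail) / (N + 1)


def closed_form_displacement(state: ClassMomentState, x, n: int) -> ClosedFormDisplacement:
    """Bundle delta, h, mean shift and order-n moment shift for one point."""
    x = _check_point(state, x)
    delta = x - state.mean
    h = delta / (state.count + 1)
    moment_shift = central_moment_update_closed_form(state, x, n) - derive_moments(state, n)
    return ClosedFormDisplacement(
        delta=delta, h=h, mean_shift=h.copy(), moment_shift=moment_shift, order=n
    )
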