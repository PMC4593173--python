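"""Jansen-Rit single- and double-column neural mass models.

Two reciprocally coupled cortical columns stand for the occipital lobe
(column 1, output ``u1``) and the frontal cortex (column 2, ``u2``).  Each
column contains three interacting populations -- pyramidal cells and
excitatory/inhibitory interneurons -- whose average postsynaptic potentials
obey second-order linear kinetics, coupled through a saturating
potential-to-rate sigmoid.  The four intra-column synapse counts are derived
from one global connectivity constant ``C`` per column as
``(C, 0.8 C, 0.25 C, 0.25 C)``.  Pyramidal firing of each column reaches the
other column through a slower delay kernel (rate constant ``a_d``) scaled by
the directed gains ``K1`` (column 1 -> 2) and ``K2`` (column 2 -> 1).

Integration is fixed-step classical Runge-Kutta (RK4) at ``dt = 1 ms`` by
default, matching a 1000 Hz recording rate; the drive is held constant over
each step.  All stochasticity lives in the externally supplied
:class:`InputSeries`, so a simulation is a pure function of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import welch
from scipy.special import expit

from ._kernels import rk4_double_column, rk4_single_column

__all__ = [
    "ColumnConstants",
    "DoubleColumnParams",
    "InputSeries",
    "SignalSegment",
    "DivergenceError",
    "sigmoid",
    "simulate_double_column",
    "simulate_double_column_batch",
    "simulate_single_column",
    "power_spectrum",
]


class DivergenceError(RuntimeError):
    """Raised when a simulated trajectory leaves the finite range."""


@dataclass(frozen=True)
class ColumnConstants:
    """Fixed physiological constants of one cortical column.

    Defaults are the literature values proposed with the original model:
    EPSP/IPSP gains ``A``/``B`` in mV, population rate constants ``a``/``b``
    and the inter-column delay rate ``a_d`` in 1/s, and the sigmoid
    parameters ``e0`` (half of the maximum firing rate, 1/s), ``v0``
    (threshold potential, mV) and ``r`` (steepness, 1/mV).
    """

    A: float = 3.25
    B: float = 22.0
    a: float = 100.0
    b: float = 50.0
    e0: float = 2.5
    v0: float = 6.0
    r: float = 0.56
    a_d: float = 33.0

    def __post_init__(self) -> None:
        for name in ("A", "B", "a", "b", "e0", "v0", "r", "a_d"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ColumnConstants.{name} must be strictly positive")
        if not self.a > self.b:
            raise ValueError("excitatory rate constant a must exceed inhibitory b")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.a, self.b, self.e0, self.v0, self.r, self.a_d])


#: Search box used by model inversion, in particle order (C1, C2, K1, K2).
PARAM_BOUNDS = {
    "C1": (60.0, 120.0),
    "C2": (60.0, 120.0),
    "K1": (1500.0, 3000.0),
    "K2": (100.0, 600.0),
}

PARAM_NAMES = ("C1", "C2", "K1", "K2")


@dataclass(frozen=True)
class DoubleColumnParams:
    """Free couplings of the double column: intra-column connectivity C1/C2
    and the directed inter-column gains K1 (1 -> 2) and K2 (2 -> 1)."""

    C1: float
    C2: float
    K1: float
    K2: float
    constants1: ColumnConstants = field(default_factory=ColumnConstants)
    constants2: ColumnConstants = field(default_factory=ColumnConstants)

    def as_vector(self) -> np.ndarray:
        return np.array([self.C1, self.C2, self.K1, self.K2])

    def within_bounds(self) -> bool:
        return all(
            PARAM_BOUNDS[n][0] <= getattr(self, n) <= PARAM_BOUNDS[n][1] for n in PARAM_NAMES
        )

    def replace(self, **kw) -> "DoubleColumnParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class InputSeries:
    """Pulse-density drive of one column, sampled at ``fs`` Hz."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("InputSeries.values must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError("InputSeries.fs must be positive")
        object.__setattr__(self, "values", v)

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass(frozen=True)
class SignalSegment:
    """A fixed-rate multichannel time series with unique channel labels."""

    data: np.ndarray
    fs: float
    labels: tuple

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.data, dtype=float))
        labels = tuple(str(x) for x in self.labels)
        if d.shape[0] != len(labels):
            raise ValueError(
                f"{d.shape[0]} data rows but {len(labels)} channel labels"
            )
        if len(set(labels)) != len(labels):
            raise ValueError(f"channel labels are not unique: {labels}")
        if not self.fs > 0:
            raise ValueError("SignalSegment.fs must be positive")
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "labels", labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not found; available: {self.labels}"
            ) from None
        return self.data[i]

    def select(self, labels) -> "SignalSegment":
        rows = [self.labels.index(l) if l in self.labels else self._missing(l) for l in labels]
        return SignalSegment(self.data[rows], self.fs, tuple(labels))

    def _missing(self, label):
        raise KeyError(f"channel {label!r} not found; available: {self.labels}")


def sigmoid(v, constants: ColumnConstants = ColumnConstants()):
    """Population potential-to-rate sigmoid: ``2 e0 / (1 + exp(r (v0 - v)))``.

    Strictly increasing in ``v`` with range (0, 2 e0); equals ``e0`` at the
    threshold potential ``v0``.
    """
    return 2.0 * constants.e0 * expit(constants.r * (np.asarray(v, dtype=float) - constants.v0))


def simulate_double_column_batch(
    param_vectors: np.ndarray,
    p: InputSeries,
    p_prime: InputSeries,
    dt: float = 1e-3,
    constants1: ColumnConstants = ColumnConstants(),
    constants2: ColumnConstants = ColumnConstants(),
    burn_in: float = 0.0,
):
    """Simulate many parameter vectors (rows of ``(C1, C2, K1, K2)``) against
    the same pair of drives.  Returns ``(u, ok)`` where ``u`` has shape
    ``(Q, 2, n_kept)`` and ``ok`` flags finite trajectories.  Used by the PSO
    objective, where one swarm generation is a single batched call.
    """
    E = np.atleast_2d(np.asarray(param_vectors, dtype=float))
    if E.shape[1] != 4:
        raise ValueError("param vectors must have 4 components (C1, C2, K1, K2)")
    if p.fs != p_prime.fs or p.values.size != p_prime.values.size:
        raise ValueError("p and p_prime must share sampling rate and length")
    if dt > 1.0 / p.fs + 1e-15:
        raise ValueError(f"integration step dt={dt} exceeds the input sampling interval")
    steps_per_sample = int(round(1.0 / (p.fs * dt)))
    if steps_per_sample != 1:
        # finer integration: repeat each held input value, then decimate
        pv = np.repeat(p.values, steps_per_sample)
        ppv = np.repeat(p_prime.values, steps_per_sample)
    else:
        pv = p.values
        ppv = p_prime.values
    n_burn = int(round(burn_in * p.fs)) * steps_per_sample
    u, ok = rk4_double_column(
        np.ascontiguousarray(E), pv, ppv, dt, constants1.as_array(), constants2.as_array(), n_burn
    )
    if steps_per_sample != 1:
        u = u[:, :, steps_per_sample - 1 :: steps_per_sample]
    return u, ok


def simulate_double_column(
    params: DoubleColumnParams,
    p: InputSeries,
    p_prime: InputSeries,
    dt: float = 1e-3,
    burn_in: float = 0.0,
) -> SignalSegment:
    """Simulate one coupled double column and return the two pyramidal
    potentials as channels ``u1`` (occipital) and ``u2`` (frontal).

    The first ``burn_in`` seconds are integrated but discarded, removing the
    transient from the all-zero initial state.  Raises
    :class:`DivergenceError` if the trajectory becomes non-finite.
    """
    u, ok = simulate_double_column_batch(
        params.as_vector()[None, :], p, p_prime, dt,
        params.constants1, params.constants2, burn_in,
    )
    if not ok[0]:
        raise DivergenceError(
            f"double-column integration diverged for parameters "
            f"C1={params.C1}, C2={params.C2}, K1={params.K1}, K2={params.K2}"
        )
    return SignalSegment(u[0], p.fs, ("u1", "u2"))


def simulate_single_column(
    C: float,
    p: InputSeries,
    dt: float = 1e-3,
    constants: ColumnConstants = ColumnConstants(),
    burn_in: float = 0.0,
) -> SignalSegment:
    """Simulate one isolated column (no inter-column coupling); channel ``u``."""
    n_burn = int(round(burn_in * p.fs))
    u, ok = rk4_single_column(float(C), p.values, dt, constants.as_array(), n_burn)
    if not ok:
        raise DivergenceError(f"single-column integration diverged for C={C}")
    return SignalSegment(u[None, :], p.fs, ("u",))


def power_spectrum(segment: SignalSegment, channel: str, nperseg: int | None = None):
    """Welch power spectral density of one channel.

    Returns ``(freqs, psd)`` with a grid from 0 to the Nyquist frequency.
    The default window length is one second (1 Hz resolution), capped at the
    segment length; requires at least one second of data.
    """
    x = segment.channel(channel)
    if segment.duration < 1.0:
        raise ValueError("power_spectrum needs at least 1 s of data")
    if nperseg is None:
        nperseg = min(int(round(segment.fs)), x.size)
    return welch(x, fs=segment.fs, nperseg=nperseg, detrend="constant")
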