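"""Data-driven directed connectivity: MVAR fitting, AIC order selection,
partial directed coherence (PDC), band averaging and electrode-group flows.

A multichannel segment x(n) is modelled as a vector autoregression

    x(n) = sum_r A_r x(n - r) + w(n),   r = 1..p,

with A_r[i, j] the linear effect of channel j at lag r on channel i.  In the
frequency domain A(f) = I - sum_r A_r exp(-i 2 pi f r / fs), and PDC from
source channel j to target i is

    pi_ij(f) = |A_ij(f)| / ||a_j(f)||,

where a_j(f) is the j-th **column** of A(f) (the standard Baccala-Sameshima
column normalisation), so that sum_i |pi_ij(f)|^2 = 1 for every source j and
frequency.  PDC magnitudes are averaged over an analysis band (6-92 Hz in
the study) to give an N x N flow matrix, stored target-by-source, and summed
over ordered electrode pairs to obtain the four area-level flows between
visual cortex (VC) and frontal area (FA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .neural_mass import SignalSegment

__all__ = [
    "MVARModel",
    "PDCSpectrum",
    "FlowSummary",
    "OrderSelection",
    "SingularityError",
    "fit_mvar",
    "select_order_aic",
    "pdc_spectrum",
    "band_average",
    "aggregate_flows",
    "segment_flows",
]


class SingularityError(np.linalg.LinAlgError):
    """Raised when the stacked MVAR regression is rank deficient."""


@dataclass(frozen=True)
class MVARModel:
    """Fitted vector autoregression: lag matrices ``coefs`` of shape
    (p, N, N), maximum-likelihood innovation covariance ``sigma`` (N, N),
    the channel labels and the effective sample count."""

    coefs: np.ndarray
    sigma: np.ndarray
    labels: tuple
    nobs: int

    @property
    def order(self) -> int:
        return self.coefs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.coefs.shape[1]


@dataclass(frozen=True)
class OrderSelection:
    order: int
    orders: np.ndarray
    aic: np.ndarray


@dataclass(frozen=True)
class PDCSpectrum:
    """PDC magnitudes ``values[i, j, k]`` = pi_ij(freqs[k]) for flow from
    source channel j to target channel i; every value lies in [0, 1] and
    sum_i values[i, j, k]**2 == 1."""

    freqs: np.ndarray
    values: np.ndarray
    labels: tuple


@dataclass(frozen=True)
class FlowSummary:
    """Band-averaged directed strengths aggregated over electrode groups:
    sums of flow-matrix entries over ordered (source, target) pairs, with
    self-loops excluded from the within-group sums."""

    vc_to_fa: float
    fa_to_vc: float
    within_vc: float
    within_fa: float

    def as_dict(self) -> dict:
        return {
            "vc_to_fa": self.vc_to_fa,
            "fa_to_vc": self.fa_to_vc,
            "within_vc": self.within_vc,
            "within_fa": self.within_fa,
        }


def fit_mvar(segment: SignalSegment, p: int, demean: bool = True) -> MVARModel:
    """Estimate a VAR(p) by multichannel ordinary least squares on the
    stacked regression (no intercept; channels are mean-centred first by
    default, as the model has no constant term).

    The normal equations are solved jointly for all channels; a
    rank-deficient regressor matrix raises :class:`SingularityError` naming
    the channels involved.
    """
    x = segment.data.T.astype(float)  # (n, N)
    n, N = x.shape
    if p < 1:
        raise ValueError("order p must be >= 1")
    if n <= N * p + p:
        raise ValueError(
            f"{n} samples are too few to identify a VAR({p}) over {N} channels"
        )
    if demean:
        x = x - x.mean(axis=0)
    Y = x[p:]
    Z = np.concatenate([x[p - r : n - r] for r in range(1, p + 1)], axis=1)
    B, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < N * p:
        raise SingularityError(
            f"rank-deficient MVAR regressors (rank {rank} < {N * p}) "
            f"for channels {segment.labels}"
        )
    resid = Y - Z @ B
    nobs = n - p
    sigma = resid.T @ resid / nobs
    coefs = B.T.reshape(N, p, N).transpose(1, 0, 2)
    return MVARModel(coefs=coefs, sigma=sigma, labels=segment.labels, nobs=nobs)


def mvar_aic(model: MVARModel) -> float:
    """Multivariate Akaike criterion: ln det(Sigma_ml) + 2 p N^2 / n."""
    sign, logdet = np.linalg.slogdet(model.sigma)
    if sign <= 0:
        return np.inf
    N = model.n_channels
    return float(logdet + 2.0 * model.order * N * N / model.nobs)


def select_order_aic(
    segment: SignalSegment, p_min: int = 5, p_max: int = 20
) -> OrderSelection:
    """Pick the VAR order minimising AIC over [p_min, p_max] (default 5-20);
    ties resolve to the smallest order."""
    if p_min < 1 or p_max < p_min:
        raise ValueError("need 1 <= p_min <= p_max")
    orders = np.arange(p_min, p_max + 1)
    aic = np.array([mvar_aic(fit_mvar(segment, int(p))) for p in orders])
    return OrderSelection(order=int(orders[int(np.argmin(aic))]), orders=orders, aic=aic)


def pdc_spectrum(model: MVARModel, freqs=None, fs: float = 1000.0) -> PDCSpectrum:
    """Evaluate PDC magnitudes on a frequency grid (default 1 Hz steps from
    1 Hz to Nyquist).  A vanishing column norm ||a_j(f)|| raises, as the
    model is then degenerate at that frequency."""
    if freqs is None:
        freqs = np.arange(1.0, fs / 2.0 + 0.5)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0 or freqs.min() <= 0 or freqs.max() > fs / 2.0:
        raise ValueError("frequencies must lie in (0, fs/2]")
    p, N, _ = model.coefs.shape
    r = np.arange(1, p + 1)
    # phase factors: (F, p)
    z = np.exp(-2j * np.pi * freqs[:, None] * r[None, :] / fs)
    Af = np.eye(N)[None, :, :] - np.einsum("fr,rij->fij", z, model.coefs)
    mags = np.abs(Af)  # (F, N, N)
    denom = np.sqrt((mags**2).sum(axis=1))  # column norms, (F, N)
    if np.any(denom == 0):
        raise ValueError("degenerate MVAR model: zero column norm of A(f)")
    values = (mags / denom[:, None, :]).transpose(1, 2, 0)  # (N, N, F)
    return PDCSpectrum(freqs=freqs, values=values, labels=model.labels)


def band_average(spectrum: PDCSpectrum, band=(6.0, 92.0)) -> pd.DataFrame:
    """Average PDC magnitude over grid frequencies inside ``band``
    (inclusive), returning the N x N flow matrix as a DataFrame indexed by
    target label with source labels as columns."""
    lo, hi = band
    mask = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the frequency grid")
    mat = spectrum.values[:, :, mask].mean(axis=2)
    labels = list(spectrum.labels)
    return pd.DataFrame(mat, index=labels, columns=labels)


def aggregate_flows(flow_matrix: pd.DataFrame, groups: dict) -> FlowSummary:
    """Sum directed strengths over electrode groups.

    ``groups`` maps "VC" and "FA" to disjoint label lists present in the
    flow matrix.  ``flow_matrix`` is target-by-source: entry (i, j) is the
    strength of flow j -> i.
    """
    try:
        vc, fa = list(groups["VC"]), list(groups["FA"])
    except KeyError as e:
        raise ValueError("groups must define both 'VC' and 'FA'") from e
    overlap = set(vc) & set(fa)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    labels = set(flow_matrix.index) & set(flow_matrix.columns)
    missing = (set(vc) | set(fa)) - labels
    if missing:
        raise KeyError(f"labels missing from flow matrix: {sorted(missing)}")

    def pair_sum(sources, targets):
        total = 0.0
        for j in sources:
            for i in targets:
                if i != j:
                    total += float(flow_matrix.at[i, j])
        return total

    return FlowSummary(
        vc_to_fa=pair_sum(vc, fa),
        fa_to_vc=pair_sum(fa, vc),
        within_vc=pair_sum(vc, vc),
        within_fa=pair_sum(fa, fa),
    )


def segment_flows(
    segment: SignalSegment,
    groups: dict,
    band=(6.0, 92.0),
    p_range=(5, 20),
    order: int | None = None,
):
    """Full per-segment chain: AIC order selection (unless ``order`` is
    given), MVAR fit, PDC, band average, group aggregation.  Returns
    ``(FlowSummary, flow_matrix, order)``."""
    if order is None:
        order = select_order_aic(segment, *p_range).order
    model = fit_mvar(segment, order)
    spectrum = pdc_spectrum(model, fs=segment.fs)
    flows = band_average(spectrum, band)
    return aggregate_flows(flows, groups), flows, order
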