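"""Generators for every input the analyses need.

The study the package emulates recorded intracranial EEG from 10 rats under
four conditions (resting control and 8/44/84 Hz flicker), five artifact-free
3 s segments per condition at 1000 Hz.  Those recordings are not public, so
this module produces stand-ins with known ground truth:

* stimulus drives -- uniform white noise in [120, 320] pulses/s, plus a
  square pulse train at the stimulus frequency for the flicker conditions;
* two-channel double-column recordings with known (C1, C2, K1, K2), the
  substrate for inversion experiments (the exact noise realisation is
  recoverable from the stored seeds, enabling shared-noise inversion);
* multichannel VAR processes with known directed structure, the substrate
  for PDC validation;
* a full emulated study combining both, with the 8 Hz condition's K1 and
  visual-to-frontal VAR coupling elevated by a fixed effect size.

Every artifact is fully determined by (spec, seed); manifests record enough
to recompute each segment bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .neural_mass import (
    DoubleColumnParams,
    InputSeries,
    PARAM_BOUNDS,
    SignalSegment,
    simulate_double_column,
)

__all__ = [
    "CONDITIONS",
    "ELECTRODE_LABELS",
    "DEFAULT_GROUPS",
    "StimulusSpec",
    "StudyFixture",
    "InversionFixture",
    "StationarityError",
    "make_stimulus_input",
    "generate_inversion_fixture",
    "generate_var_fixture",
    "generate_study_fixture",
    "load_manifest",
]

CONDITIONS = ("control", "8", "44", "84")

#: The six electrodes entering the visual-cortex / frontal-area flow analysis.
ELECTRODE_LABELS = ("V1_L", "V1_R", "V2_L", "V2_R", "FrA_L", "FrA_R")
DEFAULT_GROUPS = {
    "VC": ["V1_L", "V1_R", "V2_L", "V2_R"],
    "FA": ["FrA_L", "FrA_R"],
}


class StationarityError(ValueError):
    """Raised for VAR coefficient sets whose companion matrix is unstable."""


def normalize_condition(condition) -> str:
    c = str(condition).lower().removesuffix("hz").strip()
    if c not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    return c


@dataclass(frozen=True)
class StimulusSpec:
    """Drive of the occipital column for one condition.

    ``pulse_amplitude`` is the height of the square pulse train added on top
    of the noise floor for the flicker conditions (the study fed a 7 V drive
    to its LED; here it is a dimensionless pulse-density increment).
    ``pulse_duty`` is the fraction of each stimulus period spent high.
    """

    condition: str = "control"
    pulse_amplitude: float = 7.0
    noise_low: float = 120.0
    noise_high: float = 320.0
    duration: float = 3.0
    fs: float = 1000.0
    pulse_duty: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", normalize_condition(self.condition))
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.noise_low < self.noise_high:
            raise ValueError("noise_low must be below noise_high")
        if not 0 < self.pulse_duty < 1:
            raise ValueError("pulse_duty must lie in (0, 1)")

    @property
    def frequency(self) -> float | None:
        return None if self.condition == "control" else float(self.condition)


def make_stimulus_input(spec: StimulusSpec, seed: int) -> InputSeries:
    """Generate one drive realisation: uniform noise in the configured range,
    plus (for flicker conditions) a periodic square pulse train at the
    stimulus frequency.  Control is pure noise."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.fs))
    values = rng.uniform(spec.noise_low, spec.noise_high, n)
    f = spec.frequency
    if f is not None:
        phase = np.arange(n) * (f / spec.fs) % 1.0
        values = values + spec.pulse_amplitude * (phase < spec.pulse_duty)
    return InputSeries(values, spec.fs)


@dataclass(frozen=True)
class InversionFixture:
    """A synthetic two-channel recording with everything needed to re-run the
    generating simulation: the exact drive realisations and true parameters."""

    segment: SignalSegment
    p: InputSeries
    p_prime: InputSeries
    true_params: DoubleColumnParams
    condition: str
    burn_in: float
    seed: int


def generate_inversion_fixture(
    true_params: DoubleColumnParams,
    spec: StimulusSpec,
    seed: int,
    burn_in: float = 1.0,
    dt: float = 1e-3,
) -> InversionFixture:
    """Simulate a double-column recording for one condition.

    The drives span ``burn_in + spec.duration`` seconds; the burn-in is
    integrated and discarded, so the returned segment has ``spec.duration``
    seconds of post-transient data.  The stored drives make shared-noise
    re-simulation exact.
    """
    if not true_params.within_bounds():
        raise ValueError("true_params must lie inside the inversion search box")
    s_p, s_pp = np.random.SeedSequence(seed).spawn(2)
    full = dataclasses.replace(spec, duration=spec.duration + burn_in)
    p = make_stimulus_input(full, s_p)
    p_prime = make_stimulus_input(
        dataclasses.replace(full, condition="control"), s_pp
    )
    segment = simulate_double_column(true_params, p, p_prime, dt=dt, burn_in=burn_in)
    return InversionFixture(segment, p, p_prime, true_params, spec.condition, burn_in, seed)


def var_spectral_radius(coefficients) -> float:
    """Spectral radius of the VAR companion matrix."""
    A = np.asarray(coefficients, dtype=float)
    if A.ndim == 2:
        A = A[None, :, :]
    p, N, _ = A.shape
    companion = np.zeros((N * p, N * p))
    companion[:N, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        companion[N:, : N * (p - 1)] = np.eye(N * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def generate_var_fixture(
    coefficients,
    innovation_sd,
    n_samples: int,
    seed: int,
    labels=None,
    fs: float = 1000.0,
    burn_in: int = 500,
) -> SignalSegment:
    """Draw a stationary VAR realisation with the requested lag structure.

    ``coefficients`` is a list of (N, N) lag matrices ``A_r`` with
    ``A_r[i, j]`` the effect of channel j at lag r on channel i.  Raises
    :class:`StationarityError` if the companion spectral radius is >= 1.
    """
    A = np.asarray(coefficients, dtype=float)
    if A.ndim == 2:
        A = A[None, :, :]
    p, N, _ = A.shape
    rho = var_spectral_radius(A)
    if rho >= 1.0:
        raise StationarityError(
            f"VAR coefficient set is not stationary (companion spectral radius {rho:.3f} >= 1)"
        )
    sd = np.broadcast_to(np.asarray(innovation_sd, dtype=float), (N,))
    rng = np.random.default_rng(seed)
    total = n_samples + burn_in
    x = np.zeros((total, N))
    eps = rng.normal(0.0, 1.0, (total, N)) * sd
    for t in range(total):
        acc = eps[t].copy()
        for r in range(1, min(p, t) + 1):
            acc += A[r - 1] @ x[t - r]
        x[t] = acc
    if labels is None:
        labels = tuple(f"ch{i + 1}" for i in range(N))
    return SignalSegment(x[burn_in:].T, fs, tuple(labels))


def _default_true_params() -> dict:
    """Condition -> generating parameters: mid-box couplings with the 8 Hz
    K1 elevated by the planted effect (+500, a 25% increase)."""
    base = dict(C1=90.0, C2=90.0, K1=2000.0, K2=350.0)
    out = {}
    for c in CONDITIONS:
        d = dict(base)
        if c == "8":
            d["K1"] = 2500.0
        out[c] = DoubleColumnParams(**d)
    return out


def _default_var_coupling() -> dict:
    """Condition -> lag-1 visual-to-frontal VAR coefficient (planted flow)."""
    return {"control": 0.12, "8": 0.30, "44": 0.12, "84": 0.12}


@dataclass(frozen=True)
class StudyFixture:
    """Specification of the emulated study: subjects x conditions x segments,
    with per-subject parameter jitter around the condition-level truths."""

    subjects: int = 10
    conditions: tuple = CONDITIONS
    segments_per_condition: int = 5
    seed: int = 0
    true_params: dict = field(default_factory=_default_true_params)
    var_coupling: dict = field(default_factory=_default_var_coupling)
    duration: float = 3.0
    fs: float = 1000.0
    burn_in: float = 1.0
    pulse_amplitude: float = 7.0
    # between-subject sd of each parameter; within-subject (condition-level) sd
    subject_jitter: dict = field(
        default_factory=lambda: dict(C1=5.0, C2=5.0, K1=150.0, K2=50.0)
    )
    condition_jitter: dict = field(
        default_factory=lambda: dict(C1=2.0, C2=2.0, K1=50.0, K2=20.0)
    )
    var_coupling_jitter: float = 0.03

    def __post_init__(self) -> None:
        if self.subjects < 1 or self.segments_per_condition < 1:
            raise ValueError("subjects and segments_per_condition must be >= 1")
        object.__setattr__(
            self, "conditions", tuple(normalize_condition(c) for c in self.conditions)
        )


def _clip_params(d: dict) -> dict:
    return {k: float(np.clip(v, *PARAM_BOUNDS[k])) for k, v in d.items()}


def _electrode_var_coefficients(vc_to_fa: float) -> np.ndarray:
    """VAR(2) template over the six analysis electrodes.

    Channel order follows :data:`ELECTRODE_LABELS` (4 visual, 2 frontal).
    Baseline couplings: bidirectional links within each area, a weak fixed
    frontal-to-visual feedback, and a visual-to-frontal drive whose lag-1
    coefficient ``vc_to_fa`` carries the planted condition effect.
    """
    A1 = np.diag(np.full(6, 0.5))
    # within visual cortex
    A1[1, 0] = A1[3, 2] = 0.15
    A1[0, 1] = A1[2, 3] = 0.10
    A1[2, 0] = A1[3, 1] = 0.10
    # within frontal area
    A1[5, 4] = 0.15
    A1[4, 5] = 0.10
    # frontal -> visual feedback (constant across conditions)
    A1[0, 4] = A1[1, 5] = 0.08
    # visual -> frontal drive (planted)
    A1[4, 0] = A1[5, 1] = vc_to_fa
    A1[4, 2] = A1[5, 3] = vc_to_fa / 2.0
    A2 = np.diag(np.full(6, -0.10))
    return np.stack([A1, A2])


def _subject_truths(fixture: StudyFixture):
    """Draw per-subject, per-condition generating parameters (deterministic
    in the fixture seed)."""
    root = np.random.SeedSequence(fixture.seed)
    subj_seqs = root.spawn(fixture.subjects)
    out = []
    for s, seq in enumerate(subj_seqs):
        rng = np.random.default_rng(seq.spawn(1)[0])
        offsets = {k: rng.normal(0.0, sd) for k, sd in fixture.subject_jitter.items()}
        coupling_offset = rng.normal(0.0, fixture.var_coupling_jitter)
        per_condition = {}
        for c in fixture.conditions:
            base = fixture.true_params[c]
            jitter = {
                k: rng.normal(0.0, sd) for k, sd in fixture.condition_jitter.items()
            }
            vals = _clip_params(
                {
                    k: getattr(base, k) + offsets[k] + jitter[k]
                    for k in ("C1", "C2", "K1", "K2")
                }
            )
            coupling = float(
                np.clip(fixture.var_coupling[c] + coupling_offset, 0.02, 0.45)
            )
            per_condition[c] = (DoubleColumnParams(**vals), coupling)
        out.append((seq, per_condition))
    return out


def generate_study_fixture(
    fixture: StudyFixture, out_dir, overwrite: bool = False
) -> dict:
    """Write the full emulated study to ``out_dir`` and return its manifest.

    Layout: ``sub<SS>/<condition>/seg<K>.model.tsv`` (2-channel double-column
    recording, channels ``u1``/``u2``) and ``seg<K>.lfp.tsv`` (6-channel VAR
    recording over :data:`ELECTRODE_LABELS`), each with a JSON sidecar, plus
    ``manifest.json`` recording seeds and true parameters for every segment.
    """
    from .io import write_segment

    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output directory {out_dir} is not empty; pass overwrite=True to replace"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": fixture.seed,
        "fs": fixture.fs,
        "duration": fixture.duration,
        "burn_in": fixture.burn_in,
        "pulse_amplitude": fixture.pulse_amplitude,
        "conditions": list(fixture.conditions),
        "segments_per_condition": fixture.segments_per_condition,
        "electrode_labels": list(ELECTRODE_LABELS),
        "groups": DEFAULT_GROUPS,
        "subjects": [],
    }
    for s, (seq, per_condition) in enumerate(_subject_truths(fixture)):
        sid = f"sub{s + 1:02d}"
        subject_entry = {"id": sid, "conditions": {}}
        seg_seqs = iter(
            seq.spawn(2 * len(fixture.conditions) * fixture.segments_per_condition)
        )
        for c in fixture.conditions:
            params, coupling = per_condition[c]
            cond_dir = out_dir / sid / c
            cond_dir.mkdir(parents=True, exist_ok=True)
            spec = StimulusSpec(
                condition=c,
                pulse_amplitude=fixture.pulse_amplitude,
                duration=fixture.duration,
                fs=fixture.fs,
            )
            segments = []
            for k in range(fixture.segments_per_condition):
                model_seed = int(next(seg_seqs).generate_state(1)[0] % (2**31))
                lfp_seed = int(next(seg_seqs).generate_state(1)[0] % (2**31))
                fx = generate_inversion_fixture(
                    params, spec, model_seed, burn_in=fixture.burn_in
                )
                model_path = cond_dir / f"seg{k + 1}.model.tsv"
                write_segment(fx.segment, model_path)
                lfp = generate_var_fixture(
                    _electrode_var_coefficients(coupling),
                    1.0,
                    int(round(fixture.duration * fixture.fs)),
                    lfp_seed,
                    labels=ELECTRODE_LABELS,
                    fs=fixture.fs,
                )
                lfp_path = cond_dir / f"seg{k + 1}.lfp.tsv"
                write_segment(lfp, lfp_path)
                segments.append(
                    {
                        "index": k + 1,
                        "model_seed": model_seed,
                        "lfp_seed": lfp_seed,
                        "model_path": str(model_path.relative_to(out_dir)),
                        "lfp_path": str(lfp_path.relative_to(out_dir)),
                    }
                )
            subject_entry["conditions"][c] = {
                "true_params": {k: getattr(params, k) for k in ("C1", "C2", "K1", "K2")},
                "var_vc_to_fa": coupling,
                "segments": segments,
            }
        manifest["subjects"].append(subject_entry)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_manifest(study_dir) -> dict:
    with open(Path(study_dir) / "manifest.json") as fh:
        return json.load(fh)
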