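"""Synthetic treadmill-gait recordings.

Generates quasi-periodic three-channel recordings — anterio-posterior and
medio-lateral center-of-pressure displacement (COPap, COPml) and the
resultant vertical ground reaction force (vGRF) — with controllable
stride-time variability, within-cycle shape jitter, additive noise and slow
positional drift on the COP channels. The generator emulates the statistical
structure of instrumented-treadmill walking at 100 Hz so the downstream
segmentation, preprocessing, entropy and statistics stages can be exercised
without measured data.

Conventions
-----------
The stride phase origin (phase 0) is placed at the reference leg's
single-support midstance, i.e. the valley of the resultant vGRF when only
that foot is loaded. This is a phase-stable, observable landmark of the
force signal itself; any repeating event can anchor a stride, and choosing
this one means ``true_boundaries`` coincide with the events a vGRF-based
segmenter can actually detect. Units are centimeters for the COP channels,
newtons for vGRF, seconds and hertz for time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats as _sstats

from gaitent.errors import ParameterError

CHANNELS = ("copap", "copml", "vgrf")

#: duty factor — fraction of the stride each foot spends on the ground;
#: together with the M-depth chosen so the two-foot resultant has exactly two
#: local minima per stride (the single-support midstance valleys), with no
#: spurious dips at the double-support handover
_STANCE_FRACTION = 0.65
#: second-foot stance onset, in stride phase (half a stride after the first)
_CONTRA_OFFSET = 0.5
#: stride phase of the reference foot's heel strike (phase 0 = its midstance valley)
_HEEL_PHASE = -_STANCE_FRACTION / 2
#: relative weight of the third harmonic that carves the M-shape stance valley
_MSHAPE_DEPTH = 0.45
#: vGRF waveform oscillation scale, as a fraction of body weight, used for jitter
_VGRF_SHAPE_SCALE = 0.3


def _per_channel(value: float | Mapping[str, float], name: str) -> dict[str, float]:
    """Expand a scalar or per-channel mapping into a full channel dict."""
    if isinstance(value, Mapping):
        unknown = set(value) - set(CHANNELS)
        if unknown:
            raise ParameterError(name, f"unknown channels {sorted(unknown)}")
        return {c: float(value.get(c, 0.0)) for c in CHANNELS}
    return {c: float(value) for c in CHANNELS}


@dataclass(frozen=True)
class GaitParams:
    """Parameters of one synthetic treadmill recording.

    Attributes
    ----------
    sampling_rate : float
        Samples per second (Hz).
    mean_stride_time : float
        Mean stride duration in seconds. 1.06 s is a typical comfortable
        treadmill stride.
    stride_time_cv : float
        Coefficient of variation of stride durations. Draws are truncated
        at ±3 SD so no stride degenerates toward zero length.
    n_strides : int
        Number of strides to synthesize (>= 2).
    copap_amplitude, copml_amplitude : float
        Template excursion scales of the fore-aft and lateral COP
        oscillation, in cm.
    body_weight : float
        Mean level of the resultant vGRF, in N.
    waveform_noise_sd : float or mapping
        SD of additive i.i.d. Gaussian noise, in each channel's own units;
        a scalar applies to all channels, a mapping sets them individually.
    drift_rate : float
        Linear positional drift added to both COP channels, in cm/s —
        the slow treadmill drift the ZERO preprocessing is meant to remove.
    within_cycle_shape_jitter : float or mapping
        Dimensionless scale of per-stride smooth waveform perturbations
        (random low-order harmonics), relative to each channel's own
        oscillation scale. 0 gives identical cycle shapes.
    stance_asymmetry : float
        Fractional under-loading of the contralateral foot (0 = perfectly
        symmetric gait). A small asymmetry makes the reference leg
        identifiable from the vGRF alone.
    seed : int
        Seed for all randomness in the recording.
    """

    sampling_rate: float = 100.0
    mean_stride_time: float = 1.06
    stride_time_cv: float = 0.02
    n_strides: int = 28
    copap_amplitude: float = 20.0
    copml_amplitude: float = 8.0
    body_weight: float = 790.0
    waveform_noise_sd: float | Mapping[str, float] = 0.2
    drift_rate: float = 0.0
    within_cycle_shape_jitter: float | Mapping[str, float] = 0.1
    stance_asymmetry: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate", "must be > 0")
        if not self.mean_stride_time > 0:
            raise ParameterError("mean_stride_time", "must be > 0")
        if self.n_strides < 2:
            raise ParameterError("n_strides", "must be >= 2")
        if self.stride_time_cv < 0:
            raise ParameterError("stride_time_cv", "must be >= 0")
        if self.copap_amplitude < 0:
            raise ParameterError("copap_amplitude", "must be >= 0")
        if self.copml_amplitude < 0:
            raise ParameterError("copml_amplitude", "must be >= 0")
        if not self.body_weight > 0:
            raise ParameterError("body_weight", "must be > 0")
        if not 0 <= self.stance_asymmetry < 1:
            raise ParameterError("stance_asymmetry", "must be in [0, 1)")
        noise = _per_channel(self.waveform_noise_sd, "waveform_noise_sd")
        if any(v < 0 for v in noise.values()):
            raise ParameterError("waveform_noise_sd", "must be >= 0")
        jitter = _per_channel(self.within_cycle_shape_jitter, "within_cycle_shape_jitter")
        if any(v < 0 for v in jitter.values()):
            raise ParameterError("within_cycle_shape_jitter", "must be >= 0")

    @classmethod
    def for_duration(cls, duration_s: float, **kwargs) -> "GaitParams":
        """Params covering at least ``duration_s`` seconds of walking."""
        p = cls(**kwargs)
        n = int(np.ceil(duration_s / p.mean_stride_time))
        return replace(p, n_strides=max(n, 2))


@dataclass
class GaitRecording:
    """One subject x one condition of synchronized gait channels.

    ``true_boundaries`` (stride-start sample indices, at the reference leg's
    midstance valley) are present only for synthetic recordings.
    """

    sampling_rate: float
    copap: np.ndarray
    copml: np.ndarray
    vgrf: np.ndarray
    true_boundaries: np.ndarray | None = None

    def __post_init__(self):
        self.copap = np.asarray(self.copap, dtype=float)
        self.copml = np.asarray(self.copml, dtype=float)
        self.vgrf = np.asarray(self.vgrf, dtype=float)
        n = len(self.copap)
        if n < 1 or len(self.copml) != n or len(self.vgrf) != n:
            raise ParameterError("channels", "all three series must share a length >= 1")
        if np.any(self.vgrf < 0):
            raise ParameterError("vgrf", "vGRF samples must be non-negative")
        if self.true_boundaries is not None:
            b = np.asarray(self.true_boundaries, dtype=int)
            if np.any(np.diff(b) <= 0) or b.min(initial=0) < 0 or (len(b) and b[-1] >= n):
                raise ParameterError("true_boundaries", "must be strictly increasing within [0, N)")
            self.true_boundaries = b

    @property
    def n_samples(self) -> int:
        return len(self.copap)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel(self, variable: str) -> np.ndarray:
        if variable not in CHANNELS:
            raise ParameterError("variable", f"must be one of {CHANNELS}, got {variable!r}")
        return getattr(self, variable)


def _stance_profile(phase: np.ndarray, onset: float) -> np.ndarray:
    """M-shaped single-foot stance force profile over stride phase.

    The foot is on the ground for ``_STANCE_FRACTION`` of the stride starting
    at ``onset`` (stride phase, may be negative / wrap). Shape: two force
    peaks (loading and push-off) separated by a midstance valley.
    """
    s = np.mod(phase - onset, 1.0) / _STANCE_FRACTION
    in_stance = s < 1.0
    s = np.where(in_stance, s, 0.0)
    g = np.sin(np.pi * s) + _MSHAPE_DEPTH * np.sin(3 * np.pi * s)
    return np.where(in_stance, g, 0.0)


def _copap_template(phase: np.ndarray) -> np.ndarray:
    """Asymmetric fore-aft excursion: a long forward and a short return lobe."""
    psi = np.mod(phase - _HEEL_PHASE, 1.0)
    fwd = psi < 0.6
    out = np.empty_like(psi)
    out[fwd] = np.sin(np.pi * psi[fwd] / 0.6)
    out[~fwd] = -0.7 * np.sin(np.pi * (psi[~fwd] - 0.6) / 0.4)
    return out


def _jitter_wiggle(phase: np.ndarray, coefs: np.ndarray) -> np.ndarray:
    """Smooth per-stride waveform perturbation from three random harmonics."""
    a, b, c = coefs
    return (
        a * np.sin(2 * np.pi * phase)
        + b * np.cos(2 * np.pi * phase)
        + c * np.sin(4 * np.pi * phase)
    ) / np.sqrt(3.0)


def _draw_stride_durations(params: GaitParams, rng: np.random.Generator) -> np.ndarray:
    mean = params.mean_stride_time
    if params.stride_time_cv == 0:
        return np.full(params.n_strides, mean)
    sd = params.stride_time_cv * mean
    return _sstats.truncnorm.rvs(-3.0, 3.0, loc=mean, scale=sd, size=params.n_strides, random_state=rng)


def generate_recording(params: GaitParams) -> GaitRecording:
    """Synthesize one treadmill-walking recording.

    Per stride, a duration is drawn from a normal distribution truncated at
    ±3 SD; within each stride the three channels follow smooth periodic
    templates (asymmetric fore-aft COPap curve, one lateral COPml oscillation
    per stride, double-peaked per-foot vGRF stance profiles summed over both
    feet around body weight), optionally perturbed per stride by low-order
    harmonic jitter, then additive Gaussian noise and — on the COP channels —
    linear drift are applied. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    noise = _per_channel(params.waveform_noise_sd, "waveform_noise_sd")
    jitter = _per_channel(params.within_cycle_shape_jitter, "within_cycle_shape_jitter")

    durations = _draw_stride_durations(params, rng)
    onsets = np.concatenate([[0.0], np.cumsum(durations)])
    boundaries = np.rint(onsets * fs).astype(int)
    if np.any(np.diff(boundaries) < 2):
        raise ParameterError("mean_stride_time", "stride shorter than 2 samples at this sampling rate")
    n_samples = boundaries[-1]

    # per-sample stride index and within-stride phase in [0, 1)
    idx = np.arange(n_samples)
    stride_of = np.searchsorted(boundaries, idx, side="right") - 1
    b_lo = boundaries[stride_of]
    b_hi = boundaries[stride_of + 1]
    phase = (idx - b_lo) / (b_hi - b_lo)

    copap = params.copap_amplitude * _copap_template(phase)
    copml = params.copml_amplitude * np.sin(2 * np.pi * np.mod(phase - _HEEL_PHASE, 1.0))
    raw = _stance_profile(phase, _HEEL_PHASE) + (1.0 - params.stance_asymmetry) * _stance_profile(
        phase, _HEEL_PHASE + _CONTRA_OFFSET
    )
    vgrf = params.body_weight * raw / raw.mean()

    # per-stride smooth shape jitter, one harmonic triple per stride per channel
    scales = {
        "copap": jitter["copap"] * params.copap_amplitude,
        "copml": jitter["copml"] * params.copml_amplitude,
        "vgrf": jitter["vgrf"] * _VGRF_SHAPE_SCALE * params.body_weight,
    }
    coefs = rng.standard_normal((params.n_strides, 3, 3))
    if any(s > 0 for s in scales.values()):
        for ci, ch in enumerate(CHANNELS):
            if scales[ch] == 0:
                continue
            wig = _jitter_wiggle(phase, coefs[stride_of, ci, :].T) * scales[ch]
            if ch == "copap":
                copap = copap + wig
            elif ch == "copml":
                copml = copml + wig
            else:
                vgrf = vgrf + wig

    t = idx / fs
    if params.drift_rate != 0.0:
        copap = copap + params.drift_rate * t
        copml = copml + params.drift_rate * t

    for ch, arr in (("copap", copap), ("copml", copml), ("vgrf", vgrf)):
        if noise[ch] > 0:
            arr += rng.normal(0.0, noise[ch], size=n_samples)

    np.clip(vgrf, 0.0, None, out=vgrf)

    return GaitRecording(
        sampling_rate=fs,
        copap=copap,
        copml=copml,
        vgrf=vgrf,
        true_boundaries=boundaries[:-1],
    )


def generate_condition_pair(
    params_pref: GaitParams,
    params_max: GaitParams,
    subject_seed: int | None = None,
) -> tuple[GaitRecording, GaitRecording]:
    """Generate a (Vpref, Vmax) recording pair for one subject.

    When ``subject_seed`` is given, the two conditions use ``subject_seed``
    and ``subject_seed + 1`` so paired experiments are reproducible from one
    integer; otherwise each params' own seed is used.
    """
    params_pref.validate()
    params_max.validate()
    if subject_seed is not None:
        params_pref = replace(params_pref, seed=subject_seed)
        params_max = replace(params_max, seed=subject_seed + 1)
    return generate_recording(params_pref), generate_recording(params_max)
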