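"""Synthetic bipolar atrial electrogram (EGM) generator.

Produces seeded, morphology-controlled signals emulating the four Wells
organization classes of atrial fibrillation electrograms:

* Type I   — discrete activations on a stable (near-flat) isoelectric line;
* Type II  — discrete activations with a perturbed baseline;
* Type III — continuous fractionated activity, no discrete complexes and no
  isoelectric intervals (very short cycle lengths, <= 120 ms);
* Type IV  — Type III activity alternating with Type I/II stretches.

Activations are modelled as biphasic difference-of-Gaussians wavelets, the
shape a bipolar electrode pair records when a depolarization wavefront
passes under it.  Type III is built as a superposition of several
independently timed activation trains (colliding wavelets) plus a
band-limited continuous-activity floor.  All generators are deterministic
given ``SynthParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .errors import ParameterError, PatternError

__all__ = [
    "SynthParams",
    "EGMRecord",
    "gen_type1",
    "gen_type2",
    "gen_type3",
    "gen_type4",
    "gen_dataset",
    "DEFAULT_TYPE4_PATTERNS",
]

AF_TYPES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class SynthParams:
    """Morphology knobs for the synthetic EGM generators.

    Amplitudes are expressed as fractions of the (unit) nominal activation
    peak; downstream RMS normalization removes absolute scale anyway.

    Parameters
    ----------
    fs : sampling frequency, Hz.
    duration : record length, seconds.
    cl_mean : mean activation cycle length, ms (Type I/II trains).
    cl_jitter : relative SD of the cycle length (fraction of ``cl_mean``).
    spike_width : activation wavelet half-support, ms (the wavelet is
        exactly zero beyond ``spike_width`` ms from its center).
    baseline_noise_sd : white isoelectric-noise SD (fraction of peak).
    baseline_wander_sd : SD of the slow (1–15 Hz) residual baseline
        activity present even in organized recordings (fraction of peak).
    baseline_perturb_sd : Type II baseline-perturbation SD (fraction of
        peak); band-limited to the atrial fibrillatory-wave band (2–20 Hz).
    n_wavefronts : number of superposed activation trains for Type III.
    activity_floor_sd : Type III continuous-activity floor SD (fraction of
        peak); models the summed far-field of many simultaneous wavelets.
    seed : RNG seed; identical params + seed give bit-identical output.
    """

    fs: float = 1000.0
    duration: float = 10.0
    cl_mean: float = 170.0
    cl_jitter: float = 0.08
    spike_width: float = 10.0
    baseline_noise_sd: float = 0.02
    baseline_wander_sd: float = 0.03
    baseline_perturb_sd: float = 0.30
    n_wavefronts: int = 5
    activity_floor_sd: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ParameterError(f"fs must be positive, got {self.fs}")
        if self.duration <= 0:
            raise ParameterError(f"duration must be positive, got {self.duration}")
        if self.cl_mean <= 2 * self.spike_width:
            raise ParameterError(
                f"cl_mean ({self.cl_mean} ms) must exceed 2*spike_width "
                f"({2 * self.spike_width} ms)"
            )
        if not 0 <= self.cl_jitter < 1:
            raise ParameterError(f"cl_jitter must be in [0, 1), got {self.cl_jitter}")
        if self.spike_width <= 0:
            raise ParameterError("spike_width must be positive")
        if self.baseline_noise_sd < 0:
            raise ParameterError("baseline_noise_sd must be non-negative")
        if self.baseline_wander_sd < 0:
            raise ParameterError("baseline_wander_sd must be non-negative")
        if self.baseline_perturb_sd < 0:
            raise ParameterError("baseline_perturb_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class EGMRecord:
    """A single-channel electrogram with its sampling frequency and metadata."""

    samples: np.ndarray
    fs: float
    label: Optional[str] = None
    source: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("samples contain non-finite values")
        if self.fs <= 0:
            raise ParameterError("fs must be positive")
        if self.label is not None and self.label not in AF_TYPES:
            raise ParameterError(f"label must be one of {AF_TYPES}, got {self.label!r}")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


# ---------------------------------------------------------------------------
# activation wavelet and trains
# ---------------------------------------------------------------------------

def _biphasic_wavelet(width_ms: float, fs: float) -> np.ndarray:
    """Peak-normalized biphasic difference-of-Gaussians, zero outside
    +/- ``width_ms`` of the center."""
    half = int(round(width_ms * fs / 1000.0))
    t = np.arange(-half, half + 1) * (1000.0 / fs)  # ms
    sigma = width_ms / 5.0
    shift = sigma
    w = np.exp(-((t - shift) ** 2) / (2 * sigma**2)) - np.exp(
        -((t + shift) ** 2) / (2 * sigma**2)
    )
    return w / np.max(np.abs(w))


def _add_train(
    out: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    cl_mean: float,
    cl_jitter: float,
    width_ms: float,
    amp_low: float,
    amp_high: float,
) -> int:
    """Superpose one activation train onto ``out`` in place; returns the
    number of activations placed.  Inter-activation intervals are
    Normal(cl_mean, cl_jitter*cl_mean) ms, floored at 2*width_ms."""
    n = len(out)
    duration_ms = n * 1000.0 / fs
    kernel = _biphasic_wavelet(width_ms, fs)
    half = (len(kernel) - 1) // 2
    t = rng.uniform(0.0, cl_mean)
    count = 0
    while t < duration_ms:
        amp = rng.uniform(amp_low, amp_high)
        center = int(round(t * fs / 1000.0))
        lo, hi = center - half, center + half + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n)
        lo, hi = max(0, lo), min(n, hi)
        if lo < hi:
            out[lo:hi] += amp * kernel[klo:khi]
            count += 1
        step = rng.normal(cl_mean, cl_jitter * cl_mean)
        t += max(2 * width_ms, step)
    return count


def _bandlimited_noise(
    n: int, fs: float, rng: np.random.Generator, band: tuple, sd: float
) -> np.ndarray:
    """White noise band-passed to ``band`` (Hz) and rescaled to SD ``sd``."""
    raw = rng.standard_normal(n)
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, raw)
    s = np.std(x)
    if s == 0:
        return np.zeros(n)
    return x * (sd / s)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

#: Slow residual baseline activity band (Hz) present in every class.
WANDER_BAND = (1.0, 15.0)
#: Type II baseline-perturbation band (Hz): atrial fibrillatory waves.
PERTURB_BAND = (2.0, 20.0)
#: Type III continuous-activity floor band (Hz): summed far-field of many
#: simultaneous wavefronts.
FLOOR_BAND = (40.0, 250.0)


def _type1_core(params: SynthParams, ss: np.random.SeedSequence) -> np.ndarray:
    """Shared Type I/II skeleton: one quasi-regular train + white baseline
    noise + slow residual wander.  Draws from dedicated child streams so
    that Type II with zero perturbation reproduces Type I exactly."""
    train_ss, wander_ss = ss.spawn(2)
    rng = np.random.default_rng(train_ss)
    x = np.zeros(params.n_samples)
    _add_train(
        x,
        params.fs,
        rng,
        params.cl_mean,
        params.cl_jitter,
        params.spike_width,
        0.9,
        1.1,
    )
    if params.baseline_noise_sd > 0:
        x += rng.normal(0.0, params.baseline_noise_sd, params.n_samples)
    if params.baseline_wander_sd > 0:
        x += _bandlimited_noise(
            params.n_samples,
            params.fs,
            np.random.default_rng(wander_ss),
            WANDER_BAND,
            params.baseline_wander_sd,
        )
    return x


def gen_type1(params: SynthParams = SynthParams()) -> EGMRecord:
    """Type I: discrete activations with a stable isoelectric line."""
    core_ss, _ = np.random.SeedSequence(params.seed).spawn(2)
    x = _type1_core(params, core_ss)
    return EGMRecord(x, params.fs, label="I", meta={"params": _params_meta(params)})


def gen_type2(params: SynthParams = SynthParams()) -> EGMRecord:
    """Type II: discrete activations on a perturbed baseline.

    The perturbation is band-limited colored noise in the atrial
    fibrillatory-wave band (2–20 Hz) with SD ``baseline_perturb_sd``; with
    zero perturbation the output degenerates to :func:`gen_type1` for the
    same seed.
    """
    if params.baseline_perturb_sd > 0 and (
        params.baseline_perturb_sd <= params.baseline_noise_sd
    ):
        raise ParameterError(
            "baseline_perturb_sd must exceed baseline_noise_sd for Type II"
        )
    core_ss, extra_ss = np.random.SeedSequence(params.seed).spawn(2)
    x = _type1_core(params, core_ss)
    if params.baseline_perturb_sd > 0:
        x += _bandlimited_noise(
            params.n_samples,
            params.fs,
            np.random.default_rng(extra_ss),
            PERTURB_BAND,
            params.baseline_perturb_sd,
        )
    return EGMRecord(x, params.fs, label="II", meta={"params": _params_meta(params)})


def gen_type3(params: SynthParams = SynthParams()) -> EGMRecord:
    """Type III: continuous fractionated activity.

    Superposes ``n_wavefronts`` independently timed activation trains with
    short cycle lengths (70–120 ms, the CFAE regime) and randomized
    amplitudes/widths, peak-normalizes the sum, then adds a band-limited
    continuous-activity floor so no isoelectric gap longer than 50 ms
    survives.
    """
    if params.n_wavefronts < 3:
        raise ParameterError(
            f"n_wavefronts must be >= 3 for Type III, got {params.n_wavefronts}"
        )
    core_ss, extra_ss = np.random.SeedSequence(params.seed).spawn(2)
    rng = np.random.default_rng(core_ss)
    x = np.zeros(params.n_samples)
    for _ in range(params.n_wavefronts):
        cl = rng.uniform(70.0, 120.0)
        width = params.spike_width * rng.uniform(0.7, 1.3)
        _add_train(x, params.fs, rng, cl, 0.25, width, 0.3, 1.0)
    peak = np.max(np.abs(x))
    if peak > 0:
        x /= peak
    extra = np.random.default_rng(extra_ss)
    if params.activity_floor_sd > 0:
        x += _bandlimited_noise(
            params.n_samples, params.fs, extra, FLOOR_BAND, params.activity_floor_sd
        )
    if params.baseline_noise_sd > 0:
        x += extra.normal(0.0, params.baseline_noise_sd, params.n_samples)
    return EGMRecord(x, params.fs, label="III", meta={"params": _params_meta(params)})


_GENERATORS = {"I": gen_type1, "II": gen_type2, "III": gen_type3}

#: Ten-second alternation patterns (5 segments x 2 s) cycled by gen_dataset
#: when composing Type IV records.
DEFAULT_TYPE4_PATTERNS: tuple = (
    ("III", "I", "III", "I", "III"),
    ("I", "III", "I", "III", "I"),
    ("III", "II", "III", "II", "III"),
    ("II", "III", "II", "III", "II"),
    ("III", "I", "II", "I", "III"),
)


def gen_type4(
    params: SynthParams = SynthParams(),
    pattern: Sequence[str] = ("III", "I", "III", "I", "III"),
    seg_len_s: float = 2.0,
) -> EGMRecord:
    """Type IV: Type III activity alternating with Type I/II stretches.

    Concatenates per-tag generated segments with a 10 ms cross-taper at each
    junction (fade-out / fade-in) to avoid step discontinuities.  The
    ground-truth per-segment tags are stored in ``meta['segment_tags']``.
    """
    pattern = tuple(pattern)
    if any(tag not in ("I", "II", "III") for tag in pattern):
        raise PatternError(f"pattern tags must be I/II/III, got {pattern}")
    if "III" not in pattern or not any(tag in ("I", "II") for tag in pattern):
        raise PatternError(
            "pattern must contain at least one III tag and one I-or-II tag, "
            f"got {pattern}"
        )
    if seg_len_s < 1:
        raise ParameterError(f"seg_len_s must be >= 1 s, got {seg_len_s}")

    seg_params = replace(params, duration=seg_len_s)
    children = np.random.SeedSequence(params.seed).spawn(len(pattern))
    fade = int(round(0.010 * params.fs))  # 10 ms cross-taper
    pieces = []
    for i, (tag, child) in enumerate(zip(pattern, children)):
        seg_seed = int(child.generate_state(1)[0] % 2**31)
        seg = _GENERATORS[tag](replace(seg_params, seed=seg_seed)).samples
        if i > 0 and fade > 0:
            seg[:fade] *= np.linspace(0.0, 1.0, fade)
        if i < len(pattern) - 1 and fade > 0:
            seg[-fade:] *= np.linspace(1.0, 0.0, fade)
        pieces.append(seg)
    x = np.concatenate(pieces)
    meta = {
        "params": _params_meta(params),
        "segment_tags": list(pattern),
        "seg_len_s": float(seg_len_s),
        "crossfade_ms": 10.0,
    }
    return EGMRecord(x, params.fs, label="IV", meta=meta)


def gen_dataset(
    spec: Sequence[tuple],
    params: SynthParams = SynthParams(),
    seed: int = 0,
) -> list:
    """Generate a labelled dataset from a list of ``(af_type, count)`` pairs.

    Per-record seeds are derived from ``seed`` by a counter so the whole
    dataset is deterministic; Type IV records cycle through
    :data:`DEFAULT_TYPE4_PATTERNS`.
    """
    records = []
    counter = 0
    for af_type, count in spec:
        if af_type not in AF_TYPES:
            raise ParameterError(f"unknown AF type {af_type!r}")
        if count < 0:
            raise ParameterError(f"count must be >= 0, got {count}")
        for _ in range(int(count)):
            child = int(
                np.random.SeedSequence([int(seed), counter]).generate_state(1)[0]
                % 2**31
            )
            p = replace(params, seed=child)
            if af_type == "IV":
                pat = DEFAULT_TYPE4_PATTERNS[counter % len(DEFAULT_TYPE4_PATTERNS)]
                rec = gen_type4(p, pattern=pat, seg_len_s=params.duration / len(pat))
            else:
                rec = _GENERATORS[af_type](p)
            records.append(rec)
            counter += 1
    return records


def _params_meta(params: SynthParams) -> dict:
    d = {k: getattr(params, k) for k in params.__dataclass_fields__}
    return d
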