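"""Synthetic paired paretic / non-paretic surface-EMG gesture recordings.

The generator emulates the acquisition setup of a 4-channel wireless sEMG
device sampling at 1 kHz with a ±1.5 mV operating range, electrodes over
the flexor carpi radialis (channel 1), flexor carpi ulnaris (channel 2),
thenar eminence (channel 3) and extensor digitorum communis (channel 4).

Signal model per repetition and channel::

    s(t) = clip( a_ch(t) * c_ch(t) + n_floor * w(t) , ±limit )

where ``c_ch`` is white Gaussian noise bandpass-filtered to 20-300 Hz (the
conventional sEMG energy band), ``a_ch(t)`` is a trapezoidal activation
envelope scaled by gesture- and subject-specific channel gains, and ``w``
is broadband floor noise. The paretic arm additionally applies

* global attenuation ``alpha`` of voluntary drive,
* co-contraction leakage ``lambda`` that mixes flexor and extensor
  envelopes (abnormal flexor-extensor coupling after stroke),
* 4-8 Hz multiplicative tremor amplitude modulation,
* an elevated noise floor.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` so every output is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .cohort import Cohort
from .gestures import Gesture, GESTURES, as_gesture

N_CHANNELS = 4
FLEXOR_CHANNELS = (0, 1)   # FCR, FCU
EXTENSOR_CHANNEL = 3       # EDC

#: baseline (non-paretic) noise-floor standard deviation, mV
NOISE_FLOOR_MV = 0.02


@dataclass(frozen=True)
class SimConfig:
    """Acquisition-protocol and cohort-level simulation parameters."""

    sampling_rate: int = 1000          # Hz
    gesture_duration: float = 0.75     # s -> 750 samples per repetition
    reps_per_class: int = 10           # balanced repetitions kept per class
    device_limit: float = 1.5          # mV hard clip of the amplifier
    seed: int = 0
    raw_reps_range: tuple[int, int] = (10, 20)  # raw attempts drawn per class
    gap_duration: float = 0.5          # s of rest between gestures in a stream
    # paresis severity of a cohort-average subject's paretic arm; individual
    # subjects scale these with their motor-impairment (FMA-UE) score
    paresis_alpha: float = 0.6         # voluntary-drive attenuation in (0, 1]
    paresis_cocontraction: float = 0.3 # flexor<->extensor envelope leakage in [0, 1)
    paresis_tremor_depth: float = 0.2  # amplitude-modulation depth in [0, 1)
    paresis_noise_mult: float = 1.5    # noise-floor multiplier >= 1
    gain_sigma: float = 0.5            # log-normal sd of per-subject channel gains
    channel_mixing: float = 0.4        # mean strength of per-subject electrode crosstalk
    synergy_collapse: float = 0.6      # paretic loss of selective activation at nominal severity
    rep_gain_sigma: float = 0.1        # trial-to-trial log-normal gain jitter (non-paretic)
    rest_tone: float = 0.22            # tonic paretic baseline activity (fraction of 1 mV)

    def __post_init__(self):
        n = self.sampling_rate * self.gesture_duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError("sampling_rate * gesture_duration must be an integer "
                             f"number of samples, got {n}")
        if self.reps_per_class < 1:
            raise ValueError("reps_per_class must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.sampling_rate * self.gesture_duration))


@dataclass(frozen=True)
class GestureTemplate:
    """Per-gesture channel activation pattern and envelope timing."""

    gesture: Gesture
    channel_gains: tuple[float, float, float, float]  # mV per channel
    envelope: tuple[float, float, float] = (0.2, 0.5, 0.2)  # rise/hold/fall fractions

    def __post_init__(self):
        if len(self.channel_gains) != N_CHANNELS:
            raise ValueError("channel_gains must have 4 entries")
        if any(g < 0 for g in self.channel_gains):
            raise ValueError("channel gains must be non-negative")
        if sum(self.envelope) > 1 + 1e-9:
            raise ValueError("rise + hold + fall fractions must not exceed 1")


@dataclass(frozen=True)
class SubjectProfile:
    """Stable physiological parameters of one subject.

    Channel gain multipliers model electrode placement and anatomy and are
    shared between the two arms; the paresis parameters apply to the
    paretic arm only (the non-paretic arm always behaves like
    ``alpha=1, cocontraction=0, tremor_depth=0, noise_mult=1``).
    """

    subject_id: str
    channel_gain_multipliers: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    alpha: float = 1.0
    cocontraction: float = 0.0
    tremor_depth: float = 0.0
    tremor_freq: float = 6.0           # Hz, physiological post-stroke band 4-8
    noise_floor_multiplier: float = 1.0
    #: per-subject electrode crosstalk: rows mix the channel envelopes; the
    #: identity means perfectly selective electrode placement
    channel_mixing: tuple[tuple[float, ...], ...] = (
        (1.0, 0.0, 0.0, 0.0), (0.0, 1.0, 0.0, 0.0),
        (0.0, 0.0, 1.0, 0.0), (0.0, 0.0, 0.0, 1.0))
    #: repetition-to-repetition envelope variability (onset/shape jitter);
    #: paretic activations are markedly less repeatable
    envelope_jitter: float = 0.05
    envelope_jitter_paretic: float = 0.05
    #: abnormal mass-synergy pattern the paretic arm collapses toward
    #: (unit-mean channel weights); ``synergy_collapse`` is the stable
    #: subject-level part and ``synergy_collapse_rep`` the per-repetition
    #: random part (erratic loss of selective control varies trial to trial)
    synergy_pattern: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    synergy_collapse: float = 0.0
    synergy_collapse_rep: float = 0.0
    #: tonic involuntary activation of the paretic arm at rest (mV scale)
    rest_tone_mv: float = 0.0
    #: trial-to-trial log-normal channel-gain jitter per arm
    rep_gain_sigma: float = 0.1
    rep_gain_sigma_paretic: float = 0.1

    def __post_init__(self):
        if not 0 < self.alpha <= 1:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0 <= self.cocontraction < 1:
            raise ValueError(f"cocontraction must be in [0, 1), got {self.cocontraction}")
        if not 0 <= self.tremor_depth < 1:
            raise ValueError(f"tremor_depth must be in [0, 1), got {self.tremor_depth}")
        if self.noise_floor_multiplier < 1:
            raise ValueError("noise_floor_multiplier must be >= 1")


@dataclass(frozen=True)
class Recording:
    """One 750-sample x 4-channel gesture repetition, in mV."""

    subject_id: str
    session: str                # 'single', 'A' or 'B'
    arm: str                    # 'paretic' or 'non_paretic'
    gesture: Gesture
    repetition: int
    signal: np.ndarray          # (n_samples, 4) float32, mV
    sampling_rate: int = 1000
    device_limit: float = 1.5

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.session, self.arm, self.gesture.value, self.repetition)


@dataclass
class RecordingSet:
    """A collection of recordings with a queryable manifest."""

    recordings: list[Recording] = field(default_factory=list)
    config: SimConfig | None = None

    def __len__(self) -> int:
        return len(self.recordings)

    def manifest(self):
        import pandas as pd
        return pd.DataFrame(
            [{"subject_id": r.subject_id, "session": r.session, "arm": r.arm,
              "gesture": r.gesture.value, "repetition": r.repetition}
             for r in self.recordings])

    def select(self, subject_id=None, session=None, arm=None, gesture=None) -> "RecordingSet":
        out = []
        for r in self.recordings:
            if subject_id is not None and r.subject_id != subject_id:
                continue
            if session is not None and r.session != session:
                continue
            if arm is not None and r.arm != arm:
                continue
            if gesture is not None and r.gesture != as_gesture(gesture):
                continue
            out.append(r)
        return RecordingSet(out, self.config)

    def save(self, out_dir: str | Path, fmt: str = "%.5f") -> None:
        """One delimited-text file per repetition plus a JSON manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, r in enumerate(self.recordings):
            fname = f"rec_{i:05d}.csv"
            np.savetxt(out_dir / fname, r.signal, delimiter=",", fmt=fmt)
            entries.append({"file": fname, "subject_id": r.subject_id,
                            "session": r.session, "arm": r.arm,
                            "gesture": r.gesture.value, "repetition": r.repetition,
                            "sampling_rate": r.sampling_rate,
                            "device_limit": r.device_limit})
        (out_dir / "manifest.json").write_text(json.dumps(entries, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "RecordingSet":
        in_dir = Path(in_dir)
        entries = json.loads((in_dir / "manifest.json").read_text())
        recs = []
        for e in entries:
            sig = np.loadtxt(in_dir / e["file"], delimiter=",", dtype=np.float32)
            recs.append(Recording(
                subject_id=e["subject_id"], session=e["session"], arm=e["arm"],
                gesture=as_gesture(e["gesture"]), repetition=e["repetition"],
                signal=sig.reshape(-1, N_CHANNELS),
                sampling_rate=e["sampling_rate"], device_limit=e["device_limit"]))
        return cls(recs)


def make_default_templates() -> dict[Gesture, GestureTemplate]:
    """Default channel-gain patterns for the seven gestures.

    Gains follow the muscle groups each gesture recruits under the
    electrode montage (1 FCR, 2 FCU, 3 thenar, 4 EDC):

    ================  =====  =====  ======  =====
    gesture           FCR    FCU    thenar  EDC
    ================  =====  =====  ======  =====
    rest              0      0      0       0
    fist              0.80   0.70   0.60    0.15
    index_pinch       0.45   0.20   0.90    0.20
    wrist_flexion     0.90   0.85   0.10    0.10
    wrist_extension   0.15   0.10   0.10    1.00
    fingers_opening   0.25   0.20   0.50    0.75
    thumbs_up         0.15   0.20   0.70    0.60
    ================  =====  =====  ======  =====

    (mV before subject multipliers; rest is noise floor only.)
    """
    gains = {
        Gesture.REST: (0.0, 0.0, 0.0, 0.0),
        Gesture.FIST: (0.80, 0.70, 0.60, 0.15),
        Gesture.INDEX_PINCH: (0.45, 0.20, 0.90, 0.20),
        Gesture.WRIST_FLEXION: (0.90, 0.85, 0.10, 0.10),
        Gesture.WRIST_EXTENSION: (0.15, 0.10, 0.10, 1.00),
        Gesture.FINGERS_OPENING: (0.25, 0.20, 0.50, 0.75),
        Gesture.THUMBS_UP: (0.15, 0.20, 0.70, 0.60),
    }
    envelopes = {
        Gesture.REST: (0.0, 1.0, 0.0),
        Gesture.FIST: (0.15, 0.6, 0.15),
        Gesture.INDEX_PINCH: (0.25, 0.45, 0.25),
        Gesture.WRIST_FLEXION: (0.2, 0.55, 0.2),
        Gesture.WRIST_EXTENSION: (0.2, 0.55, 0.2),
        Gesture.FINGERS_OPENING: (0.1, 0.65, 0.2),
        Gesture.THUMBS_UP: (0.3, 0.4, 0.25),
    }
    return {g: GestureTemplate(g, gains[g], envelopes[g]) for g in GESTURES}


_SOS_CACHE: dict[tuple, np.ndarray] = {}


def _carrier_sos(fs: int) -> np.ndarray:
    key = ("carrier", fs)
    if key not in _SOS_CACHE:
        _SOS_CACHE[key] = butter(4, [20.0, 300.0], btype="bandpass", fs=fs, output="sos")
    return _SOS_CACHE[key]


def _trapezoid(n: int, rise: float, hold: float, fall: float,
               onset: float = 0.0) -> np.ndarray:
    """Trapezoidal envelope on [0, 1]; zero before onset and after the fall."""
    t = np.arange(n, dtype=np.float64) / n
    env = np.zeros(n)
    r_end = onset + rise
    h_end = r_end + hold
    f_end = h_end + fall
    if rise > 0:
        m = (t >= onset) & (t < r_end)
        env[m] = (t[m] - onset) / rise
    m = (t >= r_end) & (t < h_end)
    env[m] = 1.0
    if fall > 0:
        m = (t >= h_end) & (t < f_end)
        env[m] = (f_end - t[m]) / fall
    return env


def simulate_repetition(template: GestureTemplate, profile: SubjectProfile,
                        arm: str, config: SimConfig, rng: np.random.Generator,
                        *, session: str = "single", repetition: int = 0) -> Recording:
    """Draw one repetition for one arm of one subject.

    The paretic arm applies the profile's paresis parameters; the
    non-paretic arm is the identity (``alpha=1``, no leakage, no tremor).
    The rng stream is consumed identically for both arms so that, for a
    profile with no paresis, paretic and non-paretic draws from identical
    generator states coincide sample for sample.
    """
    if arm not in ("paretic", "non_paretic"):
        raise ValueError(f"arm must be 'paretic' or 'non_paretic', got {arm!r}")
    n = config.n_samples
    fs = config.sampling_rate

    carrier = rng.standard_normal((n, N_CHANNELS))
    floor = rng.standard_normal((n, N_CHANNELS))
    tremor_phase = rng.uniform(0, 2 * np.pi)   # drawn for both arms: stream parity
    jit = rng.uniform(size=4)                  # onset + rise/hold/fall jitter draws
    gain_z = rng.standard_normal(N_CHANNELS)   # trial-to-trial gain jitter draws
    beta_u = rng.uniform()                     # trial-to-trial collapse strength
    syn_z = rng.standard_normal(N_CHANNELS)    # trial-to-trial collapse direction

    carrier = sosfiltfilt(_carrier_sos(fs), carrier, axis=0)
    # unit-RMS carrier so channel gains are interpretable as mV RMS
    carrier /= np.sqrt(np.mean(carrier ** 2, axis=0, keepdims=True))

    paretic = arm == "paretic"
    j = profile.envelope_jitter_paretic if paretic else profile.envelope_jitter
    rise, hold, fall = template.envelope
    onset = float(jit[0]) * j
    rise, hold, fall = (max(x * (1 + 2 * j * (u - 0.5)), 0.0)
                        for x, u in zip((rise, hold, fall), jit[1:]))
    overrun = onset + rise + hold + fall
    if overrun > 1:
        rise, hold, fall = (x / overrun for x in (rise, hold, fall))
        onset /= overrun
    trap = _trapezoid(n, rise, hold, fall, onset)
    gains = np.asarray(template.channel_gains) * np.asarray(profile.channel_gain_multipliers)

    if paretic:
        gains = gains * profile.alpha
        # loss of selective control: the intended pattern partially collapses
        # toward an abnormal mass synergy, preserving overall drive. The
        # stable part points at the subject's own synergy; the (larger)
        # erratic part varies in strength and direction every repetition.
        beta_s = profile.synergy_collapse
        beta_r = profile.synergy_collapse_rep * beta_u
        if beta_s + beta_r > 0:
            mean_gain = float(np.mean(gains))
            syn_sub = np.asarray(profile.synergy_pattern)
            syn_rep = np.abs(syn_z) + 0.3
            syn_rep = syn_rep / syn_rep.mean()
            gains = ((1 - beta_s - beta_r) * gains
                     + beta_s * syn_sub * mean_gain
                     + beta_r * syn_rep * mean_gain)
    sigma_rep = profile.rep_gain_sigma_paretic if paretic else profile.rep_gain_sigma
    gains = gains * np.exp(sigma_rep * gain_z)
    amp = trap[:, None] * gains[None, :]          # (n, 4) per-channel envelope
    if paretic and profile.rest_tone_mv > 0:
        # tonic involuntary activity (spasticity) regardless of the gesture
        amp = amp + profile.rest_tone_mv * np.asarray(profile.synergy_pattern)[None, :]

    if paretic and profile.cocontraction > 0:
        lam = profile.cocontraction
        mixed = amp.copy()
        ext = amp[:, EXTENSOR_CHANNEL]
        flex_mean = amp[:, list(FLEXOR_CHANNELS)].mean(axis=1)
        for ch in FLEXOR_CHANNELS:
            mixed[:, ch] = (1 - lam) * amp[:, ch] + lam * ext
        mixed[:, EXTENSOR_CHANNEL] = (1 - lam) * ext + lam * flex_mean
        amp = mixed

    # subject-specific electrode crosstalk applies to both arms (anatomy)
    M = np.asarray(profile.channel_mixing)
    if not np.allclose(M, np.eye(N_CHANNELS)):
        amp = amp @ M.T

    if paretic and profile.tremor_depth > 0:
        t = np.arange(n) / fs
        mod = 1.0 - profile.tremor_depth * (0.5 + 0.5 * np.sin(
            2 * np.pi * profile.tremor_freq * t + tremor_phase))
        amp = amp * mod[:, None]

    noise_mult = profile.noise_floor_multiplier if paretic else 1.0
    signal = amp * carrier + NOISE_FLOOR_MV * noise_mult * floor
    signal = np.clip(signal, -config.device_limit, config.device_limit)
    return Recording(subject_id=profile.subject_id, session=session, arm=arm,
                     gesture=template.gesture, repetition=repetition,
                     signal=signal.astype(np.float32),
                     sampling_rate=fs, device_limit=config.device_limit)


#: cohort-nominal FMA-UE used to anchor severity scaling (the study cohort's
#: mean upper-extremity score)
NOMINAL_FMA_UE = 37.0


def draw_profile(subject_id: str, config: SimConfig, rng: np.random.Generator,
                 fma_ue: float | None = None) -> SubjectProfile:
    """Draw one subject's stable profile from the cohort-level config.

    The config's paresis parameters describe a subject at the cohort-nominal
    impairment (FMA-UE ~ 37/66); an individual's severity scales linearly
    with their own motor deficit, so a near-intact subject (FMA-UE 64)
    barely attenuates while a severely impaired one (FMA-UE 8) is strongly
    degraded. Without a score the nominal severity applies unchanged.
    """
    mult = np.exp(rng.normal(0.0, config.gain_sigma, N_CHANNELS))
    freq = rng.uniform(4.0, 8.0)
    # electrode-crosstalk signature: diagonally dominant row-stochastic mix
    kappa = config.channel_mixing * rng.uniform(0.5, 1.5)
    kappa = min(max(kappa, 0.0), 0.9)
    S = np.abs(rng.standard_normal((N_CHANNELS, N_CHANNELS)))
    np.fill_diagonal(S, 0.0)
    row_sums = S.sum(axis=1, keepdims=True)
    S = np.divide(S, row_sums, out=np.zeros_like(S), where=row_sums > 0)
    M = (1 - kappa) * np.eye(N_CHANNELS) + kappa * S

    impair_nominal = 1.0 - NOMINAL_FMA_UE / 66.0
    impair = (1.0 - float(fma_ue) / 66.0) if fma_ue is not None else impair_nominal
    # EMG-pattern degradation grades with the motor deficit but never
    # vanishes in the subacute phase: even high-FMA patients show clearly
    # abnormal activation patterns, hence the severity floor
    severity = max(impair / impair_nominal, 0.85)
    alpha = float(np.clip(1.0 - (1.0 - config.paresis_alpha) * severity, 0.15, 1.0))
    lam = float(np.clip(config.paresis_cocontraction * severity, 0.0, 0.8))
    depth = float(np.clip(config.paresis_tremor_depth * severity, 0.0, 0.8))
    noise_mult = 1.0 + (config.paresis_noise_mult - 1.0) * max(severity, 0.0)
    no_paresis = (config.paresis_alpha == 1.0 and config.paresis_cocontraction == 0.0
                  and config.paresis_tremor_depth == 0.0)
    jitter_paretic = 0.05 if no_paresis else min(0.05 + 0.25 * max(severity, 0.0), 0.5)
    syn = np.abs(rng.standard_normal(N_CHANNELS)) + 0.3
    syn = syn / syn.mean()
    beta_total = 0.0 if no_paresis else float(np.clip(config.synergy_collapse * severity,
                                                      0.0, 0.85))
    # degradation is mostly erratic (trial-varying), partly subject-stable
    beta_stable, beta_rep = 0.35 * beta_total, 0.65 * beta_total
    tone = 0.0 if no_paresis else float(max(config.rest_tone * severity, 0.0))
    sigma_rep_par = (config.rep_gain_sigma if no_paresis
                     else config.rep_gain_sigma + 0.3 * max(severity, 0.0))
    return SubjectProfile(
        subject_id=subject_id,
        channel_gain_multipliers=tuple(float(m) for m in mult),
        alpha=alpha,
        cocontraction=lam,
        tremor_depth=depth,
        tremor_freq=float(freq),
        noise_floor_multiplier=max(noise_mult, 1.0),
        channel_mixing=tuple(tuple(float(x) for x in row) for row in M),
        envelope_jitter=0.05,
        envelope_jitter_paretic=float(jitter_paretic),
        synergy_pattern=tuple(float(x) for x in syn),
        synergy_collapse=beta_stable,
        synergy_collapse_rep=beta_rep,
        rest_tone_mv=tone,
        rep_gain_sigma=config.rep_gain_sigma,
        rep_gain_sigma_paretic=float(min(sigma_rep_par, 0.8)),
    )


_SESSION_CODE = {"single": 0, "A": 1, "B": 2}
_ARM_CODE = {"non_paretic": 0, "paretic": 1}


def simulate_cohort(cohort: Cohort, config: SimConfig,
                    templates: dict[Gesture, GestureTemplate] | None = None) -> RecordingSet:
    """Simulate every cohort record: both arms x 7 gestures x balanced reps.

    For each (record, arm, gesture) a raw number of attempts is drawn
    uniformly from ``raw_reps_range`` (the clinical protocol over-records),
    then the first ``reps_per_class`` repetitions are kept so every class is
    exactly balanced. Subject profiles depend only on (seed, subject), so a
    patient measured in sessions A and B keeps the same anatomy while the
    recordings themselves differ.
    """
    templates = templates or make_default_templates()
    subject_order = {pid: i for i, pid in enumerate(cohort.patient_ids)}
    recs: list[Recording] = []
    for record in cohort.records:
        sidx = subject_order[record.patient_id]
        profile = draw_profile(
            record.patient_id, config,
            np.random.default_rng(np.random.SeedSequence([config.seed, 7, sidx])),
            fma_ue=record.fma_ue)
        for arm_name, arm_code in _ARM_CODE.items():
            for gidx, gesture in enumerate(GESTURES):
                ss = np.random.SeedSequence(
                    [config.seed, sidx, _SESSION_CODE[record.session], arm_code, gidx])
                rng = np.random.default_rng(ss)
                raw_count = int(rng.integers(config.raw_reps_range[0],
                                             config.raw_reps_range[1] + 1))
                for rep in range(min(raw_count, config.reps_per_class)):
                    recs.append(simulate_repetition(
                        templates[gesture], profile, arm_name, config, rng,
                        session=record.session, repetition=rep))
                # consume the rng for the discarded surplus attempts so the
                # stream layout matches the recorded protocol
                n_discard = max(raw_count - config.reps_per_class, 0)
                if n_discard:
                    rng.standard_normal((n_discard, 1))
    return RecordingSet(recs, config)


def concatenate_session(recordings: list[Recording], config: SimConfig | None = None,
                        rng: np.random.Generator | None = None):
    """Concatenate one subject/arm's repetitions into a continuous stream.

    Returns ``(stream, markers)`` where ``markers[i]`` is the 0-based start
    sample of repetition ``i``. Repetitions are separated by
    ``gap_duration`` seconds of rest-level noise.
    """
    if not recordings:
        raise ValueError("cannot concatenate an empty recording list")
    first = recordings[0]
    if any((r.subject_id, r.session, r.arm) != (first.subject_id, first.session, first.arm)
           for r in recordings):
        raise ValueError("all recordings must share subject, session and arm")
    config = config or SimConfig(sampling_rate=first.sampling_rate,
                                 device_limit=first.device_limit)
    rng = rng or np.random.default_rng(0)
    gap_n = int(round(config.gap_duration * config.sampling_rate))
    pieces, markers, pos = [], [], 0
    for r in recordings:
        markers.append(pos)
        pieces.append(r.signal)
        pos += r.signal.shape[0]
        gap = (NOISE_FLOOR_MV * rng.standard_normal((gap_n, N_CHANNELS))).astype(np.float32)
        pieces.append(gap)
        pos += gap_n
    stream = np.concatenate(pieces, axis=0)
    return stream, np.asarray(markers, dtype=np.int64)
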