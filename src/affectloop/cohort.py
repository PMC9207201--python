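"""Synthetic participant cohort for closed-loop emotion-induction studies.

Real per-trial EEG from music-listening experiments is rarely shareable,
so this module generates a cohort of synthetic participants, each with
an individual mapping from felt emotion to EEG band power, plus the
trial structure used throughout the package: 5 s of silence for baseline
correction followed by 20 s of music listening, with a 9-point SAM
self-report of felt valence and arousal in [0, 1].

Generative model
----------------
Each participant owns, per frequency band, a gain matrix (channels x 2)
that maps felt (valence, arousal) — centred at the neutral point
(0.5, 0.5) — to additive offsets of the per-channel log band-power.  A
trial's EEG is a sum over the five canonical bands of band-limited
Gaussian noise whose variance is::

    exp(baseline + gain @ (felt - 0.5) + noise)     while listening
    exp(baseline + gain @ (rest - 0.5) + noise)     before listening

where ``rest`` is the participant's resting emotion (neutral by
default, so the pre-listening variance reduces to
``exp(baseline + noise)``) and the two noise draws (sd ``noise_scale``,
per band and channel) are independent between the periods, so they
survive baseline correction and act as genuine feature noise.  The felt emotion is an affine,
per-axis distortion of the music generator's input, clipped to the unit
square: individuals do not feel exactly what the generator intends.
Because log band-power variance is the exact sufficient statistic of
this model, the downstream log-variance feature pipeline is a faithful
readout of the programmed emotion signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as _feat

__all__ = [
    "EmotionPoint", "PopulationPrior", "ParticipantModel", "TrialRecord",
    "TaskDataset", "stimulus_grid", "sample_participant", "felt_emotion",
    "quantize_sam", "generate_trial", "simulate_window", "build_cohort",
    "test_pieces", "STIMULUS_GRID_NAMES",
]


@dataclass(frozen=True)
class EmotionPoint:
    """A (valence, arousal) coordinate on the unit square."""

    valence: float
    arousal: float

    def __post_init__(self):
        for name in ("valence", "arousal"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.valence, self.arousal])

    @staticmethod
    def from_array(a) -> "EmotionPoint":
        a = np.asarray(a, dtype=float)
        return EmotionPoint(float(a[0]), float(a[1]))


# ---------------------------------------------------------------------
# stimulus grids

_TRAIN5 = [(0, 0), (0, 1), (0.5, 0.5), (1, 0), (1, 1)]
_TRAIN9 = _TRAIN5 + [(0, 0.5), (0.5, 0), (0.5, 1), (1, 0.5)]
_TRAIN13 = _TRAIN9 + [(0.25, 0.25), (0.25, 0.75), (0.75, 0.25), (0.75, 0.75)]
_TRAIN25 = _TRAIN13 + [
    (0, 0.25), (0, 0.75), (0.25, 0), (0.25, 0.5), (0.25, 1), (0.5, 0.25),
    (0.5, 0.75), (0.75, 0), (0.75, 0.5), (0.75, 1), (1, 0.25), (1, 0.75),
]
# The 25 training inputs lie exactly on the {0, .25, .5, .75, 1}^2 lattice.
# The remaining 16 of the 41 stimuli (the held-out test pieces) are taken
# on the interleaved {.125, .375, .625, .875}^2 lattice, which also hosts
# four of the five induction targets.
_TEST16 = [
    (v, a)
    for v in (0.125, 0.375, 0.625, 0.875)
    for a in (0.125, 0.375, 0.625, 0.875)
]
_FULL41 = _TRAIN25 + _TEST16
_TARGETS5 = [(0.125, 0.125), (0.125, 0.875), (0.5, 0.5), (0.875, 0.125), (0.875, 0.875)]

_GRIDS = {
    "train5": _TRAIN5,
    "train9": _TRAIN9,
    "train13": _TRAIN13,
    "train25": _TRAIN25,
    "full41": _FULL41,
    "targets5": _TARGETS5,
}
STIMULUS_GRID_NAMES = tuple(_GRIDS)


def stimulus_grid(name: str) -> list[EmotionPoint]:
    """Return one of the named music-generator input sets.

    ``train5`` .. ``train25`` are the nested fine-tuning sets; ``full41``
    is the complete stimulus battery (the 25 training inputs plus the 16
    held-out test pieces); ``targets5`` are the five induction targets.
    """
    try:
        pts = _GRIDS[name]
    except KeyError:
        raise ValueError(
            f"unknown stimulus grid {name!r}; choose from {STIMULUS_GRID_NAMES}"
        ) from None
    return [EmotionPoint(float(v), float(a)) for v, a in pts]


def test_pieces() -> list[EmotionPoint]:
    """The 16 stimuli of full41 that are in no training subset."""
    return [EmotionPoint(float(v), float(a)) for v, a in _TEST16]


# ---------------------------------------------------------------------
# participants


@dataclass(frozen=True)
class PopulationPrior:
    """Hyperparameters of the participant population.

    ``gain_population_scale`` sets the magnitude of the emotion-to-band-
    power mapping shared by the population; ``gain_individual_sd`` sets
    how strongly each participant deviates from it (inter-individual
    heterogeneity, the reason per-subject adaptation pays off).
    ``rest_sd`` spreads resting emotions around neutral; it is 0 by
    default so pre-listening EEG carries no emotion signal.
    """

    n_channels: int = 14
    baseline_logvar_mean: float = 0.0
    baseline_logvar_sd: float = 0.3
    gain_population_scale: float = 1.0
    gain_individual_sd: float = 1.0
    affect_gain_mean: float = 1.0
    affect_gain_sd: float = 0.15
    affect_offset_sd: float = 0.15
    noise_scale: float = 0.2
    label_noise: float = 0.05
    rest_sd: float = 0.0
    population_seed: int = 0

    def __post_init__(self):
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        if self.label_noise < 0:
            raise ValueError("label_noise must be >= 0")
        for name in ("baseline_logvar_sd", "gain_population_scale",
                     "gain_individual_sd", "affect_gain_sd",
                     "affect_offset_sd", "rest_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def population_gain(self, n_bands: int = 5) -> np.ndarray:
        rng = np.random.default_rng(self.population_seed)
        return rng.normal(
            0.0, self.gain_population_scale,
            size=(n_bands, self.n_channels, 2),
        )


@dataclass(frozen=True)
class ParticipantModel:
    """One synthetic participant: emotion -> EEG mapping plus report noise."""

    participant_id: str
    gain: np.ndarray            # (bands, channels, 2) log-variance gains
    baseline_logvar: np.ndarray  # (bands, channels)
    affect_gain: np.ndarray     # (2,) per-axis input -> felt gain
    affect_offset: np.ndarray   # (2,) per-axis input -> felt offset
    rest_emotion: np.ndarray    # (2,) felt emotion in silence
    noise_scale: float
    label_noise: float
    seed: int

    def __post_init__(self):
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0")
        if self.label_noise < 0:
            raise ValueError("label_noise must be >= 0")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain matrices must be finite")

    @property
    def n_channels(self) -> int:
        return self.gain.shape[1]


def sample_participant(
    prior: PopulationPrior, seed: int, participant_id: str | None = None
) -> ParticipantModel:
    """Draw one participant from the population prior; deterministic in seed."""
    rng = np.random.default_rng(seed)
    shared = prior.population_gain()
    gain = shared + rng.normal(0.0, prior.gain_individual_sd, size=shared.shape)
    baseline = rng.normal(
        prior.baseline_logvar_mean, prior.baseline_logvar_sd,
        size=(shared.shape[0], prior.n_channels),
    )
    affect_gain = rng.normal(prior.affect_gain_mean, prior.affect_gain_sd, size=2)
    affect_offset = rng.normal(0.0, prior.affect_offset_sd, size=2)
    rest = np.clip(0.5 + rng.normal(0.0, prior.rest_sd, size=2), 0.0, 1.0)
    return ParticipantModel(
        participant_id=participant_id or f"sub-{seed}",
        gain=gain,
        baseline_logvar=baseline,
        affect_gain=affect_gain,
        affect_offset=affect_offset,
        rest_emotion=rest,
        noise_scale=prior.noise_scale,
        label_noise=prior.label_noise,
        seed=int(seed),
    )


def felt_emotion(p: ParticipantModel, gen_input: EmotionPoint) -> np.ndarray:
    """Affine per-axis distortion of the generator input, clipped to [0,1]."""
    g = gen_input.as_array()
    return np.clip(0.5 + p.affect_gain * (g - 0.5) + p.affect_offset, 0.0, 1.0)


def quantize_sam(x: np.ndarray) -> np.ndarray:
    """Round to the nearest of the 9 SAM levels {0, 0.125, ..., 1}.

    Ties round half up, matching ordinary manual rounding of a slider.
    """
    return np.clip(np.floor(np.asarray(x) * 8.0 + 0.5) / 8.0, 0.0, 1.0)


# ---------------------------------------------------------------------
# trials


@dataclass
class TrialRecord:
    """One stimulus presentation: silence, listening, label."""

    eeg: np.ndarray            # (channels, samples)
    fs: float
    pre_listen_duration: float
    listen_duration: float
    generator_input: EmotionPoint
    sam_label: EmotionPoint
    markers: dict = field(default_factory=dict)  # sample indices
    channels: list = field(default_factory=list)  # channel labels

    def __post_init__(self):
        expected = int(round(self.fs * (self.pre_listen_duration + self.listen_duration)))
        if self.eeg.shape[1] != expected:
            raise ValueError(
                f"eeg has {self.eeg.shape[1]} samples, expected {expected}"
            )


@dataclass
class TaskDataset:
    """One participant's trials, treated as one meta-learning task."""

    participant: ParticipantModel
    trials: list

    def __post_init__(self):
        if self.trials:
            fs0 = self.trials[0].fs
            ch0 = tuple(self.trials[0].channels)
            for t in self.trials:
                if t.fs != fs0 or tuple(t.channels) != ch0:
                    raise ValueError("all trials must share fs and montage")

    def stimuli(self) -> list[EmotionPoint]:
        return [t.generator_input for t in self.trials]


def _band_noise(rng, n_samples, n_channels, band, fs):
    """Unit-variance band-limited Gaussian noise, per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    shaped = _feat.bandpass(white, fs, band)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _check_fs(fs: float):
    gamma_high = _feat.BANDS[-1].high
    if fs / 2.0 <= gamma_high:
        raise ValueError(
            f"fs={fs} cannot represent the gamma band (needs Nyquist > {gamma_high} Hz)"
        )


def generate_trial(
    p: ParticipantModel,
    gen_input: EmotionPoint,
    fs: float = 100.0,
    seed: int = 0,
    pre_listen_duration: float = 5.0,
    listen_duration: float = 20.0,
    channels: list | None = None,
) -> TrialRecord:
    """Simulate one trial: 5 s silence + 20 s listening, plus a SAM label."""
    _check_fs(fs)
    rng = np.random.default_rng(seed)
    felt = felt_emotion(p, gen_input)
    label = quantize_sam(
        np.clip(felt + p.label_noise * rng.standard_normal(2), 0.0, 1.0)
    )

    n_pre = int(round(fs * pre_listen_duration))
    n_lis = int(round(fs * listen_duration))
    n_ch = p.n_channels
    # independent per-period noise: a draw shared by both periods would be
    # removed exactly by the downstream baseline correction
    noise_pre = rng.normal(0.0, p.noise_scale, size=(len(_feat.BANDS), n_ch))
    noise_lis = rng.normal(0.0, p.noise_scale, size=(len(_feat.BANDS), n_ch))

    lv_pre = (
        p.baseline_logvar
        + p.gain @ (p.rest_emotion - 0.5)
        + noise_pre
    )
    lv_lis = p.baseline_logvar + p.gain @ (felt - 0.5) + noise_lis

    eeg = np.zeros((n_ch, n_pre + n_lis))
    for b, band in enumerate(_feat.BANDS):
        pre = _band_noise(rng, n_pre, n_ch, band, fs)
        lis = _band_noise(rng, n_lis, n_ch, band, fs)
        eeg[:, :n_pre] += pre * np.exp(lv_pre[b, :, None] / 2.0)
        eeg[:, n_pre:] += lis * np.exp(lv_lis[b, :, None] / 2.0)

    if channels is None:
        default_map = _feat.default_channel_map()
        if n_ch == default_map.n_channels:
            channels = list(default_map.selected_channels)
        else:
            channels = [f"ch{i}" for i in range(n_ch)]
    return TrialRecord(
        eeg=eeg,
        fs=fs,
        pre_listen_duration=pre_listen_duration,
        listen_duration=listen_duration,
        generator_input=gen_input,
        sam_label=EmotionPoint.from_array(label),
        markers={"silence_onset": 0, "music_onset": n_pre},
        channels=list(channels),
    )


def simulate_window(
    p: ParticipantModel,
    felt: np.ndarray,
    fs: float,
    rng: np.random.Generator,
    noise: np.ndarray | None = None,
    duration: float = 1.0,
) -> np.ndarray:
    """One EEG window (channels x samples) at a given felt emotion.

    Used by the closed-loop session runner, where the felt emotion tracks
    the evolving music rather than a fixed stimulus.  ``noise`` is the
    per-session band/channel log-variance offset (analogue of the
    per-trial noise); pass the same array for every window of a session
    so that baseline correction removes it.
    """
    _check_fs(fs)
    n = int(round(fs * duration))
    n_ch = p.n_channels
    if noise is None:
        noise = np.zeros((len(_feat.BANDS), n_ch))
    lv = p.baseline_logvar + p.gain @ (np.asarray(felt) - 0.5) + noise
    out = np.zeros((n_ch, n))
    for b, band in enumerate(_feat.BANDS):
        out += _band_noise(rng, n, n_ch, band, fs) * np.exp(lv[b, :, None] / 2.0)
    return out


def build_cohort(
    n_participants: int,
    grid: str = "full41",
    fs: float = 100.0,
    seed: int = 0,
    prior: PopulationPrior | None = None,
    channels: list | None = None,
) -> list[TaskDataset]:
    """A reproducible cohort: one TaskDataset per participant, one trial
    per stimulus in the named grid."""
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    prior = prior or PopulationPrior()
    stimuli = stimulus_grid(grid)
    ss = np.random.SeedSequence(seed)
    part_seeds = ss.generate_state(n_participants)
    tasks = []
    for i in range(n_participants):
        p = sample_participant(prior, int(part_seeds[i]), participant_id=f"sub-{i:02d}")
        trial_ss = np.random.SeedSequence([seed, i, 7919])
        trial_seeds = trial_ss.generate_state(len(stimuli))
        trials = [
            generate_trial(p, stim, fs=fs, seed=int(trial_seeds[j]), channels=channels)
            for j, stim in enumerate(stimuli)
        ]
        tasks.append(TaskDataset(participant=p, trials=trials))
    return tasks
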