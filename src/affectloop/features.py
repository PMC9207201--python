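"""EEG band-power log-variance features on a scalp-topographic grid.

Pipeline for one trial (5 s silence + 20 s listening):

1. keep the last 3 pre-listening seconds and the 20 listening seconds,
   cut into 23 non-overlapping 1-s windows;
2. band-pass each window into theta (4-7), alpha (8-13), low beta
   (14-21), high beta (22-29) and gamma (30-45 Hz);
3. feature = natural log of the variance of each filtered window, per
   channel and band (14 channels x 5 bands = 70 dimensions);
4. baseline-correct the 20 listening windows by subtracting the mean of
   the 3 pre-listening windows;
5. map each 70-vector into a 6 x 6 x 5 tensor using the electrode
   positions; grid cells without an electrode stay exactly zero.

Filters are 4th-order Butterworth band-passes applied forward-backward
(zero phase).  Zero-variance windows are floored at log(1e-12) rather
than producing -inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "BandDefinition", "BANDS", "ChannelMap", "default_channel_map",
    "bandpass", "segment", "logvar_features", "baseline_correct",
    "to_grid", "from_grid", "trial_features", "trial_feature_tensors",
    "batch_trial_feature_tensors", "GridFeaturizer", "GRID_SIZE", "N_PRE_WINDOWS", "N_LISTEN_WINDOWS",
    "LOGVAR_FLOOR_EPS",
]

GRID_SIZE = 6
N_PRE_WINDOWS = 3
N_LISTEN_WINDOWS = 20
LOGVAR_FLOOR_EPS = 1e-12


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")


BANDS = (
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("low_beta", 14.0, 21.0),
    BandDefinition("high_beta", 22.0, 29.0),
    BandDefinition("gamma", 30.0, 45.0),
)


# ---------------------------------------------------------------------
# channel map

# Stand-in 14-channel subset of the Quick-30 montage covering frontal,
# central, parietal and occipital sites, with a scalp-topographic layout
# on the 6x6 grid (row 0 = front).  Edit or supply a mapping file to
# match a concrete montage.
_DEFAULT_MAP = """\
F7,1,0
F3,1,1
Fz,1,2
F4,1,4
F8,1,5
C3,2,1
Cz,2,2
C4,2,4
P7,3,0
P3,3,1
Pz,3,2
P4,3,4
O1,4,2
O2,4,3
"""


@dataclass(frozen=True)
class ChannelMap:
    """Ordered channel selection plus grid coordinates for each channel."""

    selected_channels: tuple
    grid_position: dict  # label -> (row, col)

    def __post_init__(self):
        seen = set()
        for ch in self.selected_channels:
            pos = self.grid_position.get(ch)
            if pos is None:
                raise ValueError(f"channel {ch!r} has no grid position")
            r, c = pos
            if not (0 <= r < GRID_SIZE and 0 <= c < GRID_SIZE):
                raise ValueError(f"position {pos} for {ch!r} outside the grid")
            if pos in seen:
                raise ValueError(f"duplicate grid position {pos}")
            seen.add(pos)

    @property
    def n_channels(self) -> int:
        return len(self.selected_channels)

    @staticmethod
    def from_text(text: str) -> "ChannelMap":
        """Parse a plain-text ``channel,row,col`` table (0-based)."""
        channels, positions = [], {}
        for line in text.strip().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ch, r, c = (s.strip() for s in line.split(","))
            channels.append(ch)
            positions[ch] = (int(r), int(c))
        return ChannelMap(tuple(channels), positions)

    @staticmethod
    def from_file(path) -> "ChannelMap":
        with open(path) as fh:
            return ChannelMap.from_text(fh.read())

    def to_file(self, path):
        with open(path, "w") as fh:
            for ch in self.selected_channels:
                r, c = self.grid_position[ch]
                fh.write(f"{ch},{r},{c}\n")


def default_channel_map() -> ChannelMap:
    return ChannelMap.from_text(_DEFAULT_MAP)


# ---------------------------------------------------------------------
# signal operations


def _sos(fs: float, band: BandDefinition):
    if fs / 2.0 <= band.high:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) violates Nyquist at fs={fs}"
        )
    return signal.butter(
        4, [band.low, band.high], btype="bandpass", fs=fs, output="sos"
    )


_SOS_CACHE: dict = {}


def bandpass(x: np.ndarray, fs: float, band: BandDefinition) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    key = (fs, band)
    sos = _SOS_CACHE.get(key)
    if sos is None:
        sos = _SOS_CACHE[key] = _sos(fs, band)
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def segment(trial) -> np.ndarray:
    """Cut a trial into 23 one-second windows (3 baseline + 20 listening).

    Returns an array (23, channels, fs) where windows 0-2 are the last
    three pre-listening seconds and window 3 starts exactly at music
    onset.
    """
    fs = int(round(trial.fs))
    onset = trial.markers.get("music_onset", int(round(trial.fs * trial.pre_listen_duration)))
    need_pre = N_PRE_WINDOWS * fs
    need_lis = N_LISTEN_WINDOWS * fs
    if onset < need_pre:
        raise ValueError("trial has fewer than 3 s of pre-listening data")
    if trial.eeg.shape[1] - onset < need_lis:
        raise ValueError("trial has fewer than 20 s of listening data")
    start = onset - need_pre
    block = trial.eeg[:, start: onset + need_lis]
    n_win = N_PRE_WINDOWS + N_LISTEN_WINDOWS
    return np.stack(
        [block[:, i * fs: (i + 1) * fs] for i in range(n_win)], axis=0
    )


def logvar_features(
    windows: np.ndarray,
    fs: float,
    channel_labels,
    channel_map: ChannelMap | None = None,
    bands=BANDS,
) -> np.ndarray:
    """Per-window log band-power features, (n_windows, channels x bands).

    Column order is channel-major, band-minor: for each selected channel
    (in map order), the five band features in the order of ``bands``.
    """
    channel_map = channel_map or default_channel_map()
    labels = list(channel_labels)
    try:
        idx = [labels.index(ch) for ch in channel_map.selected_channels]
    except ValueError as e:
        raise ValueError(f"channel missing from recording: {e}") from None
    sel = windows[:, idx, :]                       # (n_win, n_sel, fs)
    n_win, n_sel, _ = sel.shape
    out = np.empty((n_win, n_sel, len(bands)))
    for b, band in enumerate(bands):
        filt = bandpass(sel, fs, band)
        out[:, :, b] = np.log(np.maximum(filt.var(axis=-1), LOGVAR_FLOOR_EPS))
    return out.reshape(n_win, n_sel * len(bands))


def baseline_correct(feats: np.ndarray) -> np.ndarray:
    """Subtract the mean of the 3 pre-listening rows from the 20 listening rows."""
    feats = np.asarray(feats)
    if feats.shape[0] != N_PRE_WINDOWS + N_LISTEN_WINDOWS:
        raise ValueError(
            f"expected {N_PRE_WINDOWS + N_LISTEN_WINDOWS} rows, got {feats.shape[0]}"
        )
    baseline = feats[:N_PRE_WINDOWS].mean(axis=0)
    return feats[N_PRE_WINDOWS:] - baseline


def to_grid(feature_row: np.ndarray, channel_map: ChannelMap | None = None,
            n_bands: int = len(BANDS)) -> np.ndarray:
    """Map a (channels x bands) feature vector into the 6x6xbands tensor.

    Cells without an electrode are exactly zero.
    """
    channel_map = channel_map or default_channel_map()
    row = np.asarray(feature_row).reshape(channel_map.n_channels, n_bands)
    grid = np.zeros((GRID_SIZE, GRID_SIZE, n_bands))
    for i, ch in enumerate(channel_map.selected_channels):
        r, c = channel_map.grid_position[ch]
        grid[r, c, :] = row[i]
    return grid


def from_grid(grid: np.ndarray, channel_map: ChannelMap | None = None) -> np.ndarray:
    """Inverse of :func:`to_grid` on the mapped cells."""
    channel_map = channel_map or default_channel_map()
    rows = [
        grid[channel_map.grid_position[ch][0], channel_map.grid_position[ch][1], :]
        for ch in channel_map.selected_channels
    ]
    return np.concatenate(rows)


def trial_features(trial, channel_map: ChannelMap | None = None) -> np.ndarray:
    """Full pipeline to the 20 x 70 baseline-corrected feature matrix."""
    channel_map = channel_map or default_channel_map()
    windows = segment(trial)
    feats = logvar_features(windows, trial.fs, trial.channels, channel_map)
    return baseline_correct(feats)


def trial_feature_tensors(trial, channel_map: ChannelMap | None = None) -> np.ndarray:
    """Full pipeline to the (20, 6, 6, 5) stack of grid tensors."""
    channel_map = channel_map or default_channel_map()
    corrected = trial_features(trial, channel_map)
    return np.stack([to_grid(r, channel_map) for r in corrected], axis=0)


def batch_trial_feature_tensors(trials, channel_map: ChannelMap | None = None) -> np.ndarray:
    """Feature pipeline over many trials at once, (n_trials, 20, 6, 6, 5).

    Numerically identical to stacking :func:`trial_feature_tensors` per
    trial (the band-pass runs along the time axis of each window), but
    filters all windows of all trials in one call per band.
    """
    channel_map = channel_map or default_channel_map()
    if not trials:
        raise ValueError("no trials to featurize")
    windows = np.concatenate([segment(t) for t in trials], axis=0)
    n_win = N_PRE_WINDOWS + N_LISTEN_WINDOWS
    feats = logvar_features(windows, trials[0].fs, trials[0].channels, channel_map)
    feats = feats.reshape(len(trials), n_win, -1)
    corrected = feats[:, N_PRE_WINDOWS:] - feats[:, :N_PRE_WINDOWS].mean(axis=1, keepdims=True)
    n_bands = len(BANDS)
    rows = corrected.reshape(len(trials), N_LISTEN_WINDOWS, channel_map.n_channels, n_bands)
    grids = np.zeros((len(trials), N_LISTEN_WINDOWS, GRID_SIZE, GRID_SIZE, n_bands))
    for i, ch in enumerate(channel_map.selected_channels):
        r, c = channel_map.grid_position[ch]
        grids[:, :, r, c, :] = rows[:, :, i, :]
    return grids


class GridFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from trials to stacked grid feature tensors.

    ``transform`` takes a sequence of trials and returns an array
    (n_trials, 20, 6, 6, 5); it is stateless, so ``fit`` is a no-op.
    """

    def __init__(self, channel_map: ChannelMap | None = None):
        self.channel_map = channel_map

    def fit(self, X, y=None):
        return self

    def transform(self, trials):
        cm = self.channel_map or default_channel_map()
        return batch_trial_feature_tensors(list(trials), cm)
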