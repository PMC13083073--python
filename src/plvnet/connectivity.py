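"""Complex Morlet decomposition, instantaneous phase, and phase-locking value.

The bank holds 30 log-spaced center frequencies per band with a fixed width
of three cycles: sigma_t = cycles/(2 pi f) seconds, sigma_f = f/cycles Hz.
Kernels are Gabor-normalized (unit L2 norm) and truncated at +/-4 sigma_t.
The phase-locking value for a channel pair is the magnitude of the
trial-averaged unit phasor of the instantaneous phase difference,

    PLV(f, t) = | (1/N) sum_trials exp(j (phi_y - phi_x)) |,

averaged over all frequency bins and the post-stimulus window (0-600 ms for
delta, 0-300 ms for theta) with no baseline normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len

from .config import BANDS, PLV_WINDOWS_MS
from .epochs import EpochArray
from .pairs import PairSet

__all__ = [
    "WaveletBank", "TFPhase", "build_bank", "transform", "plv",
    "window_average", "pair_plv_table", "plv_matrix", "aggregate",
]


@dataclass
class WaveletBank:
    center_freqs: np.ndarray   # Hz, strictly increasing
    cycles: float
    fs: float
    kernels: list[np.ndarray]  # complex, odd length, unit L2 norm

    @property
    def sigma_t(self) -> np.ndarray:
        """Temporal standard deviation per center frequency, seconds."""
        return self.cycles / (2 * np.pi * self.center_freqs)

    @property
    def sigma_f(self) -> np.ndarray:
        """Spectral standard deviation per center frequency, Hz."""
        return self.center_freqs / self.cycles


def build_bank(band: tuple[float, float], n_bins: int = 30, cycles: float = 3.0,
               fs: float = 256.0) -> WaveletBank:
    lo, hi = band
    if not 0 < lo < hi:
        raise ValueError("band edges must satisfy 0 < lo < hi")
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz at/above Nyquist for fs={fs}")
    freqs = np.logspace(np.log10(lo), np.log10(hi), n_bins)
    kernels = []
    for f in freqs:
        sig_t = cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sig_t * fs))
        t = np.arange(-half, half + 1) / fs
        k = np.exp(2j * np.pi * f * t) * np.exp(-(t ** 2) / (2 * sig_t ** 2))
        kernels.append(k / np.linalg.norm(k))
    return WaveletBank(center_freqs=freqs, cycles=cycles, fs=fs, kernels=kernels)


@dataclass
class TFPhase:
    phase: np.ndarray        # (trial, channel, freq, time), wrapped to (-pi, pi]
    freqs: np.ndarray
    fs: float
    onset_index: int
    channel_labels: list[str]
    valid: np.ndarray        # (freq, time) bool; False within 2 sigma_t of the edges
    amplitude: np.ndarray | None = None

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


def transform(epochs: EpochArray, bank: WaveletBank, *,
              channels: list[str] | None = None,
              keep_amplitude: bool = False) -> TFPhase:
    """Convolve every trial/channel with every wavelet and take the argument.

    Convolution runs in the frequency domain with "same" alignment. Samples
    within 2 sigma_t of either epoch border are flagged invalid per frequency.
    """
    labels = channels if channels is not None else list(epochs.channel_labels)
    idx = [epochs.channel_index(l) for l in labels]
    data = epochs.data[:, idx, :]
    n_trials, n_ch, n_samp = data.shape
    max_len = max(len(k) for k in bank.kernels)
    if n_samp < max_len:
        raise ValueError(
            f"epoch of {n_samp} samples shorter than the lowest-frequency kernel ({max_len})"
        )
    nfft = next_fast_len(n_samp + max_len - 1)
    # single precision: phase error ~1e-6 rad, far below any quantity of interest
    spec = fft(data.astype(np.float32), nfft, axis=-1)
    n_freq = len(bank.center_freqs)
    out = np.empty((n_trials, n_ch, n_freq, n_samp), dtype=np.complex64)
    for fi, kernel in enumerate(bank.kernels):
        half = (len(kernel) - 1) // 2
        kspec = fft(kernel.astype(np.complex64), nfft)
        conv = ifft(spec * kspec, axis=-1)
        out[:, :, fi, :] = conv[..., half:half + n_samp]
    valid = np.ones((n_freq, n_samp), dtype=bool)
    for fi, sig_t in enumerate(bank.sigma_t):
        margin = int(np.ceil(2 * sig_t * bank.fs))
        valid[fi, :margin] = False
        if margin > 0:
            valid[fi, n_samp - margin:] = False
    return TFPhase(
        phase=np.angle(out), freqs=bank.center_freqs, fs=bank.fs,
        onset_index=epochs.onset_index, channel_labels=list(labels), valid=valid,
        amplitude=np.abs(out) if keep_amplitude else None,
    )


def plv(phase: TFPhase, pair: tuple[str, str]) -> np.ndarray:
    """freq x time PLV matrix for one channel pair."""
    i = phase.channel_index(pair[0])
    j = phase.channel_index(pair[1])
    diff = phase.phase[:, j] - phase.phase[:, i]
    return np.abs(np.mean(np.exp(1j * diff), axis=0))


def window_average(plv_map: np.ndarray, band_context: str, fs: float,
                   onset_index: int, valid: np.ndarray | None = None) -> float:
    """Mean PLV over all frequency bins and the post-stimulus window.

    The window is half-open, ``round(W * fs)`` samples from stimulus onset
    (154 samples for the 600 ms delta window at 256 Hz). Raises if any
    windowed sample is edge-invalid at any frequency.
    """
    w_lo, w_hi = PLV_WINDOWS_MS[band_context]
    start = onset_index + int(round(w_lo / 1000 * fs))
    n_w = int(round((w_hi - w_lo) / 1000 * fs))
    stop = start + n_w
    if start < 0 or stop > plv_map.shape[-1]:
        raise ValueError("averaging window exceeds the epoch")
    if valid is not None and not np.all(valid[:, start:stop]):
        raise ValueError("averaging window overlaps the edge-invalid region")
    return float(np.mean(plv_map[:, start:stop]))


def pair_plv_table(
    epochs: EpochArray,
    bank: WaveletBank,
    pairset: PairSet,
    band: str,
) -> pd.DataFrame:
    """Tidy per-pair PLV rows for one subject/condition/band.

    Columns: subject, group, condition, band, pair, category, plv, n_trials.
    """
    tf = transform(epochs, bank, channels=pairset.electrodes())
    phasor = np.exp(1j * tf.phase.astype(np.float32))
    rows = []
    for (a, b), name, cat in zip(pairset.pairs, pairset.names, pairset.category):
        i, j = tf.channel_index(a), tf.channel_index(b)
        plv_map = np.abs(np.mean(phasor[:, j] * np.conj(phasor[:, i]), axis=0))
        value = window_average(plv_map, band, tf.fs, tf.onset_index, tf.valid)
        rows.append(
            {"subject": epochs.subject_id, "group": epochs.group,
             "condition": epochs.condition, "band": band, "pair": name,
             "category": cat, "plv": value, "n_trials": epochs.n_trials}
        )
    return pd.DataFrame(rows)


def plv_matrix(epochs: EpochArray, bank: WaveletBank, band: str,
               channels: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Symmetric window-averaged PLV matrix over a channel set (network input)."""
    tf = transform(epochs, bank, channels=channels)
    labels = tf.channel_labels
    n = len(labels)
    out = np.zeros((n, n))
    phasor = np.exp(1j * tf.phase)
    for i in range(n):
        for j in range(i + 1, n):
            m = np.abs(np.mean(phasor[:, j] * np.conj(phasor[:, i]), axis=0))
            out[i, j] = out[j, i] = window_average(m, band, tf.fs, tf.onset_index, tf.valid)
    return out, labels


def aggregate(table: pd.DataFrame, pairset: PairSet,
              predictor_pairs: list[str] | None = None,
              predictor_condition: str = "target",
              weights: dict[str, float] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hemisphere-level and subject-level aggregates of a pair PLV table.

    Hemisphere level: per subject/band/condition, the arithmetic mean over
    pairs of each category. Subject level: the "weighted average coherence"
    predictor — by default the unweighted mean over all pairs, target
    condition only; an optional per-pair weight vector is supported.
    """
    expected = set(pairset.names)
    for key, sub in table.groupby(["subject", "band", "condition"]):
        missing = expected - set(sub["pair"])
        if missing:
            raise ValueError(f"missing pair rows for {key}: {sorted(missing)[:3]}...")
    hemi = (
        table.groupby(["subject", "group", "band", "condition", "category"], as_index=False)
        ["plv"].mean().rename(columns={"plv": "plv_mean"})
    )
    sel = table[table["condition"] == predictor_condition]
    if predictor_pairs is not None:
        sel = sel[sel["pair"].isin(predictor_pairs)]
    if weights:
        sel = sel.assign(_w=sel["pair"].map(weights).astype(float))
        subj = (
            sel.groupby(["subject", "group", "band"])
            .apply(lambda d: np.average(d["plv"], weights=d["_w"]), include_groups=False)
            .rename("coherence").reset_index()
        )
    else:
        subj = (
            sel.groupby(["subject", "group", "band"], as_index=False)["plv"]
            .mean().rename(columns={"plv": "coherence"})
        )
    return hemi, subj
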