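"""Filtering, resampling, epoch segmentation, amplitude-based trial
rejection, spherical-spline current source density, and IQR outlier
exclusion.

The CSD transform is the Perrin-style spherical-spline surface Laplacian.
With electrode cosine distances x = cos(theta_ij), the spline kernel is

    g(x) = (1/4pi) * sum_{n=1..N} (2n+1) / (n(n+1))^m * P_n(x)

and the Laplacian kernel h(x) uses exponent m-1 in the denominator. The
spline coefficients c solve the ridge-regularized interpolation system with
a zero-sum constraint; the CSD at each electrode is H @ c. The sphere is
dimensionless (unit radius): values are in uV/m^2 up to a fixed head-radius
scale factor of 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numpy.polynomial import legendre
from scipy import signal

from .epochs import EpochArray, context_n_samples, CONTEXT_WINDOWS
from .montage import Montage

log = logging.getLogger(__name__)

__all__ = [
    "FilterSpec", "OutlierFilterResult", "bandpass", "resample", "segment",
    "reject_amplitude", "csd", "csd_matrices", "iqr_exclude",
]


@dataclass
class FilterSpec:
    highpass: float = 0.01
    lowpass: float = 60.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.highpass < self.lowpass:
            raise ValueError("need 0 < highpass < lowpass")
        if self.lowpass >= fs / 2:
            raise ValueError(f"lowpass {self.lowpass} Hz is at/above Nyquist for fs={fs}")


def bandpass(data: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per channel (last axis = time)."""
    spec = spec or FilterSpec()
    spec.validate(fs)
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("non-finite samples in input")
    # separate high- and low-pass cascades: a joint band-pass design is
    # numerically ill-conditioned with a 0.01 Hz lower edge
    sos = np.vstack([
        signal.butter(spec.order, spec.highpass, btype="highpass", fs=fs, output="sos"),
        signal.butter(spec.order, spec.lowpass, btype="lowpass", fs=fs, output="sos"),
    ])
    if spec.zero_phase:
        # generous padding; note the 0.01 Hz high-pass still has an ~16 s
        # time constant, so edge transients are physical — callers analyse
        # records much longer than that (the epoching windows cut interior
        # segments anyway)
        padlen = min(data.shape[-1] - 1, int(10 * fs))
        return signal.sosfiltfilt(sos, data, axis=-1, padlen=padlen)
    return signal.sosfilt(sos, data, axis=-1)


def resample(data: np.ndarray, fs_in: float, fs_out: float = 256.0,
             allow_upsample: bool = False) -> np.ndarray:
    """Anti-aliased polyphase resampling along the last axis."""
    if fs_out > fs_in and not allow_upsample:
        raise ValueError(f"upsampling {fs_in} -> {fs_out} Hz not allowed")
    if fs_out == fs_in:
        return np.asarray(data, dtype=float)
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return signal.resample_poly(np.asarray(data, dtype=float), frac.numerator,
                                frac.denominator, axis=-1)


def segment(
    continuous: np.ndarray,
    onsets: np.ndarray,
    band_context: str,
    *,
    fs: float,
    channel_labels: list[str],
    subject_id: str = "",
    group: str = "HC",
    condition: str = "target",
) -> EpochArray:
    """Cut half-open windows around stimulus onsets into an EpochArray.

    Delta context uses [-3, +3) s, theta [-1, +1) s. Onsets whose window
    exceeds the record bounds are dropped with a logged warning.
    """
    continuous = np.atleast_2d(np.asarray(continuous, dtype=float))
    onsets = np.sort(np.asarray(onsets, dtype=int))
    pre_s, _ = CONTEXT_WINDOWS[band_context]
    n_samp = context_n_samples(band_context, fs)
    pre = int(round(-pre_s * fs))
    n_total = continuous.shape[-1]
    trials, dropped = [], 0
    for onset in onsets:
        start = onset - pre
        if start < 0 or start + n_samp > n_total:
            dropped += 1
            continue
        trials.append(continuous[:, start:start + n_samp])
    if dropped:
        log.warning("segment: dropped %d/%d events with out-of-bounds windows",
                    dropped, len(onsets))
    if not trials:
        raise ValueError("no events with a complete window inside the record")
    return EpochArray(
        subject_id=subject_id, group=group, condition=condition,
        band_context=band_context, fs=fs, data=np.stack(trials),
        onset_index=pre, channel_labels=list(channel_labels),
    )


def reject_amplitude(epochs: EpochArray, threshold: float) -> EpochArray:
    """Drop trials containing any sample with \\|amplitude\\| above threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = np.max(np.abs(epochs.data), axis=(1, 2)) <= threshold
    n_removed = int((~keep).sum())
    if n_removed:
        log.info("reject_amplitude: removed %d/%d trials (> %g)",
                 n_removed, epochs.n_trials, threshold)
    if not keep.any():
        raise ValueError("all trials removed by amplitude rejection")
    return epochs.with_data(epochs.data[keep])


def _legendre_kernel(x: np.ndarray, n_leg: int, exponent: int) -> np.ndarray:
    n = np.arange(1, n_leg + 1, dtype=float)
    coefs = np.zeros(n_leg + 1)
    coefs[1:] = (2 * n + 1) / (n * (n + 1)) ** exponent
    return legendre.legval(x, coefs) / (4 * np.pi)


def csd_matrices(montage: Montage, m: int = 4, n_leg: int = 10,
                 lam: float = 1e-5) -> tuple[np.ndarray, np.ndarray]:
    """Spline matrix G and Laplacian matrix H for a montage."""
    x = montage.cosine_angles()
    g = _legendre_kernel(x, n_leg, m)
    h = _legendre_kernel(x, n_leg, m - 1)
    return g, h


def csd(epochs: EpochArray, montage: Montage, m: int = 4, n_leg: int = 10,
        lam: float = 1e-5) -> EpochArray:
    """Spherical-spline surface Laplacian of every trial and sample.

    Solves, per time sample, the constrained ridge system

        [G + lam*I  1] [c ]   [v]
        [1^T        0] [c0] = [0]

    and returns H @ c in place of the voltages. A spatially uniform map
    (and any added constant) lands entirely in c0 and maps to zero output.
    """
    if len(montage) < 4:
        raise ValueError("CSD needs at least 4 electrodes with positions")
    sub = montage.subset(epochs.channel_labels)
    g, h = csd_matrices(sub, m=m, n_leg=n_leg, lam=lam)
    n = len(sub)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = g + lam * np.eye(n)
    aug[:n, n] = 1.0
    aug[n, :n] = 1.0
    n_tr, _, n_samp = epochs.data.shape
    v = epochs.data.transpose(1, 0, 2).reshape(n, n_tr * n_samp)
    rhs = np.vstack([v, np.zeros((1, v.shape[1]))])
    try:
        sol = np.linalg.solve(aug, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular CSD spline system: {exc}") from exc
    out = (h @ sol[:n]).reshape(n, n_tr, n_samp).transpose(1, 0, 2)
    return epochs.with_data(out)


@dataclass
class OutlierFilterResult:
    kept: list[int]
    excluded: list[int]
    q1: float
    q3: float
    iqr: float
    fences: tuple[float, float] = field(default=(0.0, 0.0))


def iqr_exclude(values) -> OutlierFilterResult:
    """Exclude values strictly beyond Q1 - 3*IQR or Q3 + 3*IQR.

    Quartiles use the linear-interpolation convention; values exactly on a
    fence are retained (exclusion is strict "beyond").
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 4 or not np.all(np.isfinite(values)):
        raise ValueError("need at least 4 finite values in a 1-d array")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3 * iqr, q3 + 3 * iqr
    keep = (values >= lo) & (values <= hi)
    return OutlierFilterResult(
        kept=list(np.flatnonzero(keep)),
        excluded=list(np.flatnonzero(~keep)),
        q1=float(q1), q3=float(q3), iqr=float(iqr), fences=(float(lo), float(hi)),
    )
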