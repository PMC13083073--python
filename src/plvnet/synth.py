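"""Synthetic oddball-EEG cohorts with known inter-channel phase coupling.

Each trial is 1/f background noise plus a stimulus-locked oscillatory burst
(raised-cosine taper). Phase coupling is directional: designated driver
channels get independent uniform burst phases per trial, and each coupled
target channel receives a burst component whose phase equals its driver's
phase plus a fixed lag plus von Mises jitter of concentration kappa. The
trial-asymptotic PLV of a driver-target pair is therefore the Bessel ratio
I1(kappa)/I0(kappa) — a closed-form oracle for the whole connectivity stack.
A target listed with several drivers carries an equal-weight superposition
of driver-locked components.

Patient-like groups scale kappa down on the designated effect pairs only,
so group differences are confined to those pairs. Subject-level covariates
are linear in the model-implied mean coherence c = mean_a I1(k_a)/I0(k_a)
over the coupled assignments: mmse = a0 + a1*c + eps, error = b0 - b1*c + eps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import i0, i1

from .config import BANDS
from .epochs import CONTEXT_WINDOWS, EpochArray
from .montage import Montage, load_montage

__all__ = [
    "CouplingSpec", "CohortSpec", "generate_trial", "generate_cohort",
    "generate_stimulus_sequence", "draw_subjects", "null_coupling",
    "pink_noise", "bessel_plv",
    "DEFAULT_EFFECT_PAIRS", "DEFAULT_BASELINE_PAIRS", "DEFAULT_GROUP_MULTIPLIERS",
]

DEFAULT_EFFECT_PAIRS = [
    ("F3", "TP8"), ("F3", "P8"), ("F3", "O2"), ("F4", "T7"), ("F4", "P8"), ("F3", "T8"),
]
DEFAULT_BASELINE_PAIRS = [
    ("C3", "P3"), ("C4", "P4"), ("C3", "TP7"), ("C4", "P7"), ("C3", "O1"),
]
#: kappa multipliers on the effect pairs, per group (HC preserved, PDD most reduced)
DEFAULT_GROUP_MULTIPLIERS = {"HC": 1.0, "PD_MCI": 0.7, "PDD": 0.35, "DLB": 0.5}

#: default burst carrier and taper window per band context
_BAND_BURSTS = {"delta": (2.0, (0.0, 800.0)), "theta": (5.5, (0.0, 400.0))}


def bessel_plv(kappa: float) -> float:
    """Asymptotic PLV of a von Mises-jittered pair: I1(kappa)/I0(kappa)."""
    if kappa == 0:
        return 0.0
    return float(i1(kappa) / i0(kappa))


def pink_noise(shape: tuple[int, ...], exponent: float, rng: np.random.Generator,
               fs: float = 256.0) -> np.ndarray:
    """1/f^exponent background noise along the last axis, unit standard deviation."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2)
    spec = (rng.standard_normal(shape[:-1] + (len(freqs),))
            + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))) * scale
    out = np.fft.irfft(spec, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


@dataclass
class CouplingSpec:
    band: str = "theta"
    base_kappa: float = 2.5
    effect_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_EFFECT_PAIRS))
    group_multipliers: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_MULTIPLIERS))
    baseline_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_BASELINE_PAIRS))
    burst_freq: float | None = None        # Hz; defaults to the band's carrier
    burst_window_ms: tuple[float, float] | None = None
    snr_db: float = 10.0                   # burst-peak RMS over background RMS
    noise_exponent: float = 1.0            # 1/f spectral slope
    lag: float = np.pi / 4                 # fixed driver->target phase lag

    def __post_init__(self) -> None:
        if self.base_kappa < 0:
            raise ValueError("base_kappa must be >= 0")
        if any(m < 0 for m in self.group_multipliers.values()):
            raise ValueError("kappa multipliers must be >= 0")
        if self.burst_freq is None:
            self.burst_freq = _BAND_BURSTS[self.band][0]
        if self.burst_window_ms is None:
            self.burst_window_ms = _BAND_BURSTS[self.band][1]
        lo, hi = BANDS[self.band]
        if not lo <= self.burst_freq <= hi:
            raise ValueError(f"burst_freq {self.burst_freq} Hz outside the {self.band} band")

    def assignments(self, group: str = "HC",
                    subject_scale: float = 1.0) -> dict[str, list[tuple[str, float, float]]]:
        """Resolve per-target components: target -> [(driver, kappa, weight)]."""
        mult = self.group_multipliers.get(group, 1.0)
        raw: dict[str, list[tuple[str, float]]] = {}
        for src, dst in self.baseline_pairs:
            raw.setdefault(dst, []).append((src, self.base_kappa * subject_scale))
        for src, dst in self.effect_pairs:
            raw.setdefault(dst, []).append((src, self.base_kappa * mult * subject_scale))
        return {dst: [(src, k, 1.0 / len(comps)) for src, k in comps]
                for dst, comps in raw.items()}

    def model_coherence(self, group: str = "HC", subject_scale: float = 1.0) -> float:
        """Model-implied mean pair coherence over the coupled assignments."""
        kappas = [k for comps in self.assignments(group, subject_scale).values()
                  for _, k, _ in comps]
        return float(np.mean([bessel_plv(k) for k in kappas]))


def generate_trial(spec: CouplingSpec, montage: Montage, fs: float,
                   window: tuple[float, float], rng: np.random.Generator,
                   assignments: dict | None = None) -> np.ndarray:
    """One channel x sample trial: 1/f noise plus a phase-coupled burst."""
    t0, t1 = window
    n = int(round((t1 - t0) * fs))
    t = t0 + np.arange(n) / fs
    w0, w1 = (v / 1000 for v in spec.burst_window_ms)
    if w0 < t0 or w1 > t1:
        raise ValueError("burst window lies outside the epoch window")
    taper = np.zeros(n)
    inside = (t >= w0) & (t < w1)
    taper[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - w0) / (w1 - w0)))
    if assignments is None:
        assignments = spec.assignments()
    amp = np.sqrt(2.0) * 10 ** (spec.snr_db / 20)
    labels = montage.labels
    drivers = {src for comps in assignments.values() for src, _, _ in comps}
    base_phase = {
        lab: rng.uniform(-np.pi, np.pi)
        for lab in labels if lab in drivers or lab not in assignments
    }
    data = pink_noise((len(labels), n), spec.noise_exponent, rng, fs)
    omega = 2 * np.pi * spec.burst_freq
    for ci, lab in enumerate(labels):
        if lab in assignments:
            burst = np.zeros(n)
            for src, kappa, weight in assignments[lab]:
                if kappa < 0:
                    raise ValueError("kappa must be >= 0")
                jitter = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
                phi = base_phase[src] + spec.lag + jitter
                burst += weight * np.cos(omega * t + phi)
        else:
            burst = np.cos(omega * t + base_phase[lab])
        data[ci] += amp * taper * burst
    return data


@dataclass
class CohortSpec:
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HC": 24, "PD_MCI": 20, "PDD": 18, "DLB": 11})
    # retained artifact-free trial counts, mean +/- sd per group and condition
    trials_target: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "HC": (17.6, 2.9), "PD_MCI": (14.9, 1.8), "PDD": (15.1, 2.5), "DLB": (14.3, 2.3)})
    trials_nontarget: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "HC": (19.7, 3.2), "PD_MCI": (18.6, 2.8), "PDD": (16.5, 2.7), "DLB": (16.5, 2.6)})
    min_trials: int = 5
    age: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "HC": (61.3, 7.95), "PD_MCI": (67.5, 8.59), "PDD": (70.2, 7.41), "DLB": (70.3, 9.27)})
    # covariates linear in model coherence c
    mmse_intercept: float = 14.0   # a0
    mmse_slope: float = 20.0       # a1 >= 0
    mmse_sd: float = 1.5
    error_intercept: float = 12.0  # b0
    error_slope: float = 14.0      # b1 >= 0
    error_sd: float = 1.5
    kappa_subject_sd: float = 0.15  # lognormal sd of the per-subject coupling scale
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mmse_slope < 0 or self.error_slope < 0:
            raise ValueError("covariate slopes must be >= 0")
        if any(n < 2 for n in self.group_sizes.values()):
            raise ValueError("every group needs at least 2 subjects")


def _draw_trials(mean: float, sd: float, floor: int, rng: np.random.Generator) -> int:
    return max(floor, int(round(rng.normal(mean, sd))))


def draw_subjects(cohort: "CohortSpec", coupling: CouplingSpec,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Subject-level draws only (no EEG): coupling scale, model coherence,
    age, and the coherence-linked covariates."""
    rows = []
    for group, size in cohort.group_sizes.items():
        for si in range(size):
            scale = float(np.exp(rng.normal(0.0, cohort.kappa_subject_sd)))
            c = coupling.model_coherence(group, scale)
            rows.append({
                "subject_id": f"{group}{si + 1:02d}", "group": group,
                "kappa_scale": scale, "model_coherence": c,
                "age": float(rng.normal(*cohort.age[group])),
                "mmse": float(cohort.mmse_intercept + cohort.mmse_slope * c
                              + rng.normal(0, cohort.mmse_sd)),
                "error_score": float(cohort.error_intercept - cohort.error_slope * c
                                     + rng.normal(0, cohort.error_sd)),
            })
    return pd.DataFrame(rows)


def generate_cohort(
    cohort: CohortSpec,
    coupling: CouplingSpec,
    montage: Montage | None = None,
    conditions: tuple[str, ...] = ("target",),
    fs: float = 256.0,
) -> tuple[list[EpochArray], pd.DataFrame]:
    """Simulate every subject's epochs plus the covariate table.

    Fully reproducible from ``cohort.rng_seed``. Covariate columns:
    subject_id, group, age, mmse, error_score, model_coherence.
    """
    if coupling.effect_pairs == [] and any(
        m != 1.0 for m in coupling.group_multipliers.values()
    ):
        raise ValueError("group effect requested but effect_pairs is empty")
    montage = montage or load_montage("default30")
    rng = np.random.default_rng(cohort.rng_seed)
    window = CONTEXT_WINDOWS[coupling.band]
    trial_stats = {"target": cohort.trials_target, "nontarget": cohort.trials_nontarget}
    covariates = draw_subjects(cohort, coupling, rng)
    epoch_sets: list[EpochArray] = []
    for _, row in covariates.iterrows():
        assignments = coupling.assignments(row["group"], row["kappa_scale"])
        for condition in conditions:
            mean, sd = trial_stats[condition][row["group"]]
            n_trials = _draw_trials(mean, sd, cohort.min_trials, rng)
            trials = np.stack([
                generate_trial(coupling, montage, fs, window, rng, assignments)
                for _ in range(n_trials)
            ])
            epoch_sets.append(EpochArray(
                subject_id=row["subject_id"], group=row["group"], condition=condition,
                band_context=coupling.band, fs=fs, data=trials,
                onset_index=int(round(-window[0] * fs)),
                channel_labels=list(montage.labels),
            ))
    return epoch_sets, covariates.drop(columns=["kappa_scale"])


def generate_stimulus_sequence(
    n_total: int = 120, n_target: int = 40,
    isi_range: tuple[float, float] = (3.0, 7.0),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Randomized oddball event timeline: onset seconds and target/nontarget codes."""
    if n_target > n_total:
        raise ValueError("n_target cannot exceed n_total")
    if not 0 < isi_range[0] <= isi_range[1]:
        raise ValueError("invalid ISI range")
    rng = rng or np.random.default_rng()
    codes = np.array(["target"] * n_target + ["nontarget"] * (n_total - n_target))
    rng.shuffle(codes)
    isis = rng.uniform(isi_range[0], isi_range[1], size=n_total)
    onsets = np.cumsum(isis)
    return pd.DataFrame({"onset_s": onsets, "code": codes})


def null_coupling(coupling: CouplingSpec) -> CouplingSpec:
    """Same generator with all group effects switched off (multipliers = 1)."""
    return replace(coupling, group_multipliers={g: 1.0 for g in coupling.group_multipliers})
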