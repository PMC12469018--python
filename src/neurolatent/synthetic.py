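"""Synthetic cohorts with the statistical structure the framework assumes.

Two properties of real ICA time courses matter for this pipeline and are
planted explicitly:

* **Temporal asymmetry** — BOLD-like responses rise faster than they decay,
  so the direction of time is statistically identifiable and the
  time-reversal pretext task is learnable.  Each component time course is a
  sparse random event train convolved with an asymmetric rise/decay kernel
  plus Gaussian noise.
* **Network-level case/control differences** — designated functional
  networks carry planted amplitude/offset differences in patients, giving
  the probing stage a known ground truth.

A time-symmetric control corpus (stationary Gaussian, hence invariant in law
under time reversal) is provided as a negative control for the pretext task.

All generators are deterministic given their seed and use a counter-based
substream per subject, so subject ``i`` is identical regardless of how many
subjects are requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .core_io import CohortDataset, NetworkMap, TimeCourse

__all__ = [
    "SynthConfig",
    "EffectSpec",
    "gen_pretrain_corpus",
    "gen_clinical_cohort",
    "gen_symmetric_corpus",
    "asymmetric_kernel",
    "kernel_moments",
    "increment_skewness_score",
]


@dataclass
class SynthConfig:
    """Generator settings.

    The defaults are desk-scale study conditions: 200 subjects of 200 time
    points over 53 components, an impulse response rising in ~1 time step and
    decaying over ~6 (a caricature of hemodynamic asymmetry), events at 8 per
    100 time points, and additive noise at half the typical response scale.
    """

    n_subjects: int = 200
    T_total: int = 200
    C: int = 53
    kernel_rise: float = 1.0
    kernel_decay: float = 6.0
    event_rate: float = 8.0  # expected events per 100 time points
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.kernel_rise >= self.kernel_decay:
            raise ValueError("kernel_rise must be < kernel_decay (asymmetry)")
        for name in ("n_subjects", "T_total", "C"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("kernel_rise", "kernel_decay", "event_rate", "noise_sd"):
            if getattr(self, name) <= 0 and name != "noise_sd":
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class EffectSpec:
    """A planted disorder signature on one or more functional networks.

    ``amplitude_factor`` rescales the pre-noise signal of every component in
    the target networks for patients (0.5 halves the response amplitude, i.e.
    suppressed activity; 2.0 doubles it); ``mean_shift`` adds a constant
    offset, likewise before noise.

    Two disrupted-dynamics knobs alter the impulse response's temporal shape
    in patients while leaving its energy (hence signal variance) matched to
    controls: ``decay_factor`` stretches the decay time constant, and
    ``asymmetry_factor`` interpolates the kernel toward its time-reverse
    (1 = unchanged, 0 = fully time-symmetric responses — precisely the
    feature the time-reversal pretext task learns to detect).
    """

    target_networks: list[str] = field(default_factory=lambda: ["Auditory"])
    amplitude_factor: float = 0.5
    mean_shift: float = 0.0
    decay_factor: float = 1.0
    asymmetry_factor: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitude_factor <= 0 or self.decay_factor <= 0:
            raise ValueError("amplitude_factor and decay_factor must be > 0")
        if not 0.0 <= self.asymmetry_factor <= 1.0:
            raise ValueError("asymmetry_factor must lie in [0, 1]")
        if not self.target_networks:
            raise ValueError("at least one target network required")


def asymmetric_kernel(rise: float, decay: float, length: int | None = None) -> np.ndarray:
    """Difference-of-exponentials impulse response k(t) = e^(-t/decay) - e^(-t/rise).

    Fast rise / slow decay yields a right-skewed response; skewness flips sign
    under time reversal, which is exactly the signal the pretext task learns.
    Normalized to unit peak.
    """
    if length is None:
        length = int(np.ceil(6 * decay))
    t = np.arange(length, dtype=np.float64)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    return k / k.max()


def kernel_moments(rise: float, decay: float) -> dict[str, float]:
    """Closed-form moments of the kernel viewed as a density on [0, inf).

    For p(t) proportional to e^(-t/a) - e^(-t/b) with a = decay, b = rise:
    mean = a + b, variance = a^2 + b^2, third central moment = 2(a^3 + b^3),
    hence skewness 2(a^3+b^3) / (a^2+b^2)^(3/2) > 0 always.
    """
    a, b = float(decay), float(rise)
    var = a * a + b * b
    mu3 = 2.0 * (a ** 3 + b ** 3)
    return {
        "mean": a + b,
        "variance": var,
        "third_central_moment": mu3,
        "skewness": mu3 / var ** 1.5,
    }


def _subject_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    # counter-based substream: (seed, stream, index) fully determines the draws
    return np.random.default_rng([seed, stream, index])


def _events(rng: np.random.Generator, T: int, C: int, cfg: SynthConfig) -> np.ndarray:
    """Sparse event trains with gamma-distributed positive amplitudes."""
    p = cfg.event_rate / 100.0
    return (rng.random((T, C)) < p) * rng.gamma(shape=2.0, scale=1.0, size=(T, C))


def _convolve(events: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return sp_signal.fftconvolve(events, kernel[:, None], mode="full", axes=0)[: len(events)]


def _asymmetric_subject(cfg: SynthConfig, stream: int, index: int,
                        effect: EffectSpec | None = None,
                        effect_comps: np.ndarray | None = None) -> np.ndarray:
    rng = _subject_rng(cfg.seed, stream, index)
    events = _events(rng, cfg.T_total, cfg.C, cfg)
    kernel = asymmetric_kernel(cfg.kernel_rise, cfg.kernel_decay)
    sig = _convolve(events, kernel)
    if effect is not None and effect_comps is not None and effect_comps.size:
        if effect.decay_factor != 1.0 or effect.asymmetry_factor != 1.0:
            k_eff = asymmetric_kernel(cfg.kernel_rise,
                                      cfg.kernel_decay * effect.decay_factor,
                                      length=max(len(kernel), int(np.ceil(
                                          6 * cfg.kernel_decay * effect.decay_factor))))
            a = effect.asymmetry_factor
            k_eff = a * k_eff + (1.0 - a) * k_eff[::-1]
            # energy-match so variance carries no group information
            k_eff = k_eff * np.sqrt((kernel ** 2).sum() / (k_eff ** 2).sum())
            target = _convolve(events[:, effect_comps], k_eff)
        else:
            target = sig[:, effect_comps]
        sig[:, effect_comps] = effect.amplitude_factor * target + effect.mean_shift
    noise = cfg.noise_sd * rng.standard_normal((cfg.T_total, cfg.C))
    return sig + noise


def gen_pretrain_corpus(cfg: SynthConfig, cohort_id: str = "SYNTH-PRETRAIN") -> CohortDataset:
    """Healthy-control corpus with temporally asymmetric dynamics.

    All labels are 1 (control); the pretext task ignores them.
    """
    subjects = [
        TimeCourse(_asymmetric_subject(cfg, stream=0, index=i), subject_id=f"{cohort_id}-{i:04d}")
        for i in range(cfg.n_subjects)
    ]
    return CohortDataset(subjects, np.ones(cfg.n_subjects, dtype=np.int64), cohort_id)


def gen_clinical_cohort(cfg: SynthConfig, effect: EffectSpec, net_map: NetworkMap,
                        n_hc: int, n_pat: int,
                        cohort_id: str = "SYNTH-CLIN") -> CohortDataset:
    """Case/control cohort: controls share the corpus dynamics, patients carry
    the planted effect on the target networks (applied to the pre-noise signal).

    Labels follow the cohort convention: patient = 0, healthy control = 1.
    """
    if n_hc < 1 or n_pat < 1:
        raise ValueError("n_hc and n_pat must be >= 1")
    if net_map.n_components != cfg.C:
        raise ValueError(f"network map covers {net_map.n_components} components, config has {cfg.C}")
    comps = []
    for net in effect.target_networks:
        c = net_map.components_of(net)
        if c.size == 0:
            raise ValueError(f"target network {net!r} absent from network map")
        comps.append(c)
    effect_comps = np.unique(np.concatenate(comps))

    eff_cfg = SynthConfig(**{**cfg.__dict__, "seed": cfg.seed + effect.seed})
    subjects: list[TimeCourse] = []
    labels: list[int] = []
    for i in range(n_hc):
        subjects.append(
            TimeCourse(_asymmetric_subject(eff_cfg, stream=1, index=i),
                       subject_id=f"{cohort_id}-HC-{i:04d}")
        )
        labels.append(1)
    for i in range(n_pat):
        subjects.append(
            TimeCourse(
                _asymmetric_subject(eff_cfg, stream=2, index=i,
                                    effect=effect, effect_comps=effect_comps),
                subject_id=f"{cohort_id}-PT-{i:04d}",
            )
        )
        labels.append(0)
    return CohortDataset(subjects, np.array(labels, dtype=np.int64), cohort_id)


def gen_symmetric_corpus(cfg: SynthConfig, cohort_id: str = "SYNTH-SYM") -> CohortDataset:
    """Time-symmetric negative control: stationary Gaussian series.

    White noise smoothed with a symmetric Gaussian kernel is a stationary
    Gaussian process, whose law is invariant under time reversal; no
    classifier can beat chance on the pretext task here.
    """
    width = max(1.0, cfg.kernel_decay / 2.0)
    half = int(np.ceil(3 * width))
    t = np.arange(-half, half + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (t / width) ** 2)
    kernel /= np.sqrt((kernel ** 2).sum())  # unit output variance
    subjects = []
    for i in range(cfg.n_subjects):
        rng = _subject_rng(cfg.seed, 3, i)
        pad = half
        white = rng.standard_normal((cfg.T_total + 2 * pad, cfg.C))
        smooth = sp_signal.fftconvolve(white, kernel[:, None], mode="same", axes=0)
        x = smooth[pad: pad + cfg.T_total] + cfg.noise_sd * rng.standard_normal((cfg.T_total, cfg.C))
        subjects.append(TimeCourse(x, subject_id=f"{cohort_id}-{i:04d}"))
    return CohortDataset(subjects, np.ones(cfg.n_subjects, dtype=np.int64), cohort_id)


def increment_skewness_score(values: np.ndarray) -> float:
    """Model-free time-direction statistic: mean skewness of first differences.

    Fast-rise/slow-decay dynamics make increments right-skewed in forward time
    and left-skewed after reversal, so the sign of this score is already a
    above-chance original-vs-reversed classifier.  Used as a learnability
    oracle before any model training.
    """
    d = np.diff(values, axis=0)
    return float(np.mean(sp_stats.skew(d, axis=0)))
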