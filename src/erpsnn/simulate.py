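"""Synthetic oddball-ERP cohorts with plantable group/time/psychometric effects.

The generator emulates a 4-tone auditory oddball study: two groups
(experimental, waitlist) assessed at up to three time points, with averaged
ERP epochs per participant for target and distractor stimuli recorded from a
62-channel cap at 1 kHz (1300-sample epochs, stimulus onset at sample 0).

Averaged ERPs are modelled as a sum of component templates -- Gaussian-in-time
bumps with scalp topographies expressed as per-channel gains in [-1, 1]:

* N100 (100 ms, -4 uV) and N200 (200 ms, -3 uV), frontocentral;
* a P300-family late positivity (+6 uV, 280-400 ms) that is
  occipitoparietal-maximal for targets and anterior-shifted for distractors,
  mirroring the posterior P3b / anterior P3a-P3c distinction.

Each late component carries an event-locked oscillatory burst (a cosine
carrier under the same Gaussian envelope).  A purely monophasic bump changes
millisecond-scale first differences very little, so a difference-threshold
spike encoder would be almost blind to amplitude effects; the burst makes
component gain visible as spike density, which is the quantity the
reservoir statistics consume.

Three planted effects provide ground truth for recovery tests:

* ``frontal_gain_delta`` scales frontal-channel late-positivity gain for
  experimental-group post-training samples (a Time x Group interaction);
* a per-participant latent scales right-frontal late-positivity gain
  (``rf_gain_sd``);
* psychometric scores are coupled to that latent: FFMQ positively, BDI and
  DASS negatively, with target correlation ``psychometric_coupling``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScheduleConfig",
    "StimulusSchedule",
    "ERPComponentSpec",
    "CohortSpec",
    "ERPSample",
    "generate_schedule",
    "default_components",
    "render_template",
    "generate_cohort",
]

GROUPS = ("experimental", "waitlist")
TIME_POINTS = ("T1", "T2", "T3")
STIMULI = ("target", "distractor")
STIMULUS_KINDS = ("standard", "noise", "target", "distractor")


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


# --------------------------------------------------------------------------
# stimulus schedules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleConfig:
    """Oddball task composition: two blocks of 90/18/18/18 stimuli by default
    (62.5% standards, 12.5% each noise/target/distractor), inter-stimulus
    interval 1100 +/- 100 ms."""

    block_count: int = 2
    per_block_counts: Mapping[str, int] = field(
        default_factory=lambda: {"standard": 90, "noise": 18, "target": 18, "distractor": 18}
    )
    isi_ms: float = 1100.0
    jitter_ms: float = 100.0

    def validate(self) -> None:
        if self.block_count < 0:
            raise ConfigurationError("block_count must be >= 0")
        for kind, n in self.per_block_counts.items():
            if kind not in STIMULUS_KINDS:
                raise ConfigurationError(f"unknown stimulus kind {kind!r}")
            if n < 0:
                raise ConfigurationError(f"negative count for {kind!r}")
        if self.jitter_ms < 0 or self.jitter_ms > self.isi_ms:
            raise ConfigurationError("jitter must lie in [0, isi]")


@dataclass(frozen=True)
class StimulusSchedule:
    """A realised stimulus sequence: (onset_ms, kind) events in onset order."""

    events: tuple
    block_count: int
    per_block_counts: Mapping[str, int]

    def __len__(self) -> int:
        return len(self.events)

    def counts(self) -> dict:
        out: dict = {}
        for _, kind in self.events:
            out[kind] = out.get(kind, 0) + 1
        return out

    def onsets(self) -> np.ndarray:
        return np.array([t for t, _ in self.events], dtype=float)


def generate_schedule(config: ScheduleConfig = ScheduleConfig(), seed: int = 0) -> StimulusSchedule:
    """Generate a randomised oddball stimulus schedule.

    Event order is shuffled independently within each block; composition per
    block matches ``config.per_block_counts`` exactly (counts are not
    sampled).  Consecutive onsets are separated by a uniform draw from
    ``isi_ms +/- jitter_ms``.  Deterministic given ``seed``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    events = []
    t = 0.0
    first = True
    for _ in range(config.block_count):
        kinds = [k for k, n in config.per_block_counts.items() for _ in range(n)]
        order = rng.permutation(len(kinds))
        for i in order:
            if not first:
                t += rng.uniform(config.isi_ms - config.jitter_ms,
                                 config.isi_ms + config.jitter_ms)
            events.append((t, kinds[i]))
            first = False
    return StimulusSchedule(
        events=tuple(events),
        block_count=config.block_count,
        per_block_counts=dict(config.per_block_counts),
    )


# --------------------------------------------------------------------------
# component templates
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ERPComponentSpec:
    """One simulated ERP component.

    ``topography`` maps every montage channel to a gain in [-1, 1].  The
    waveform is ``amplitude_uv * envelope(t)`` with a Gaussian envelope of
    sigma ``width_ms / 2`` centred on ``latency_ms``, plus an event-locked
    burst ``ripple_fraction * amplitude_uv * envelope(t) * cos(2 pi f (t -
    latency))`` when ``ripple_fraction > 0``.
    """

    name: str
    latency_ms: float
    width_ms: float
    amplitude_uv: float
    topography: Mapping[str, float]
    ripple_hz: float = 0.0
    ripple_fraction: float = 0.0

    def validate(self, channels: Sequence[str]) -> None:
        if self.width_ms <= 0:
            raise ConfigurationError(f"component {self.name}: width must be > 0")
        unknown = set(self.topography) - set(channels)
        if unknown:
            raise ConfigurationError(
                f"component {self.name}: unknown channels {sorted(unknown)}"
            )
        missing = set(channels) - set(self.topography)
        if missing:
            raise ConfigurationError(
                f"component {self.name}: missing gains for {sorted(missing)}"
            )
        for ch, g in self.topography.items():
            if not -1.0 <= g <= 1.0:
                raise ConfigurationError(
                    f"component {self.name}: gain for {ch} outside [-1, 1]"
                )

    def waveform(self, n_samples: int, rate_hz: float) -> np.ndarray:
        t = np.arange(n_samples) * 1000.0 / rate_hz
        sigma = self.width_ms / 2.0
        env = np.exp(-0.5 * ((t - self.latency_ms) / sigma) ** 2)
        w = env.copy()
        if self.ripple_fraction > 0.0 and self.ripple_hz > 0.0:
            w = w + self.ripple_fraction * env * np.cos(
                2.0 * np.pi * self.ripple_hz * (t - self.latency_ms) / 1000.0
            )
        return self.amplitude_uv * w


def _anterior_coordinate(montage) -> np.ndarray:
    y = montage.coords[:, 1]
    return y / np.abs(y).max()


def default_components(montage, stimulus: str) -> tuple:
    """Default component set for one stimulus type.

    Targets get an occipitoparietal-maximal late positivity, distractors an
    anterior-shifted one; both share frontocentral N100/N200 negativities.
    Topography gains follow smooth anterior-posterior gradients of the scalp
    y-coordinate so neighbouring channels carry similar gain.
    """
    if stimulus not in STIMULI:
        raise ConfigurationError(f"unknown stimulus {stimulus!r}")
    a = _anterior_coordinate(montage)
    chs = montage.channels
    # gain ceilings leave headroom so planted multipliers (up to 2x on the
    # frontal late positivity) never clip at the [-1, 1] bound
    fc = 0.2 + 0.3 * np.exp(-0.5 * ((a - 0.1) / 0.35) ** 2)
    post = 0.25 + 0.40 * (1.0 - a) / 2.0
    ant = 0.20 + 0.30 * (1.0 + a) / 2.0
    topo_fc = dict(zip(chs, fc))
    n100 = ERPComponentSpec("N100", 100.0, 30.0, -8.0, topo_fc,
                            ripple_hz=22.0, ripple_fraction=0.5)
    n200 = ERPComponentSpec("N200", 200.0, 40.0, -6.0, topo_fc,
                            ripple_hz=22.0, ripple_fraction=0.5)
    if stimulus == "target":
        p3 = ERPComponentSpec("P3b", 340.0, 120.0, 9.0, dict(zip(chs, post)),
                              ripple_hz=40.0, ripple_fraction=1.5)
    else:
        p3 = ERPComponentSpec("P3a", 320.0, 120.0, 9.0, dict(zip(chs, ant)),
                              ripple_hz=40.0, ripple_fraction=1.5)
    return (n100, n200, p3)


def render_template(components: Sequence[ERPComponentSpec], channels: Sequence[str],
                    epoch_len: int, rate_hz: float) -> np.ndarray:
    """Deterministic noise-free channel x time template for a component set."""
    data = np.zeros((len(channels), epoch_len), dtype=float)
    for comp in components:
        comp.validate(channels)
        wave = comp.waveform(epoch_len, rate_hz)
        gains = np.array([comp.topography[ch] for ch in channels])
        data += gains[:, None] * wave[None, :]
    return data


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ERPSample:
    """One participant's averaged ERP epoch for one condition (microvolts)."""

    participant_id: str
    group: str
    time_point: str
    stimulus: str
    data: np.ndarray  # channels x time
    channels: tuple

    def __post_init__(self):
        if self.data.shape[0] != len(self.channels):
            raise ValueError("row count must equal number of channels")
        if not np.isfinite(self.data).all():
            raise ValueError("sample contains non-finite values")


@dataclass(frozen=True)
class CohortSpec:
    """Design and effect sizes of a synthetic cohort.

    ``frontal_gain_delta`` multiplies frontal-channel late-positivity gain by
    ``1 + delta`` for experimental-group samples at post-training time points
    (every time point after T1).  ``psychometric_coupling`` is the target
    correlation between FFMQ and the latent right-frontal gain;
    ``rf_gain_sd`` sets that latent's spread (0 removes between-participant
    signal variability entirely).
    """

    n_per_group: int = 10
    groups: tuple = GROUPS
    time_points: tuple = ("T1", "T2")
    stimuli: tuple = STIMULI
    epoch_len: int = 1300
    sample_rate_hz: float = 1000.0
    noise_sd_uv: float = 0.5
    ar_coef: float = 0.0
    frontal_gain_delta: float = 1.0
    rf_gain_sd: float = 0.3
    psychometric_coupling: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group <= 0:
            raise ConfigurationError("n_per_group must be > 0")
        if self.epoch_len <= 0:
            raise ConfigurationError("epoch_len must be > 0")
        if self.noise_sd_uv < 0:
            raise ConfigurationError("noise_sd_uv must be >= 0")
        if not -1.0 <= self.psychometric_coupling <= 1.0:
            raise ConfigurationError("psychometric_coupling must lie in [-1, 1]")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ConfigurationError("ar_coef must lie in [0, 1)")
        for g in self.groups:
            if g not in GROUPS:
                raise ConfigurationError(f"unknown group {g!r}")
        for t in self.time_points:
            if t not in TIME_POINTS:
                raise ConfigurationError(f"unknown time point {t!r}")
        for s in self.stimuli:
            if s not in STIMULI:
                raise ConfigurationError(f"unknown stimulus {s!r}")


_PSYCH_BASE = {
    "FFMQ": (125.0, 15.0, +1.0),
    "BDI": (12.0, 7.0, -1.0),
    "DASS_Depression": (8.0, 6.0, -1.0),
    "DASS_Anxiety": (6.0, 5.0, -1.0),
    "DASS_Stress": (10.0, 6.0, -1.0),
}


def _participant_ids(spec: CohortSpec) -> list:
    short = {"experimental": "exp", "waitlist": "wl"}
    return [
        (f"{short[g]}{i + 1:02d}", g)
        for g in spec.groups
        for i in range(spec.n_per_group)
    ]


def _scaled_topography(comp: ERPComponentSpec, scale: Mapping[str, float]) -> ERPComponentSpec:
    topo = {ch: float(np.clip(g * scale.get(ch, 1.0), -1.0, 1.0))
            for ch, g in comp.topography.items()}
    return replace(comp, topography=topo)


def generate_cohort(spec: CohortSpec, montage=None):
    """Generate a cohort of averaged-ERP samples plus a psychometric table.

    Returns
    -------
    samples : list of ERPSample
        One sample per participant x time point x stimulus, in deterministic
        order (group, participant, time, stimulus).
    psychometrics : pandas.DataFrame
        One row per participant: FFMQ, BDI, DASS scores, the generative
        ``latent_rf_gain`` (ground truth for recovery tests) and ``group``.

    All randomness derives from ``spec.seed``; two calls with equal specs
    return byte-identical arrays.
    """
    spec.validate()
    if montage is None:
        from .fixtures import load_montage

        montage = load_montage()
    chs = montage.channels
    frontal = [c for c in chs if montage.regions.loc[c, "site"] == "frontal"]
    right_frontal = [
        c for c in chs
        if montage.regions.loc[c, "site"] == "frontal"
        and montage.regions.loc[c, "hemisphere"] == "right"
    ]

    base = {s: default_components(montage, s) for s in spec.stimuli}
    participants = _participant_ids(spec)

    # participant latents and psychometrics
    rng_p = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    z = rng_p.standard_normal(len(participants))
    rf_gain = np.maximum(0.1, 1.0 + spec.rf_gain_sd * z)
    c = spec.psychometric_coupling
    rows = {}
    for name, (mu, sd, sign) in _PSYCH_BASE.items():
        eps = rng_p.standard_normal(len(participants))
        rows[name] = mu + sd * (sign * c * z + np.sqrt(max(0.0, 1.0 - c * c)) * eps)
    psych = pd.DataFrame(rows, index=[pid for pid, _ in participants])
    psych.index.name = "participant_id"
    psych["latent_rf_gain"] = rf_gain
    psych["group"] = [g for _, g in participants]

    samples = []
    for p_idx, (pid, group) in enumerate(participants):
        rf_scale = {ch: rf_gain[p_idx] for ch in right_frontal}
        for t_idx, tp in enumerate(spec.time_points):
            post_training = group == "experimental" and tp != "T1"
            for s_idx, stim in enumerate(spec.stimuli):
                comps = []
                for comp in base[stim]:
                    if comp.amplitude_uv > 0:  # late positivity carries effects
                        scale = dict(rf_scale)
                        if post_training and spec.frontal_gain_delta != 0.0:
                            for ch in frontal:
                                scale[ch] = scale.get(ch, 1.0) * (1.0 + spec.frontal_gain_delta)
                        comp = _scaled_topography(comp, scale)
                    comps.append(comp)
                data = render_template(comps, chs, spec.epoch_len, spec.sample_rate_hz)
                if spec.noise_sd_uv > 0:
                    rng = np.random.default_rng(
                        np.random.SeedSequence([spec.seed, 2, p_idx, t_idx, s_idx])
                    )
                    eps = rng.standard_normal(data.shape)
                    if spec.ar_coef > 0.0:
                        from scipy.signal import lfilter

                        eps = lfilter([np.sqrt(1 - spec.ar_coef ** 2)],
                                      [1.0, -spec.ar_coef], eps, axis=1)
                    data = data + spec.noise_sd_uv * eps
                samples.append(
                    ERPSample(pid, group, tp, stim, data, tuple(chs))
                )
    return samples, psych
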