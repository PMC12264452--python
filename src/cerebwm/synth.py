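"""Synthetic EEG and 2-back behavior with known ground-truth effects.

The generator emulates the statistical structure the downstream analyses
assume: 1000 Hz sampling, a 10-10 montage containing the fronto-central
reporting electrodes FC1/FCz/FC2, stimulus-locked ERP deflections in the
standard component windows, event-related band-limited oscillations riding
on 1/f background noise, inter-channel phase coupling with a controllable
phase-locking value, and per-group pre/post effect deltas (ERP amplitude,
band power, coupling, reaction-time shift).  Every quantity the pipeline
estimates therefore has a known injected value, giving each stage a
parameter-recovery test surface.

Five stimulation groups are simulated (1, 5, 10, 20 Hz and sham), each with
a pre and a post session of resting and task EEG plus a 2-back behavioral
session of 150 trials with 30% targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import mne
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .bands import DEFAULT_BANDS
from .containers import EpochSet, Montage

__all__ = [
    "ERPComponent",
    "EffectDelta",
    "SimConfig",
    "BehavioralSession",
    "SubjectRecord",
    "StudyDataset",
    "GROUPS",
    "default_erp_components",
    "default_effect_deltas",
    "generate_montage",
    "generate_epochs",
    "generate_behavior",
    "generate_study",
    "behavior_to_csv",
    "behavior_from_csv",
]

GROUPS = ("rTMS1", "rTMS5", "rTMS10", "rTMS20", "sham")
SESSIONS = ("pre", "post")

# Ordered 10-10 electrode labels used to build montages of any size; the
# reporting subset FC1/FCz/FC2 always comes first so it is present at the
# minimum channel count.  Labels follow the naming of the standard montage
# shipped with mne.
_CHANNEL_ORDER = (
    # grown outward from the fronto-central patch so that every prefix is a
    # spatially contiguous layout (each electrode keeps a close neighbour)
    "FC1", "FCz", "FC2", "Cz", "Fz", "C1", "C2", "F1", "F2", "FC3",
    "FC4", "C3", "C4", "F3", "F4", "CP1", "CPz", "CP2", "CP3", "CP4",
    "P1", "Pz", "P2", "P3", "P4", "AFz", "PO3", "POz", "PO4", "O1",
    "Oz", "O2", "AF3", "AF4", "F5", "F6", "FC5", "FC6", "C5", "C6",
    "CP5", "CP6", "P5", "P6", "PO7", "PO8", "Fp1", "Fp2", "F7", "F8",
    "FT7", "FT8", "T7", "T8", "TP7", "TP8", "P7", "P8",
)


@dataclass(frozen=True)
class ERPComponent:
    """A stimulus-locked deflection: Gaussian template with analytic peak.

    ``width_ms`` is the Gaussian sigma; ``amplitude_uv`` is signed (negative
    for the N components).  ``topography`` maps channel label to a weight in
    [0, 1]; unlisted channels fall back to a distance decay from FCz.
    """

    label: str
    peak_ms: float
    width_ms: float
    amplitude_uv: float
    topography: dict[str, float] | None = None


def default_erp_components() -> tuple[ERPComponent, ...]:
    """N100/P150/N200/P300 templates peaking inside their scoring windows."""
    return (
        ERPComponent("N100", 100.0, 12.0, -3.0),
        ERPComponent("P150", 160.0, 15.0, 4.0),
        ERPComponent("N200", 250.0, 20.0, -2.5),
        ERPComponent("P300", 330.0, 30.0, 3.5),
    )


@dataclass(frozen=True)
class EffectDelta:
    """Post-minus-pre ground-truth shifts for one stimulation group.

    erp_uv: additive change of a component's amplitude (µV) in the post
    session; band_gain: multiplicative change of a band's oscillation
    amplitude (1.0 = none; ``10**(db/20)`` yields a +db power change);
    plv: additive change of the target phase-locking value per band;
    rt_s: additive shift of the mean reaction time (negative = faster).
    """

    erp_uv: dict[str, float] = field(default_factory=dict)
    band_gain: dict[str, float] = field(default_factory=dict)
    plv: dict[str, float] = field(default_factory=dict)
    rt_s: float = 0.0

    @classmethod
    def zero(cls) -> "EffectDelta":
        return cls()


def default_effect_deltas() -> dict[str, EffectDelta]:
    """Ground-truth group effects the simulation injects by default.

    Reaction-time shifts reproduce the printed group means (all groups get
    faster, consistent with a training effect; the 5 Hz group most).  The
    5 Hz group additionally carries the electrophysiological effects the
    analysis is meant to recover: a +2 µV P150 increase, +1 dB theta and
    alpha power, and a +0.15 theta-band phase-locking increase.  The 10 Hz
    group gets a modest N100 increase (more negative), and the remaining
    groups differ from sham only in reaction time.
    """
    db1 = 10.0 ** (1.0 / 20.0)  # amplitude gain giving +1 dB power
    return {
        "rTMS1": EffectDelta(rt_s=-0.106),
        "rTMS5": EffectDelta(
            erp_uv={"P150": 2.0},
            band_gain={"theta": db1, "alpha": db1},
            plv={"theta": 0.15},
            rt_s=-0.112,
        ),
        "rTMS10": EffectDelta(erp_uv={"N100": -1.0}, rt_s=-0.072),
        "rTMS20": EffectDelta(rt_s=-0.093),
        "sham": EffectDelta(rt_s=-0.051),
    }


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with the study conditions as defaults."""

    n_channels: int = 32
    fs: float = 1000.0
    tmin: float = -0.2  # seconds relative to stimulus
    tmax: float = 0.8
    n_trials: int = 60  # EEG epochs per task session
    n_rest_segments: int = 30  # 2 s resting segments per session
    rest_segment_s: float = 2.0
    noise_exponent: float = 1.0
    noise_sd_uv: float = 2.0
    band_powers: dict[str, float] = field(
        default_factory=lambda: {
            "theta": 2.0, "alpha": 3.0, "beta1": 0.8, "beta2": 0.5, "gamma": 0.4
        }
    )
    erp_components: tuple[ERPComponent, ...] = field(default_factory=default_erp_components)
    plv_coupling: dict[str, float] = field(default_factory=lambda: {"theta": 0.45})
    # disjoint long-range synchrony pairs (fronto-parietal/occipital); each
    # pair shares its own carrier, so raising the coupling adds shortcut
    # edges to the lattice-like baseline network without forming a clique
    coupled_pairs: tuple[tuple[str, str], ...] = (
        ("FC1", "P1"), ("FC2", "P2"), ("FCz", "Pz"), ("Fz", "POz"),
        ("Cz", "Oz"), ("F1", "PO3"), ("F2", "PO4"), ("F3", "P3"),
        ("F4", "P4"), ("C1", "O1"), ("C2", "O2"), ("FC3", "CP3"),
        ("FC4", "CP4"), ("AFz", "CPz"))
    # volume-conduction-like spatial smearing: Gaussian mixing of channel
    # signals over electrode distance (meters); None disables
    mixing_sigma_m: float | None = 0.03
    burst_center_ms: float = 250.0  # event-related oscillation envelope
    burst_sigma_ms: float = 70.0
    n_behavior_trials: int = 150
    target_frac: float = 0.30
    hit_rate: float = 0.85
    fa_rate: float = 0.10
    rt_mean_s: float = 0.80
    rt_shift_s: float = 0.25  # lognormal shift (non-decision floor)
    rt_sigma_ln: float = 0.35
    n_subjects_per_group: int = 12
    effect_deltas: dict[str, EffectDelta] = field(default_factory=default_effect_deltas)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.tmin <= -0.2 and self.tmax >= 0.35):
            raise ValueError(
                "epoch window must span the baseline (-200..0 ms) and the "
                "analysis window (50..350 ms)"
            )
        if any(a < 0 for a in self.band_powers.values()):
            raise ValueError("band amplitudes must be >= 0")
        if any(not (0.0 <= p <= 1.0) for p in self.plv_coupling.values()):
            raise ValueError("target PLV must lie in [0, 1]")
        if self.noise_sd_uv < 0:
            raise ValueError("noise SD must be >= 0")


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def generate_montage(n_channels: int = 32) -> Montage:
    """A 10-10 montage subset of ``n_channels`` electrodes.

    FC1, FCz and FC2 are always included.  Positions come from the standard
    1005 montage shipped with mne (head frame, meters).
    """
    if n_channels < 4:
        raise ValueError("n_channels must be >= 4")
    if n_channels > len(_CHANNEL_ORDER):
        raise ValueError(f"montage supports at most {len(_CHANNEL_ORDER)} channels")
    labels = _CHANNEL_ORDER[:n_channels]
    std = mne.channels.make_standard_montage("colin27_1005").get_positions()["ch_pos"]
    pos = np.array([std[c] for c in labels])
    return Montage(labels, pos)


# ---------------------------------------------------------------------------
# EEG epochs
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                exponent: float, fs: float) -> np.ndarray:
    """1/f^exponent noise via spectral shaping of white noise, unit variance."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    f[0] = f[1]  # keep DC finite
    spec *= f ** (-exponent / 2.0)
    out = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _component_weights(comp: ERPComponent, montage: Montage) -> np.ndarray:
    """Per-channel topography weights; default is a fronto-central decay."""
    if comp.topography is not None:
        return np.array([comp.topography.get(c, 0.0) for c in montage.ch_names])
    ref = montage.positions[montage.index(["FCz"])[0]]
    d = np.linalg.norm(montage.positions - ref, axis=1)
    scale = max(np.median(d), 1e-9)
    return np.exp(-((d / (1.5 * scale)) ** 2))


def _smooth_phase_noise(rng: np.random.Generator, shape: tuple[int, ...],
                        n_samples: int, fs: float, cutoff_hz: float,
                        sd: float) -> np.ndarray:
    """Slowly varying Gaussian phase jitter with standard deviation ``sd``."""
    raw = rng.standard_normal(shape + (n_samples,))
    sigma = fs / (2.0 * np.pi * cutoff_hz)
    smooth = gaussian_filter1d(raw, sigma, axis=-1, mode="wrap")
    cur = smooth.std(axis=-1, keepdims=True)
    cur[cur == 0] = 1.0
    return smooth / cur * sd


def generate_epochs(cfg: SimConfig, *, group: str = "sham", session: str = "pre",
                    kind: str = "task", rng: np.random.Generator | None = None,
                    montage: Montage | None = None) -> EpochSet:
    """Simulate one session's epochs for one subject.

    ``kind="task"`` epochs are stimulus-locked: ERP templates plus
    event-related oscillatory bursts (Gaussian envelope) on 1/f noise.
    ``kind="rest"`` epochs are stationary segments without ERPs, with the
    oscillations (and the phase coupling) present throughout — the input
    the PLV network stage expects.

    The post session applies the group's configured :class:`EffectDelta`.
    Identical configs and seeds give bit-identical arrays.
    """
    if kind not in ("task", "rest"):
        raise ValueError("kind must be 'task' or 'rest'")
    if group not in cfg.effect_deltas:
        raise ValueError(f"group {group!r} missing from effect_deltas "
                         "(explicit zeros required)")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    montage = montage or generate_montage(cfg.n_channels)
    n_ch = montage.n_channels
    delta = cfg.effect_deltas[group] if session == "post" else EffectDelta.zero()

    if kind == "task":
        tmin, n_trials = cfg.tmin, cfg.n_trials
        n_samp = int(round((cfg.tmax - cfg.tmin) * cfg.fs)) + 1
    else:
        tmin, n_trials = 0.0, cfg.n_rest_segments
        n_samp = int(round(cfg.rest_segment_s * cfg.fs))
    t = tmin + np.arange(n_samp) / cfg.fs

    data = np.zeros((n_ch, n_samp, n_trials))
    if cfg.noise_sd_uv > 0:
        data += cfg.noise_sd_uv * _pink_noise(
            rng, (n_ch, n_trials), n_samp, cfg.noise_exponent, cfg.fs
        ).transpose(0, 2, 1)

    # event-related oscillation envelope (rest: flat)
    if kind == "task":
        env = np.exp(-0.5 * ((t * 1000.0 - cfg.burst_center_ms) / cfg.burst_sigma_ms) ** 2)
        env = env * (t >= 0)  # oscillatory response follows the stimulus
    else:
        env = np.ones(n_samp)

    pairs_idx: list[tuple[int, int]] = []
    if cfg.plv_coupling:
        lut = {ch: i for i, ch in enumerate(montage.ch_names)}
        used: set[str] = set()
        for a, b in cfg.coupled_pairs:
            if a not in lut or b not in lut:
                continue  # pair not realizable on this montage subset
            if a in used or b in used:
                raise ValueError("coupled_pairs must be disjoint")
            used.update((a, b))
            pairs_idx.append((lut[a], lut[b]))

    for band_name, amp in cfg.band_powers.items():
        band = DEFAULT_BANDS[band_name]
        amp = amp * delta.band_gain.get(band_name, 1.0)
        if amp == 0:
            continue
        fc = band.center
        target_plv = cfg.plv_coupling.get(band_name)
        if target_plv is not None:
            target_plv = float(np.clip(target_plv + delta.plv.get(band_name, 0.0), 0.0, 1.0))
        # uncoupled channels oscillate at an independent random frequency
        # inside the band with a random phase, so their pairwise phase
        # differences drift and PLV stays near the sampling floor
        f_ct = rng.uniform(band.low, band.high, size=(n_ch, n_trials, 1))
        phases = rng.uniform(0, 2 * np.pi, size=(n_ch, n_trials, 1))
        osc = np.cos(2 * np.pi * f_ct * t[None, None, :] + phases)
        if target_plv is not None and pairs_idx:
            # each pair shares a carrier (its own random in-band frequency
            # and phase per trial); both members add smooth phase jitter of
            # std sqrt(-ln PLV), so their phase difference is
            # N(0, -2 ln PLV) and the sample-level PLV is the target.
            # Distinct carriers keep different pairs mutually unlocked.
            sd = math.sqrt(-math.log(max(target_plv, 1e-12))) if target_plv < 1 else 0.0
            idx = np.array(pairs_idx, dtype=int)  # (n_pairs, 2)
            f_pair = rng.uniform(band.low, band.high, size=(len(idx), n_trials, 1))
            phase_pair = rng.uniform(0, 2 * np.pi, size=(len(idx), n_trials, 1))
            jitter = _smooth_phase_noise(
                rng, (len(idx), 2, n_trials), n_samp, cfg.fs,
                cutoff_hz=band.low, sd=sd)
            for k in range(2):
                osc[idx[:, k]] = np.cos(
                    2 * np.pi * f_pair * t[None, None, :] + phase_pair
                    + jitter[:, k])
        data += amp * env[None, :, None] * osc.transpose(0, 2, 1)

    if kind == "task":
        t_ms = t * 1000.0
        for comp in cfg.erp_components:
            a = comp.amplitude_uv + delta.erp_uv.get(comp.label, 0.0)
            if a == 0:
                continue
            template = np.exp(-0.5 * ((t_ms - comp.peak_ms) / comp.width_ms) ** 2)
            w = _component_weights(comp, montage)
            data += a * w[:, None, None] * template[None, :, None]

    if cfg.mixing_sigma_m is not None:
        # volume-conduction-like smearing: every electrode sees a
        # distance-weighted mixture of its neighbours.  This gives the PLV
        # matrices their lattice-like distance structure (nearby pairs
        # phase-lock through shared signal), on top of which the injected
        # long-range coupling acts as small-world shortcuts.
        d2 = montage.distances() ** 2
        w = np.exp(-d2 / (2.0 * cfg.mixing_sigma_m**2))
        w /= w.sum(axis=1, keepdims=True)
        data = np.tensordot(w, data, axes=1)

    return EpochSet(
        data=data, fs=cfg.fs, tmin=tmin, ch_names=montage.ch_names,
        group=group, session=session, condition=kind,
        meta={"n_trials": n_trials},
    )


# ---------------------------------------------------------------------------
# 2-back behavior
# ---------------------------------------------------------------------------

@dataclass
class BehavioralSession:
    """One 2-back run: per-trial letters, target flags, responses and RTs."""

    trials: pd.DataFrame  # columns: trial, letter, is_target, response, rt_s
    group: str
    session: str

    def __post_init__(self) -> None:
        required = {"trial", "letter", "is_target", "response", "rt_s"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"missing behavioral columns: {sorted(missing)}")
        if (self.trials["rt_s"] <= 0).any():
            raise ValueError("reaction times must be positive")

    @property
    def n_trials(self) -> int:
        return len(self.trials)


_LETTERS = tuple("ABCDEFGHIJ")


def generate_behavior(cfg: SimConfig, *, group: str = "sham", session: str = "pre",
                      rng: np.random.Generator | None = None) -> BehavioralSession:
    """Simulate one 2-back run of ``n_behavior_trials`` letters.

    Exactly ``round(target_frac * n)`` trials are 2-back targets (the letter
    repeats the one two steps earlier).  Responses follow the configured hit
    and false-alarm rates; reaction times are shifted-lognormal with the
    group x session mean shift from ``effect_deltas``.
    """
    n = cfg.n_behavior_trials
    if n < 10:
        raise ValueError("need at least 10 trials")
    if not (0.0 < cfg.target_frac < 1.0):
        raise ValueError("target fraction must lie in (0, 1)")
    if group not in cfg.effect_deltas:
        raise ValueError(f"group {group!r} missing from effect_deltas")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_targets = int(round(cfg.target_frac * n))
    if n_targets > n - 2:
        raise ValueError("target fraction leaves no room for the 2-back lag")
    target_idx = rng.choice(np.arange(2, n), size=n_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True

    letters = []
    for i in range(n):
        if is_target[i]:
            letters.append(letters[i - 2])
        else:
            pool = [c for c in _LETTERS if i < 2 or c != letters[i - 2]]
            letters.append(pool[rng.integers(len(pool))])

    # "response" is the match keypress: a hit on targets, a false alarm on
    # non-targets
    u = rng.random(n)
    response = np.where(is_target, u < cfg.hit_rate, u < cfg.fa_rate)

    shift = cfg.effect_deltas[group].rt_s if session == "post" else 0.0
    mean_rt = cfg.rt_mean_s + shift
    body = mean_rt - cfg.rt_shift_s
    if body <= 0:
        raise ValueError("rt shift leaves non-positive lognormal body mean")
    mu = math.log(body) - cfg.rt_sigma_ln**2 / 2.0
    rt = cfg.rt_shift_s + rng.lognormal(mu, cfg.rt_sigma_ln, size=n)

    df = pd.DataFrame({
        "trial": np.arange(n), "letter": letters, "is_target": is_target,
        "response": response, "rt_s": rt,
    })
    return BehavioralSession(df, group=group, session=session)


def behavior_to_csv(session: BehavioralSession, path) -> None:
    df = session.trials.copy()
    df["group"] = session.group
    df["session"] = session.session
    df.to_csv(path, index=False)


def behavior_from_csv(path) -> BehavioralSession:
    df = pd.read_csv(path)
    group = str(df["group"].iloc[0])
    session = str(df["session"].iloc[0])
    return BehavioralSession(
        df.drop(columns=["group", "session"]), group=group, session=session
    )


# ---------------------------------------------------------------------------
# whole study
# ---------------------------------------------------------------------------

@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    task: dict[str, EpochSet]          # session -> epochs
    rest: dict[str, EpochSet]
    behavior: dict[str, BehavioralSession]


@dataclass
class StudyDataset:
    subjects: list[SubjectRecord]
    montage: Montage
    config: SimConfig

    def by_group(self, group: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == group]


def generate_study(cfg: SimConfig, *, groups: tuple[str, ...] = GROUPS,
                   include_rest: bool = True) -> StudyDataset:
    """Simulate the full five-group pre/post study.

    Every subject gets task epochs, resting epochs (optional) and a 2-back
    behavioral run for both sessions.  Only groups whose
    :class:`EffectDelta` is non-zero differ from sham in expectation.
    Deterministic for a fixed config (per-subject streams are spawned from
    ``cfg.seed``).
    """
    missing = [g for g in groups if g not in cfg.effect_deltas]
    if missing:
        raise ValueError(f"groups missing from effect_deltas: {missing} "
                         "(explicit zeros required)")
    montage = generate_montage(cfg.n_channels)
    root = np.random.SeedSequence(cfg.seed)
    subjects: list[SubjectRecord] = []
    for gi, group in enumerate(groups):
        for si in range(cfg.n_subjects_per_group):
            child = root.spawn(1)[0]
            rng = np.random.default_rng(child)
            task, rest, behav = {}, {}, {}
            for session in SESSIONS:
                task[session] = generate_epochs(
                    cfg, group=group, session=session, kind="task",
                    rng=rng, montage=montage)
                if include_rest:
                    rest[session] = generate_epochs(
                        cfg, group=group, session=session, kind="rest",
                        rng=rng, montage=montage)
                behav[session] = generate_behavior(
                    cfg, group=group, session=session, rng=rng)
            subjects.append(SubjectRecord(
                subject_id=f"{group}_s{si:02d}", group=group,
                task=task, rest=rest, behavior=behav))
    return StudyDataset(subjects=subjects, montage=montage, config=cfg)
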