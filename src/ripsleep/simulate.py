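"""Ground-truthed synthetic sleep recordings.

The generator produces the three statistical signatures the classifier
exploits in real recordings:

* **Breathing regularity.** NREM breathing is metronomic, REM breathing is
  irregular, and wake breathing is the most variable.  Each breath is a
  single sinusoidal cycle whose period and amplitude are redrawn per breath
  from the current stage's distribution, so breath-duration and
  breath-amplitude dispersion carry the stage signal.
* **Thoraco-abdominal coupling.** The abdominal belt lags the thoracic belt
  by a stage-dependent phase, largest in REM (paradoxical-breathing analog),
  so the inter-belt correlation is stage-informative.
* **Movement.** The activity channel is near-zero noise with Poisson-timed
  bursts; the burst rate is an order of magnitude higher in wake.

Sleep architecture is a first-order Markov chain over {WAKE, REM, NREM} at
the 30-s epoch level, and apnea/hypopnea events are realized as >=10-s
multiplicative amplitude dips on both belts, placed only inside sleep, with
the event count pinned to ``round(target_ahi * sleep_hours)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .types import (
    EPOCH_SECONDS,
    NREM,
    REM,
    STAGES,
    WAKE,
    RespiratoryEvent,
    RespiratoryEventList,
    SignalRecord,
    as_hypnogram,
    is_sleep,
)

__all__ = [
    "StageParams",
    "SyntheticStudyConfig",
    "DEFAULT_STAGE_PARAMS",
    "DEFAULT_TRANSITION_MATRIX",
    "simulate_hypnogram",
    "simulate_signals",
    "generate_cohort",
]


@dataclass(frozen=True)
class StageParams:
    """Signal-generating parameters for one sleep stage.

    Parameters
    ----------
    breath_rate_mean, breath_rate_sd : float
        Breaths per minute; the SD drives breathing (ir)regularity.
    amplitude_mean, amplitude_sd : float
        Per-breath peak amplitude in arbitrary RIP units.
    thoracoabdominal_phase_lag : float
        Phase (radians, in [0, pi]) by which the abdominal belt lags the
        thoracic belt.
    activity_burst_rate : float
        Movement bursts per minute on the activity channel.
    activity_burst_amplitude : float
        Peak amplitude of a movement burst.
    """

    breath_rate_mean: float
    breath_rate_sd: float
    amplitude_mean: float
    amplitude_sd: float
    thoracoabdominal_phase_lag: float
    activity_burst_rate: float
    activity_burst_amplitude: float

    def __post_init__(self) -> None:
        for name in (
            "breath_rate_mean", "breath_rate_sd", "amplitude_mean",
            "amplitude_sd", "activity_burst_rate", "activity_burst_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"StageParams.{name} must be strictly positive")
        if not 0.0 <= self.thoracoabdominal_phase_lag <= np.pi:
            raise ValueError("thoracoabdominal_phase_lag must lie in [0, pi]")


#: Default per-stage parameters.  Ordering constraints: breathing regularity
#: NREM > REM > WAKE (breath_rate_sd smallest in NREM) and movement
#: WAKE >> REM ~ NREM.  Phase lag is largest in REM, where thoraco-abdominal
#: coupling is weakest in real recordings.
DEFAULT_STAGE_PARAMS: dict[str, StageParams] = {
    WAKE: StageParams(
        breath_rate_mean=15.0, breath_rate_sd=2.8,
        amplitude_mean=1.0, amplitude_sd=0.35,
        thoracoabdominal_phase_lag=0.4,
        activity_burst_rate=6.0, activity_burst_amplitude=5.0,
    ),
    REM: StageParams(
        breath_rate_mean=15.5, breath_rate_sd=1.8,
        amplitude_mean=0.85, amplitude_sd=0.22,
        thoracoabdominal_phase_lag=1.1,
        activity_burst_rate=0.3, activity_burst_amplitude=2.0,
    ),
    NREM: StageParams(
        breath_rate_mean=13.0, breath_rate_sd=0.6,
        amplitude_mean=1.0, amplitude_sd=0.10,
        thoracoabdominal_phase_lag=0.15,
        activity_burst_rate=0.15, activity_burst_amplitude=1.5,
    ),
}

#: Default epoch-to-epoch transition matrix (rows/cols in STAGES order).
#: Strong self-transitions give realistic bout structure; wake resolves
#: mostly into NREM, and REM is entered mostly from NREM.
DEFAULT_TRANSITION_MATRIX = np.array(
    [
        [0.90, 0.01, 0.09],  # from WAKE
        [0.05, 0.90, 0.05],  # from REM
        [0.03, 0.07, 0.90],  # from NREM
    ]
)

# Additive sensor noise, as a fraction of the stage's mean amplitude.
_NOISE_FRACTION = 0.05
# Amplitude retained during events (both belts).
_APNEA_FACTOR = 0.05
_HYPOPNEA_FACTOR = 0.5


def _validate_transition_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"transition matrix must be 3x3, got shape {m.shape}")
    if np.any(m < 0) or np.any(m > 1):
        raise ValueError("transition probabilities must lie in [0, 1]")
    row_sums = m.sum(axis=1)
    for i, s in enumerate(row_sums):
        if abs(s - 1.0) > 1e-9:
            raise ValueError(
                f"transition matrix row {i} ({STAGES[i]}) sums to {s!r}, not 1"
            )
    return m


@dataclass
class SyntheticStudyConfig:
    """Configuration of one synthetic overnight study."""

    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITION_MATRIX.copy()
    )
    n_epochs: int = 960
    stage_params: dict[str, StageParams] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PARAMS)
    )
    target_ahi: float = 10.0
    sample_rate: float = 25.0
    seed: int = 0
    initial_stage: str = WAKE

    def __post_init__(self) -> None:
        self.transition_matrix = _validate_transition_matrix(self.transition_matrix)
        if self.n_epochs < 25:
            raise ValueError("n_epochs must be >= 25 (one full model window)")
        if self.sample_rate < 10.0:
            raise ValueError("sample_rate must be >= 10 Hz")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be non-negative")
        missing = set(STAGES) - set(self.stage_params)
        if missing:
            raise ValueError(f"stage_params missing stages: {sorted(missing)}")


def simulate_hypnogram(
    transition_matrix: np.ndarray,
    n_epochs: int,
    initial_stage: str = WAKE,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a hypnogram from a first-order Markov chain.

    Parameters
    ----------
    transition_matrix : (3, 3) array
        Row-stochastic epoch-to-epoch transition probabilities in
        ``STAGES`` order (WAKE, REM, NREM).
    n_epochs : int
        Number of 30-s epochs to generate (>= 1).
    initial_stage : str
        Stage of the first epoch.
    seed : int or Generator
        Random source; identical seeds give identical hypnograms.

    Returns
    -------
    ndarray of str
        Stage labels of length ``n_epochs``.
    """
    m = _validate_transition_matrix(transition_matrix)
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if initial_stage not in STAGES:
        raise ValueError(f"unknown initial stage {initial_stage!r}")
    rng = np.random.default_rng(seed)
    states = np.empty(n_epochs, dtype=np.int64)
    states[0] = STAGES.index(initial_stage)
    for t in range(1, n_epochs):
        states[t] = rng.choice(3, p=m[states[t - 1]])
    return np.array(STAGES, dtype="<U4")[states]


def _place_events(
    hypnogram: np.ndarray,
    target_ahi: float,
    analysis_duration: float,
    rng: np.random.Generator,
) -> RespiratoryEventList:
    """Place ``round(target_ahi * sleep_hours)`` non-overlapping events
    uniformly over contiguous sleep, by rejection sampling."""
    sleep_mask = is_sleep(hypnogram)
    if target_ahi > 0 and not sleep_mask.any():
        raise ValueError(
            "target_ahi > 0 but the hypnogram contains no sleep epochs; "
            "cannot place respiratory events"
        )
    sleep_hours = sleep_mask.sum() * EPOCH_SECONDS / 3600.0
    n_events = int(round(target_ahi * sleep_hours))
    if n_events == 0:
        return RespiratoryEventList([], analysis_duration)

    sleep_epochs = np.flatnonzero(sleep_mask)
    placed: list[RespiratoryEvent] = []
    intervals: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 20000 * n_events
    while len(placed) < n_events:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n_events} non-overlapping events "
                f"(placed {len(placed)}); sleep period too fragmented"
            )
        duration = float(rng.uniform(10.0, 30.0))
        epoch = int(rng.choice(sleep_epochs))
        start = epoch * EPOCH_SECONDS + float(
            rng.uniform(0.0, EPOCH_SECONDS)
        )
        end = start + duration
        if end > analysis_duration:
            continue
        # every epoch touched by the event must be sleep
        touched = np.arange(int(start // EPOCH_SECONDS),
                            int(np.ceil(end / EPOCH_SECONDS)))
        touched = touched[touched < len(hypnogram)]
        if not sleep_mask[touched].all():
            continue
        if any(start < e + 1.0 and s - 1.0 < end for s, e in intervals):
            continue  # keep >=1 s separation between events
        kind = "apnea" if rng.random() < 0.5 else "hypopnea"
        placed.append(RespiratoryEvent(start, duration, kind))
        intervals.append((start, end))
    return RespiratoryEventList(placed, analysis_duration)


def _event_envelope(
    events: RespiratoryEventList, n_samples: int, sample_rate: float
) -> np.ndarray:
    env = np.ones(n_samples)
    for ev in events:
        i0 = int(round(ev.start * sample_rate))
        i1 = int(round(ev.end * sample_rate))
        factor = _APNEA_FACTOR if ev.kind == "apnea" else _HYPOPNEA_FACTOR
        env[i0:i1] = factor
    return env


def _activity_channel(
    hypnogram: np.ndarray,
    stage_params: dict[str, StageParams],
    sample_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    spe = int(round(EPOCH_SECONDS * sample_rate))  # samples per epoch
    n = len(hypnogram) * spe
    base_amp = min(p.activity_burst_amplitude for p in stage_params.values())
    act = np.abs(rng.normal(0.0, 0.02 * base_amp, size=n))
    t_local = np.arange(spe) / sample_rate
    for e, stage in enumerate(hypnogram):
        p = stage_params[stage]
        n_bursts = rng.poisson(p.activity_burst_rate * EPOCH_SECONDS / 60.0)
        for _ in range(n_bursts):
            center = rng.uniform(0.0, EPOCH_SECONDS)
            width = rng.uniform(0.3, 1.5)
            amp = abs(rng.normal(p.activity_burst_amplitude,
                                 0.3 * p.activity_burst_amplitude))
            bump = amp * np.exp(-0.5 * ((t_local - center) / width) ** 2)
            act[e * spe:(e + 1) * spe] += bump
    return act


def simulate_signals(
    hypnogram: np.ndarray,
    config: SyntheticStudyConfig,
) -> tuple[SignalRecord, RespiratoryEventList]:
    """Render RIP + activity signals and respiratory events for a hypnogram.

    Both belts are breath-by-breath sinusoid trains whose per-breath period
    and amplitude are drawn from the current stage's :class:`StageParams`;
    the abdominal belt is phase-lagged by the stage's coupling parameter.
    Events multiply both belts by 0.05 (apnea) or 0.5 (hypopnea) over their
    span.  Gaussian sensor noise (SD = 5% of the stage's mean amplitude) is
    added last.

    Returns the recording and the reference event list; fully reproducible
    from ``config.seed``.
    """
    hyp = as_hypnogram(hypnogram)
    if len(hyp) != config.n_epochs:
        raise ValueError(
            f"hypnogram has {len(hyp)} epochs but config.n_epochs="
            f"{config.n_epochs}"
        )
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    spe = int(round(EPOCH_SECONDS * fs))
    n_samples = config.n_epochs * spe
    duration = config.n_epochs * EPOCH_SECONDS

    thorax = np.zeros(n_samples)
    abdomen = np.zeros(n_samples)

    # Breath-by-breath synthesis: each breath is one sinusoidal cycle whose
    # period/amplitude come from the stage at the breath's onset.
    t = 0.0
    while t < duration:
        epoch = min(int(t // EPOCH_SECONDS), config.n_epochs - 1)
        p = config.stage_params[hyp[epoch]]
        rate = rng.normal(p.breath_rate_mean, p.breath_rate_sd)
        rate = float(np.clip(rate, 4.0, 40.0))
        breath_dur = 60.0 / rate
        amp_th = max(float(rng.normal(p.amplitude_mean, p.amplitude_sd)), 0.05)
        amp_ab = max(float(rng.normal(p.amplitude_mean, p.amplitude_sd)), 0.05)
        lag = p.thoracoabdominal_phase_lag
        i0 = int(round(t * fs))
        i1 = min(int(round((t + breath_dur) * fs)), n_samples)
        if i1 > i0:
            tau = (np.arange(i0, i1) / fs - t) / breath_dur  # in [0, 1)
            thorax[i0:i1] = amp_th * np.sin(2 * np.pi * tau)
            abdomen[i0:i1] = amp_ab * np.sin(2 * np.pi * tau - lag)
        t += breath_dur

    events = _place_events(hyp, config.target_ahi, duration, rng)
    env = _event_envelope(events, n_samples, fs)
    thorax *= env
    abdomen *= env

    # stage-dependent sensor noise floor
    noise_sd = np.repeat(
        [_NOISE_FRACTION * config.stage_params[s].amplitude_mean for s in hyp],
        spe,
    )
    thorax += rng.normal(0.0, 1.0, n_samples) * noise_sd
    abdomen += rng.normal(0.0, 1.0, n_samples) * noise_sd

    activity = _activity_channel(hyp, config.stage_params, fs, rng)

    record = SignalRecord(thorax, abdomen, activity, fs)
    return record, events


def generate_cohort(
    n_subjects: int,
    ahi_range: tuple[float, float],
    base_config: SyntheticStudyConfig | None = None,
    seed: int = 0,
) -> list[tuple[SignalRecord, np.ndarray, RespiratoryEventList]]:
    """Generate a cohort of synthetic overnight studies.

    Target AHIs are spread evenly across ``ahi_range`` so that all four
    SDB severity groups (<5, 5-15, 15-30, >=30 events/h) are represented
    whenever the range spans them.  Per-subject seeds are derived from the
    master ``seed`` through a spawned :class:`numpy.random.SeedSequence`,
    so cohorts are reproducible element-wise.

    Returns a list of ``(SignalRecord, hypnogram, RespiratoryEventList)``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    lo, hi = ahi_range
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
        raise ValueError(f"invalid ahi_range {ahi_range!r}")
    if base_config is None:
        base_config = SyntheticStudyConfig()

    targets = np.linspace(lo, hi, n_subjects) if n_subjects > 1 else np.array(
        [(lo + hi) / 2.0]
    )
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    cohort = []
    for i, (target, child) in enumerate(zip(targets, children)):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = replace(base_config, target_ahi=float(target), seed=sub_seed)
        hyp = simulate_hypnogram(
            cfg.transition_matrix, cfg.n_epochs, cfg.initial_stage,
            seed=sub_seed,
        )
        record, events = simulate_signals(hyp, cfg)
        record.subject_id = f"S{i:03d}"
        cohort.append((record, hyp, events))
    return cohort
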