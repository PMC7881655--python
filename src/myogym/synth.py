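"""Seedable synthetic surface-EMG generator.

Emulates the recording protocol's inputs without hardware: each movement
has a fixed nonnegative 8-channel activation pattern; a trial multiplies
that pattern by a trapezoidal amplitude envelope (ramp--5 s plateau--ramp
at 30/60/90% of MVC) and by independent per-channel band-limited Gaussian
carriers (20--450 Hz, the usual surface-EMG band, normalized to unit RMS),
plus white baseline noise. The plateau RMS of channel *c* is therefore
``pattern[movement, c] * level`` up to noise, so amplitude ratios across
levels and channels are controlled exactly.

Pattern separability is one dial: ``overlap`` blends each movement's
one-hot channel pattern toward a common uniform pattern (0 = orthogonal
patterns, 1 = identical). ``noise`` and ``amplitude_jitter`` control the
within-movement variability that the consistency metric (WD) sees.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .protocols import trapezoid
from .recording import (
    LEVELS,
    MOVEMENTS,
    N_CHANNELS,
    POSTURES,
    REST,
    EmgRecording,
    Procedure,
)


def movement_patterns(overlap: float = 0.0) -> np.ndarray:
    """The 7 x 8 channel-activation matrix at a given pattern overlap.

    Row i is ``(1 - overlap) * e_i + overlap * 1``: one-hot per movement at
    overlap 0 (mutually orthogonal), identical rows at overlap 1.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must be in [0, 1]")
    base = np.zeros((len(MOVEMENTS), N_CHANNELS))
    base[np.arange(len(MOVEMENTS)), np.arange(len(MOVEMENTS))] = 1.0
    return (1.0 - overlap) * base + overlap * np.ones_like(base)


@dataclass
class GeneratorParams:
    """Study-condition knobs of the synthetic-EMG generator.

    ``noise`` and ``amplitude_jitter`` are fractions of the unit-RMS
    carrier amplitude; ``overlap`` blends movement patterns toward
    identical. The defaults describe a cooperative subject with moderately
    distinct movements.
    """

    seed: int
    fs: float = 1000.0
    overlap: float = 0.2
    noise: float = 0.05
    amplitude_jitter: float = 0.1
    carrier_band: tuple[float, float] = (20.0, 450.0)
    ramp_s: float = 1.0
    plateau_s: float = 5.0
    patterns: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.patterns is None:
            self.patterns = movement_patterns(self.overlap)
        self.patterns = np.asarray(self.patterns, float)
        if self.patterns.shape != (len(MOVEMENTS), N_CHANNELS):
            raise ValueError(
                f"patterns must be {(len(MOVEMENTS), N_CHANNELS)}, "
                f"got {self.patterns.shape}"
            )
        if np.any(self.patterns < 0):
            raise ValueError("pattern weights must be nonnegative")


def _carriers(n: int, params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Independent unit-RMS band-limited Gaussian carriers, shape (n, 8)."""
    lo, hi = params.carrier_band
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=params.fs, output="sos")
    white = rng.standard_normal((n, N_CHANNELS))
    x = sps.sosfiltfilt(sos, white, axis=0)
    rms = np.sqrt(np.mean(x * x, axis=0))
    return x / np.where(rms > 0, rms, 1.0)


def generate_recording(
    movement: str,
    level: float,
    params: GeneratorParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    posture: str = "armrest",
    recorded_at: str | None = None,
) -> EmgRecording:
    """One synthetic trapezoid-tracked trial (or rest, for level 0).

    Channel c is ``pattern[movement, c] * envelope(t) * carrier_c(t) +
    noise * n_c(t)``; the envelope is attached as the recording's force
    reference. Identical seeds give identical signals.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    if movement == REST:
        n = round((params.ramp_s * 2 + params.plateau_s) * params.fs)
        envelope = np.zeros(n)
        weights = np.zeros(N_CHANNELS)
        level = 0.0
    else:
        idx = MOVEMENTS.index(movement)
        weights = params.patterns[idx]
        envelope = trapezoid(
            level, plateau_s=params.plateau_s, ramp_s=params.ramp_s, fs=params.fs
        )
        n = envelope.size
    carriers = _carriers(n, params, rng)
    jitter = 1.0
    if params.amplitude_jitter > 0:
        jitter = max(0.1, 1.0 + params.amplitude_jitter * rng.standard_normal())
    signal = (jitter * envelope[:, None] * weights[None, :]) * carriers
    if params.noise > 0:
        signal = signal + params.noise * rng.standard_normal((n, N_CHANNELS))
    return EmgRecording(
        signal=signal,
        fs=params.fs,
        movement=movement,
        level=level,
        posture=posture,
        reference=envelope,
        recorded_at=recorded_at,
    )


def generate_procedure(
    index: int,
    params: GeneratorParams,
    movements: Sequence[str],
    rng: np.random.Generator,
    posture: str | None = None,
    levels: Sequence[float] = LEVELS,
    include_rest: bool = False,
) -> Procedure:
    """One recording procedure: per movement an MVC baseline then one
    trapezoid trial per graded level, all in one posture."""
    posture = posture or POSTURES[index % len(POSTURES)]
    recs = []
    for m in movements:
        recs.append(generate_recording(
            m, 1.0, params, rng=rng, posture=posture,
            recorded_at=f"procedure{index:02d}/{m}_mvc",
        ))
        for lvl in levels:
            recs.append(generate_recording(
                m, lvl, params, rng=rng, posture=posture,
                recorded_at=f"procedure{index:02d}/{m}_{int(lvl * 100):02d}",
            ))
    if include_rest:
        recs.append(generate_recording(
            REST, 0.0, params, rng=rng, posture=posture,
            recorded_at=f"procedure{index:02d}/rest",
        ))
    return Procedure(index=index, posture=posture, recordings=recs)


def generate_session(
    params: GeneratorParams,
    movements: Sequence[str],
    n_procedures: int = 5,
    levels: Sequence[float] = LEVELS,
    include_rest: bool = False,
) -> list[Procedure]:
    """An ordered series of recording procedures with postures cycling
    hanging -> armrest -> reaching, reproducible from ``params.seed``."""
    ss = np.random.SeedSequence(params.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(n_procedures)]
    return [
        generate_procedure(i, params, movements, rngs[i],
                           levels=levels, include_rest=include_rest)
        for i in range(n_procedures)
    ]
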