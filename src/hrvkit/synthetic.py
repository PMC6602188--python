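"""Synthetic RR-interval generation.

Beats are generated with an integral pulse frequency modulation (IPFM)
model: an instantaneous heart rate

    r(t) = (1000 / mean_ibi) · (1 + a_lf sin(2π f_lf t)
                                  + a_hf sin(2π f_hf t + φ))

is integrated and a beat emitted each time the integral crosses an
integer. The LF (≈0.1 Hz) and HF (≈0.25 Hz) modulation depths place
oscillatory power at exactly known band fractions, giving the analysis
pipeline a ground truth to recover: to first order in the depths the
normalized LF power is a_lf² / (a_lf² + a_hf²). Beat-to-beat Gaussian
noise, a linear slow trend and injected ectopic beats emulate the
artifacts the preprocessing stages must handle.

Paired-cohort simulation draws per-subject parameters around an "off"
and an "on" condition template; the defaults mirror the direction of
the stimulation effect in the study cohort this package analyzes
(higher heart rate and LF dominance with stimulation off, longer
intervals and more HF power with stimulation on).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .rr_io import RRRecording

__all__ = [
    "AutonomicState",
    "OFF_STATE",
    "ON_STATE",
    "simulate_rr",
    "inject_artifacts",
    "simulate_cohort",
    "theoretical_band_fractions",
]


@dataclass(frozen=True)
class AutonomicState:
    """Generator parameters for one subject/condition.

    Modulation depths are proportions of the mean rate; ``noise_sd`` is
    the per-beat Gaussian jitter in ms; ``trend_slope`` a linear drift
    in ms per second; ``ectopic_rate`` premature beats per minute.
    """

    mean_ibi: float = 900.0  # ms
    a_lf: float = 0.05
    a_hf: float = 0.04
    f_lf: float = 0.1  # Hz
    f_hf: float = 0.25  # Hz
    noise_sd: float = 25.0  # ms
    trend_slope: float = 0.0  # ms/s
    ectopic_rate: float = 0.0  # per minute
    hf_phase: float = np.pi / 3

    def __post_init__(self):
        if not 400 <= self.mean_ibi <= 1500:
            raise ValueError("mean_ibi must lie in [400, 1500] ms")
        for name, depth in (("a_lf", self.a_lf), ("a_hf", self.a_hf)):
            if not 0 <= depth <= 0.4:
                raise ValueError(f"{name} must lie in [0, 0.4]")
        if not 0.04 <= self.f_lf < 0.15:
            raise ValueError("f_lf must lie in the LF band [0.04, 0.15)")
        if not 0.15 <= self.f_hf <= 0.4:
            raise ValueError("f_hf must lie in the HF band [0.15, 0.4]")


# Condition templates for the paired crossover design: "off" shows
# faster rate and LF dominance (normalized LF ~0.61), "on" longer
# intervals and a near-balanced spectrum (~0.52).
OFF_STATE = AutonomicState(mean_ibi=910.0, a_lf=0.050, a_hf=0.040)
ON_STATE = AutonomicState(mean_ibi=975.0, a_lf=0.048, a_hf=0.046)


def simulate_rr(
    state: AutonomicState,
    duration_s: float = 300.0,
    seed: Optional[int] = None,
    subject_id: Optional[str] = None,
    condition: Optional[str] = None,
) -> RRRecording:
    """Generate an RR recording from the IPFM model.

    The modulated rate is integrated on a 1 ms grid; beat times are the
    interpolated integer crossings of the integral. Noise and trend are
    added per interval afterwards. Reproducible from ``seed``.
    """
    if duration_s < 60:
        raise ValueError("duration must be at least 60 s")
    if state.a_lf + state.a_hf >= 1:
        raise ValueError("total modulation depth must stay below 1")
    rng = np.random.default_rng(seed)
    dt = 0.001
    t = np.arange(0.0, duration_s + dt, dt)
    rate = (1000.0 / state.mean_ibi) * (
        1.0
        + state.a_lf * np.sin(2 * np.pi * state.f_lf * t)
        + state.a_hf * np.sin(2 * np.pi * state.f_hf * t + state.hf_phase)
    )
    integral = np.concatenate([[0.0], np.cumsum((rate[1:] + rate[:-1]) / 2.0 * dt)])
    n_beats = int(np.floor(integral[-1]))
    if n_beats < 2:
        raise ValueError("rate too low for the requested duration")
    beat_times = np.interp(np.arange(1, n_beats + 1), integral, t)
    rr = np.diff(np.concatenate([[0.0], beat_times])) * 1000.0
    if state.noise_sd > 0:
        rr = rr + rng.normal(0.0, state.noise_sd, rr.size)
    if state.trend_slope != 0:
        rr = rr + state.trend_slope * beat_times
    rr = np.maximum(rr, 1.0)  # noise must not produce non-physical intervals
    rec = RRRecording(
        intervals=rr, subject_id=subject_id, condition=condition
    )
    if state.ectopic_rate > 0:
        rec, _ = inject_artifacts(rec, state.ectopic_rate, seed=rng.integers(2**31))
    return rec


def inject_artifacts(
    rec: RRRecording, ectopic_rate: float, seed: Optional[int] = None
) -> Tuple[RRRecording, np.ndarray]:
    """Inject premature-beat artifacts; returns (recording, positions).

    Each event splits a beat into a 40 %-early interval followed by a
    compensatory long interval, conserving total time exactly. Returned
    positions are the indices of the short intervals in the new series.
    """
    if ectopic_rate < 0:
        raise ValueError("rate must be non-negative")
    if ectopic_rate == 0:
        return rec, np.zeros(0, dtype=int)
    rng = np.random.default_rng(seed)
    n_events = int(round(ectopic_rate * rec.duration_s / 60.0))
    n_events = min(n_events, rec.n_beats // 4)
    if n_events == 0:
        return rec, np.zeros(0, dtype=int)
    # leave the edges alone so median-filter neighborhoods stay sane
    candidates = np.arange(2, rec.n_beats - 2)
    chosen = np.sort(rng.choice(candidates, size=n_events, replace=False))
    # keep events non-adjacent
    keep = np.concatenate([[True], np.diff(chosen) > 2])
    chosen = chosen[keep]
    out: List[float] = []
    positions: List[int] = []
    idx_set = set(chosen.tolist())
    for i, v in enumerate(rec.intervals):
        if i in idx_set:
            positions.append(len(out))
            out.append(0.6 * v)
            out.append(0.4 * v + rec.intervals[min(i + 1, rec.n_beats - 1)])
        elif (i - 1) in idx_set:
            continue  # consumed by the compensatory interval
        else:
            out.append(float(v))
    new = replace(rec, intervals=np.array(out))
    return new, np.array(positions, dtype=int)


def theoretical_band_fractions(state: AutonomicState) -> Tuple[float, float]:
    """First-order normalized LF/HF fractions of the generator.

    Valid in the small-modulation regime (depths ≤ 0.2): the RR
    modulation amplitude at each frequency is proportional to the
    depth, so band power splits as the squared depths.
    """
    if state.a_lf == 0 and state.a_hf == 0:
        raise ValueError("band fractions undefined without modulation")
    if max(state.a_lf, state.a_hf) > 0.2:
        raise ValueError("first-order approximation needs depths <= 0.2")
    total = state.a_lf**2 + state.a_hf**2
    return state.a_lf**2 / total, state.a_hf**2 / total


def _perturb(state: AutonomicState, rng: np.random.Generator, rel_sd: float) -> AutonomicState:
    draw = lambda v: v * float(np.exp(rng.normal(0.0, rel_sd)))
    return replace(
        state,
        mean_ibi=float(np.clip(draw(state.mean_ibi), 400, 1500)),
        a_lf=float(np.clip(draw(state.a_lf), 0.0, 0.4)),
        a_hf=float(np.clip(draw(state.a_hf), 0.0, 0.4)),
    )


def simulate_cohort(
    n_subjects: int = 22,
    off_state: AutonomicState = OFF_STATE,
    on_state: AutonomicState = ON_STATE,
    between_subject_sd: float = 0.08,
    within_subject_sd: float = 0.02,
    duration_s: float = 300.0,
    seed: Optional[int] = None,
    generate_recordings: bool = True,
) -> Tuple[Dict[Tuple[str, str], RRRecording], pd.DataFrame]:
    """Simulate a paired off/on cohort.

    Each subject gets a multiplicative parameter draw shared by both
    conditions (log-normal, ``between_subject_sd``) applied to the two
    condition templates, plus an independent per-condition draw
    (``within_subject_sd``) standing for visit-to-visit variability.
    Returns ``(recordings, truth)``: recordings keyed by
    ``(subject_id, condition)`` (empty when ``generate_recordings`` is
    False) and the realized per-subject parameter table with the
    first-order band fractions as ground truth.
    """
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects")
    rng = np.random.default_rng(seed)
    recordings: Dict[Tuple[str, str], RRRecording] = {}
    rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        subject_factor = rng.normal(0.0, between_subject_sd)
        for condition, template in (("off", off_state), ("on", on_state)):
            state = _perturb(
                replace(
                    template,
                    mean_ibi=float(
                        np.clip(template.mean_ibi * np.exp(subject_factor), 400, 1500)
                    ),
                ),
                rng,
                within_subject_sd,
            )
            row = {
                "subject_id": sid,
                "condition": condition,
                "mean_ibi": state.mean_ibi,
                "a_lf": state.a_lf,
                "a_hf": state.a_hf,
                "noise_sd": state.noise_sd,
            }
            if state.a_lf > 0 or state.a_hf > 0:
                nlf, nhf = theoretical_band_fractions(state)
                row["nlf_true"], row["nhf_true"] = nlf, nhf
            rows.append(row)
            if generate_recordings:
                recordings[(sid, condition)] = simulate_rr(
                    state,
                    duration_s=duration_s,
                    seed=int(rng.integers(2**31)),
                    subject_id=sid,
                    condition=condition,
                )
    truth = pd.DataFrame(rows)
    return recordings, truth
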