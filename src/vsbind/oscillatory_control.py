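"""Oscillator-gated scheduling of binding operations.

Ideal sampled sinusoids stand in for self-excited neural populations.
Their role is purely *control*: an upward threshold crossing of the fast
(gate) oscillation triggers one discrete binding operation; two gates in
antiphase segregate operation streams so they never co-fire; and the
phase of a slower, stimulus-entrained oscillation — not its amplitude —
is read out as the boundary-relative ordinal position of each committed
item (a functional use of phase–amplitude coupling).  Time is unitless
discrete steps.

The scheduler changes *when* bindings happen, never *what* is encoded:
:func:`gated_encode` produces a trace bit-identical to the static
:func:`~vsbind.sequence_memory.encode_sequence` on the same ordered tokens.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import CollisionError, ParameterError
from .hrr_core import Vocabulary
from .positional_tags import TagSet
from .sequence_memory import DEFAULT_GAMMA, DEFAULT_RHO, SequenceTrace, encode_sequence

__all__ = [
    "GateEvent",
    "oscillator_signal",
    "run_oscillator",
    "antisynchronous_pair",
    "phase_to_position",
    "gate_schedule",
    "gated_encode",
    "phase_concentration",
]


@dataclass(frozen=True)
class GateEvent:
    """One discrete control event emitted by an oscillator."""

    time_step: int
    source: str
    kind: str = "trigger"  # trigger | gain_on | gain_off
    decoded_order: int | None = None


def _check_freq(freq: float) -> None:
    if not (0.0 < freq < 0.5):
        raise ParameterError(f"freq must be in (0, 0.5) cycles/step (Nyquist), got {freq}")


def oscillator_signal(
    freq: float, steps: int, phase0: float = 0.0, amplitude: float = 1.0
) -> np.ndarray:
    """amplitude * sin(2*pi*freq*t + phase0) sampled at t = 0..steps-1."""
    _check_freq(freq)
    if steps < 1:
        raise ParameterError(f"steps must be >= 1, got {steps}")
    t = np.arange(steps)
    return amplitude * np.sin(2.0 * np.pi * freq * t + phase0)


def run_oscillator(
    freq: float,
    threshold: float = 0.0,
    steps: int = 100,
    phase0: float = 0.0,
    amplitude: float = 1.0,
    source: str = "P1",
) -> list[GateEvent]:
    """Trigger events at upward threshold crossings of the sampled sinusoid.

    A step t fires when signal(t-1) < threshold <= signal(t); the virtual
    sample at t = -1 is evaluated analytically so a crossing at t = 0 counts.
    """
    s = oscillator_signal(freq, steps, phase0, amplitude)
    prev = np.empty(steps)
    prev[0] = amplitude * np.sin(2.0 * np.pi * freq * (-1.0) + phase0)
    prev[1:] = s[:-1]
    fire = (prev < threshold) & (s >= threshold)
    return [GateEvent(int(t), source, "trigger") for t in np.nonzero(fire)[0]]


def antisynchronous_pair(
    freq: float, steps: int, threshold: float = 0.0
) -> tuple[list[GateEvent], list[GateEvent]]:
    """Two gate streams offset by pi: the crossings interleave and can never
    share a time step, segregating the operations they trigger."""
    if steps == 0:
        return [], []
    p1 = run_oscillator(freq, threshold, steps, phase0=0.0, source="P1")
    p2 = run_oscillator(freq, threshold, steps, phase0=np.pi, source="P2")
    return p1, p2


def phase_to_position(phase: float, K: int) -> int:
    """Map an oscillator phase to one of K equal bins -> ordinal order 1..K.

    Boundary-relative: the phase bin (position within the cycle anchored at
    the chunk boundary), not absolute time, determines the tag index.
    """
    if K < 1:
        raise ParameterError(f"K must be >= 1, got {K}")
    wrapped = float(np.mod(phase, 2.0 * np.pi))
    return min(K, 1 + int(np.floor(K * wrapped / (2.0 * np.pi))))


def gate_schedule(
    onsets: Sequence[int],
    freq: float,
    steps: int | None = None,
    threshold: float = 0.0,
    source: str = "gate",
) -> list[GateEvent]:
    """Commit schedule for stimuli arriving at the given onsets.

    Each stimulus is committed at the first gate trigger at or after its
    onset; its ordinal order is decoded from the phase of a slow oscillator
    at freq/K that is entrained (phase-reset) at the first commit.  Two
    stimuli claiming the same trigger raise a collision error.
    """
    onsets = [int(o) for o in onsets]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise ParameterError("onsets must be strictly increasing")
    if len(onsets) == 0:
        return []
    K = len(onsets)
    if steps is None:
        steps = onsets[-1] + int(np.ceil(2.0 / freq)) + 1
    if onsets[-1] >= steps:
        raise ParameterError("every onset must lie within the simulated horizon")
    triggers = [e.time_step for e in run_oscillator(freq, threshold, steps)]
    commits = []
    used: set[int] = set()
    for onset in onsets:
        t = next((tt for tt in triggers if tt >= onset), None)
        if t is None:
            raise ParameterError(
                f"no gate trigger at or after onset {onset} within {steps} steps"
            )
        if t in used:
            raise CollisionError(
                f"two stimuli map to the gate trigger at t={t}; increase the gate frequency"
            )
        used.add(t)
        commits.append(t)
    t0 = commits[0]
    slow = freq / K
    events = []
    for t in commits:
        phase = 2.0 * np.pi * slow * (t - t0)
        events.append(GateEvent(t, source, "trigger", phase_to_position(phase, K)))
    return events


def gated_encode(
    tokens: Sequence[str],
    onsets: Sequence[int],
    freq: float,
    vocab: Vocabulary,
    tags: TagSet,
    gamma: float = DEFAULT_GAMMA,
    rho: float = DEFAULT_RHO,
    steps: int | None = None,
    threshold: float = 0.0,
) -> tuple[SequenceTrace, list[GateEvent]]:
    """Oscillator-scheduled sequence encoding.

    Each token's position (x) item binding is committed at its gate trigger
    with the order index decoded from the entrained slow phase.  The final
    trace is bit-identical to the static encoder on the same ordered tokens
    (the dynamic/static equivalence contract).  Returns (trace, events).
    """
    tokens = list(tokens)
    if len(tokens) != len(onsets):
        raise ParameterError(f"{len(tokens)} tokens but {len(onsets)} onsets")
    if len(tokens) == 0:
        return encode_sequence([], vocab, tags, gamma, rho), []
    events = gate_schedule(onsets, freq, steps, threshold)
    orders = [e.decoded_order for e in events]
    if sorted(orders) != list(range(1, len(tokens) + 1)):
        raise CollisionError(
            f"decoded phase orders {orders} are not a permutation of 1..{len(tokens)}; "
            "the stimulus rate does not match the gate rate"
        )
    by_order = [name for _, name in sorted(zip(orders, tokens))]
    return encode_sequence(by_order, vocab, tags, gamma, rho), events


def phase_concentration(events: Sequence[GateEvent], slow_freq: float, phase0: float = 0.0) -> float:
    """Resultant length of gate-event phases on a slow cycle, in [0, 1].

    Values near 1 mean the fast gate fires at one fixed phase of the slow
    oscillation — phase–amplitude coupling as a functional property.
    """
    if len(events) == 0:
        raise ParameterError("phase_concentration needs at least one event")
    phases = np.array([2.0 * np.pi * slow_freq * e.time_step + phase0 for e in events])
    return float(np.abs(np.mean(np.exp(1j * phases))))
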