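"""Example target shapes.

The four radial-frequency targets (high-frequency, low-frequency,
bumpy-brick, twisted-plus) are hand-written approximations in the spirit
of the originals -- each has non-zero amplitude on two to four
frequencies, gates all on, amplitudes in the same bookkeeping units as
random distractors.  They are NOT reconstructions of the original
parameter values, which were published only graphically.

The rabbit-like silhouette is a synthetic body + head + two-ears radius
function sampled at 360 points; a faithful polar reconstruction of it
requires the full run of radial frequencies, which is what makes it a
useful naturalistic target.
"""

from __future__ import annotations

import numpy as np

from .genome import N_FREQUENCIES, RFGenome
from .synthesis import ShapeContour, SynthConfig

__all__ = ["example_target", "rabbit_silhouette", "TARGET_NAMES"]

TARGET_NAMES = ("HF", "LF", "BB", "TP")

# frequency (1-based) -> (amplitude, phase degrees); approximations only
_TARGET_SPECS: dict[str, dict[int, tuple[float, float]]] = {
    # high-frequency: fine lobes from the top of the frequency range
    "HF": {8: 12.0, 10: 8.0},
    # low-frequency: a slow two-three lobed blob
    "LF": {2: 45.0, 3: 22.0},
    # bumpy brick: an elongated body (f=2) carrying fine bumps (f=6)
    "BB": {2: 45.0, 6: 14.0},
    # twisted plus: four lobes (f=4) with a higher-harmonic twist
    "TP": {4: 35.0, 8: 9.0},
}
_TARGET_PHASES = {"HF": (90.0, 30.0), "LF": (90.0, 200.0), "BB": (90.0, 45.0), "TP": (90.0, 135.0)}


def example_target(name: str) -> RFGenome:
    """A named example target genome (approximate HF/LF/BB/TP analogue).

    Gates are all on; inactive frequencies simply carry zero amplitude,
    so the active set is exactly the non-zero-amplitude set.
    """
    name = name.upper()
    if name not in _TARGET_SPECS:
        raise KeyError(f"unknown target {name!r}; choose from {TARGET_NAMES}")
    amps = np.zeros(N_FREQUENCIES)
    phases = np.full(N_FREQUENCIES, 360.0)
    for (freq, amp), phase in zip(_TARGET_SPECS[name].items(), _TARGET_PHASES[name]):
        amps[freq - 1] = amp
        phases[freq - 1] = phase
    return RFGenome(
        amplitudes=amps,
        phases=phases,
        gates=np.ones(N_FREQUENCIES, dtype=int),
        id=f"target-{name}",
    )


def _bump(theta: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    """Smooth angular bump (wrapped Gaussian) for silhouette construction."""
    d = np.angle(np.exp(1j * (theta - center)))
    return height * np.exp(-0.5 * (d / width) ** 2)


def rabbit_silhouette(cfg: SynthConfig = SynthConfig(), n_points: int | None = None) -> ShapeContour:
    """Synthetic rabbit-like silhouette: body, head bump and two long ears.

    Star-shaped (radius is a single-valued function of angle), sampled at
    n_points angles, scaled so the mean radius equals cfg.base_radius.
    """
    n = n_points or cfg.n_points
    theta = 2 * np.pi * np.arange(n) / n
    r = np.ones(n)
    r += _bump(theta, np.pi / 2 + 0.45, 0.16, 1.15)  # left ear
    r += _bump(theta, np.pi / 2 - 0.45, 0.16, 1.15)  # right ear
    r += _bump(theta, np.pi / 2, 0.55, 0.25)  # head
    r += _bump(theta, -np.pi / 2, 1.1, 0.35)  # haunches
    r *= cfg.base_radius / r.mean()
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return ShapeContour(points=pts, source="rabbit-synthetic", base_radius=cfg.base_radius)
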