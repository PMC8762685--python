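"""Radial-frequency (RF) genomes.

An RF distractor shape is parameterized by a 30-element "genome": for each
of 10 integer radial frequencies, an amplitude (internal bookkeeping units),
a phase in degrees, and a binary on/off gate.  Gating a frequency off is
equivalent to setting its amplitude to zero in the synthesized shape, but
the latent amplitude is retained so evolution can re-activate it.

Initialization follows an approximate 1/f amplitude law: the amplitude at
frequency f is drawn uniformly from [amp_low, amp_high] and divided by f,
so frequency 1 spans 50-150 (defaults), frequency 2 spans 25-75, and so on.
"""

from __future__ import annotations

import json
import logging
import uuid
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "N_FREQUENCIES",
    "RFGenome",
    "AmplitudeSpectrum",
    "InitConfig",
    "random_genome",
    "effective_spectrum",
    "read_genome",
    "write_genome",
    "read_population",
    "write_population",
]

logger = logging.getLogger(__name__)

#: Number of radial frequencies in a genome (frequencies 1..10).
N_FREQUENCIES = 10


class GenomeError(ValueError):
    """Raised for invalid genome definitions or malformed genome files."""


@dataclass(frozen=True)
class RFGenome:
    """One distractor shape in radial-frequency space.

    Parameters
    ----------
    amplitudes : ndarray, shape (10,)
        Non-negative modulation amplitudes, one per radial frequency 1..10,
        in internal units (100 units == one base radius after synthesis
        scaling).
    phases : ndarray, shape (10,)
        Phases in degrees, each in (0, 360].
    gates : ndarray, shape (10,)
        Binary flags; a gated-off frequency contributes nothing to the
        synthesized contour.
    id : str
        Opaque identifier (UUID hex by default).
    lineage : tuple of str
        Parent genome ids, empty for randomly initialized genomes.
    """

    amplitudes: np.ndarray
    phases: np.ndarray
    gates: np.ndarray
    id: str = field(default_factory=lambda: uuid.uuid4().hex)
    lineage: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        phases = np.asarray(self.phases, dtype=float)
        gates = np.asarray(self.gates, dtype=int)
        for name, arr in (("amplitudes", amps), ("phases", phases), ("gates", gates)):
            if arr.shape != (N_FREQUENCIES,):
                raise GenomeError(
                    f"{name} must have exactly {N_FREQUENCIES} entries, got shape {arr.shape}"
                )
        if np.any(amps < 0):
            raise GenomeError("amplitudes must be non-negative")
        if np.any((phases <= 0) | (phases > 360)):
            raise GenomeError("phases must lie in (0, 360] degrees")
        if not np.isin(gates, (0, 1)).all():
            raise GenomeError("gates must be binary")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "phases", phases)
        object.__setattr__(self, "gates", gates)
        object.__setattr__(self, "lineage", tuple(self.lineage))

    def with_id(self, new_id: str, lineage: tuple[str, ...] | None = None) -> "RFGenome":
        return replace(self, id=new_id, lineage=self.lineage if lineage is None else lineage)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RFGenome):
            return NotImplemented
        return (
            np.array_equal(self.amplitudes, other.amplitudes)
            and np.array_equal(self.phases, other.phases)
            and np.array_equal(self.gates, other.gates)
            and self.id == other.id
            and self.lineage == other.lineage
        )


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """Radial Fourier amplitude spectrum, indexed by frequency 1..K.

    ``amps[k]`` is the amplitude at radial frequency ``k + 1``.  Genome
    spectra have K = 10; silhouette spectra may run up to K = n_points - 1.
    """

    amps: np.ndarray

    def __post_init__(self) -> None:
        amps = np.asarray(self.amps, dtype=float)
        if amps.ndim != 1 or amps.size < 1:
            raise GenomeError("spectrum must be a non-empty 1-D vector")
        if np.any(amps < 0):
            raise GenomeError("spectrum amplitudes must be non-negative")
        object.__setattr__(self, "amps", amps)

    def __len__(self) -> int:
        return self.amps.size


@dataclass(frozen=True)
class InitConfig:
    """Random-initialization settings for generation-1 distractor pools."""

    amp_low: float = 50.0
    amp_high: float = 150.0
    phase_low: float = 1.0
    phase_high: float = 360.0
    n_freq: int = N_FREQUENCIES
    gate_on_prob: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.amp_low < self.amp_high:
            raise GenomeError("amp_low must be < amp_high")
        if not self.phase_low < self.phase_high:
            raise GenomeError("phase_low must be < phase_high")
        if self.n_freq < 1:
            raise GenomeError("n_freq must be >= 1")
        if not 0.0 <= self.gate_on_prob <= 1.0:
            raise GenomeError("gate_on_prob must be a probability")


def random_genome(cfg: InitConfig = InitConfig(), rng: np.random.Generator | None = None) -> RFGenome:
    """Draw one random genome.

    Amplitude at frequency f is Uniform(amp_low, amp_high) / f (an
    approximate 1/f spectrum); phase is Uniform(phase_low, phase_high)
    degrees; each gate is Bernoulli(gate_on_prob).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    freqs = np.arange(1, cfg.n_freq + 1, dtype=float)
    amps = rng.uniform(cfg.amp_low, cfg.amp_high, cfg.n_freq) / freqs
    phases = rng.uniform(cfg.phase_low, cfg.phase_high, cfg.n_freq)
    gates = (rng.random(cfg.n_freq) < cfg.gate_on_prob).astype(int)
    if cfg.n_freq != N_FREQUENCIES:  # pad/truncate to the canonical genome length
        amps = np.resize(amps, N_FREQUENCIES)
        phases = np.clip(np.resize(phases, N_FREQUENCIES), 1e-9, 360.0)
        gates = np.resize(gates, N_FREQUENCIES)
    return RFGenome(amplitudes=amps, phases=phases, gates=gates)


def effective_spectrum(g: RFGenome) -> AmplitudeSpectrum:
    """Gated amplitude spectrum: amps[f] = gate[f] * amplitude[f]."""
    return AmplitudeSpectrum(amps=g.gates * g.amplitudes)


# ---------------------------------------------------------------------------
# JSON serialization


_REQUIRED_KEYS = ("amplitudes", "phases", "gates")


def _genome_to_dict(g: RFGenome) -> dict:
    return {
        "amplitudes": g.amplitudes.tolist(),
        "phases": g.phases.tolist(),
        "gates": g.gates.tolist(),
        "id": g.id,
        "lineage": list(g.lineage),
    }


def _genome_from_dict(obj: dict, source: str = "<genome>") -> RFGenome:
    if not isinstance(obj, dict):
        raise GenomeError(f"{source}: genome record must be a JSON object")
    for key in _REQUIRED_KEYS:
        if key not in obj:
            raise GenomeError(f"{source}: missing required field '{key}'")
    known = set(_REQUIRED_KEYS) | {"id", "lineage"}
    extra = set(obj) - known
    if extra:
        logger.warning("%s: ignoring unknown genome fields %s", source, sorted(extra))
    try:
        return RFGenome(
            amplitudes=np.asarray(obj["amplitudes"], dtype=float),
            phases=np.asarray(obj["phases"], dtype=float),
            gates=np.asarray(obj["gates"], dtype=int),
            id=str(obj.get("id", uuid.uuid4().hex)),
            lineage=tuple(obj.get("lineage") or ()),
        )
    except (TypeError, ValueError) as exc:
        raise GenomeError(f"{source}: {exc}") from exc


def write_genome(g: RFGenome, path: str | Path) -> None:
    """Write one genome as a JSON object."""
    Path(path).write_text(json.dumps(_genome_to_dict(g), indent=2) + "\n")


def read_genome(path: str | Path) -> RFGenome:
    """Read one genome from a JSON file written by :func:`write_genome`."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GenomeError(f"{path}: not valid JSON ({exc})") from exc
    return _genome_from_dict(obj, source=str(path))


def write_population(genomes: list[RFGenome], path: str | Path) -> None:
    """Write a list of genomes as a JSON array."""
    Path(path).write_text(
        json.dumps([_genome_to_dict(g) for g in genomes], indent=2) + "\n"
    )


def read_population(path: str | Path) -> list[RFGenome]:
    path = Path(path)
    try:
        arr = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise GenomeError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(arr, list):
        raise GenomeError(f"{path}: population file must hold a JSON array")
    return [_genome_from_dict(obj, source=f"{path}[{i}]") for i, obj in enumerate(arr)]
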