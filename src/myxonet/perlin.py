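"""One-dimensional gradient (Perlin-style) fractal noise.

Each agent steers with two independent noise streams, one per Cartesian
component.  A stream is a deterministic function of (master seed,
stream id, frame): integer lattice points get pseudo-random gradients
in [-1, 1] from a hash, and values between lattice points are smoothly
interpolated with the quintic fade curve, so consecutive samples are
correlated — the "memory" that makes foraging paths smooth rather than
a jittery uncorrelated walk.

Fractal noise sums several octaves: each successive octave doubles the
sampling frequency and halves the range.  With first-octave range
[-A, A] the sum over k octaves is bounded by A * sum(2**-k) < 2A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_U64 = np.uint64


def _mix(z: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer: avalanche an unsigned 64-bit integer array."""
    z = (z + _U64(0x9E3779B97F4A7C15)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(0xFFFFFFFFFFFFFFFF)
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(0xFFFFFFFFFFFFFFFF)
    return z ^ (z >> _U64(31))


def _gradient(ix: np.ndarray, stream: np.ndarray, seed: int, octave: int) -> np.ndarray:
    """Pseudo-random gradient in [-1, 1) at integer lattice point ``ix``."""
    with np.errstate(over="ignore"):
        h = _mix(
            ix.astype(np.int64).view(_U64) * _U64(0xD6E8FEB86659FD93)
            ^ _mix(stream.astype(np.int64).view(_U64))
            ^ _mix(np.asarray(seed * 2654435761 + octave, dtype=np.int64).view(_U64))
        )
    return (h >> _U64(11)).astype(float) * (1.0 / 2**53) * 2.0 - 1.0


def _fade(t: np.ndarray) -> np.ndarray:
    return t * t * t * (t * (t * 6.0 - 15.0) + 10.0)


def perlin1d(x: np.ndarray, stream: np.ndarray, seed: int, octave: int = 0) -> np.ndarray:
    """Single-octave 1-D gradient noise, range [-1, 1]."""
    x, stream = np.broadcast_arrays(
        np.asarray(x, dtype=float), np.asarray(stream, dtype=np.int64)
    )
    xi = np.floor(x)
    f = x - xi
    xi = xi.astype(np.int64)
    g0 = _gradient(xi, stream, seed, octave)
    g1 = _gradient(xi + 1, stream, seed, octave)
    u = _fade(f)
    # lerp of the two gradient ramps; max |value| = 0.5 at f = 0.5, so x2
    return 2.0 * ((1.0 - u) * g0 * f + u * g1 * (f - 1.0))


def fractal_noise(
    t: float | np.ndarray,
    stream: int | np.ndarray,
    seed: int,
    base_frequency: float = 0.01,
    octaves: int = 4,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Sum of ``octaves`` noise layers; frequency x2, range /2 per layer.

    Deterministic in (seed, stream, t); bounded by ±2*amplitude.
    """
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    t = np.asarray(t, dtype=float)
    stream = np.asarray(stream, dtype=np.int64)
    out = np.zeros(np.broadcast_shapes(t.shape, stream.shape), dtype=float)
    freq = base_frequency
    amp = amplitude
    for k in range(octaves):
        out = out + amp * perlin1d(t * freq, stream, seed, octave=k)
        freq *= 2.0
        amp *= 0.5
    return out


@dataclass(frozen=True)
class NoiseStream:
    """Handle for one seeded 1-D fractal-noise stream.

    Convenience wrapper for per-agent use; the vectorised simulation
    calls :func:`fractal_noise` over arrays of stream ids directly.
    """

    seed: int
    stream_id: int
    base_frequency: float = 0.01
    octaves: int = 4
    amplitude: float = 1.0

    def sample(self, t: float | np.ndarray) -> float | np.ndarray:
        val = fractal_noise(
            t,
            self.stream_id,
            self.seed,
            base_frequency=self.base_frequency,
            octaves=self.octaves,
            amplitude=self.amplitude,
        )
        return float(val) if np.isscalar(t) or np.ndim(t) == 0 else val
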