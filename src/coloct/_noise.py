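"""Counter-based procedural random fields.

The speckle-forming scatterer field and the backscatter heterogeneity of a
phantom must be a deterministic function of *position in the tissue*, not of
the beam that happens to interrogate it: two scan lanes crossing the same
voxel have to see the same sub-resolution scatterers, otherwise overlap-based
self-calibration has nothing to lock onto.  Sequential RNG streams cannot
provide that, so spatial cells are hashed (splitmix64) into uniforms and
complex-Gaussian phasors on demand.
"""

from __future__ import annotations

import numpy as np

_U64 = np.uint64

# splitmix64 constants
_C1 = _U64(0x9E3779B97F4A7C15)
_C2 = _U64(0xBF58476D1CE4E5B9)
_C3 = _U64(0x94D049BB133111EB)
# distinct odd multipliers to decorrelate the three lattice axes
_PX = _U64(0x8DA6B343EC53F6C5)
_PY = _U64(0xD8163841E869B52D)
_PZ = _U64(0x61C8864680B583EB)


def _splitmix64(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):  # uint64 wraparound is the point
        x = (x + _C1).astype(_U64)
        x ^= x >> _U64(30)
        x *= _C2
        x ^= x >> _U64(27)
        x *= _C3
        x ^= x >> _U64(31)
    return x


def _cell_key(ix, iy, iz, seed: int, stream: int) -> np.ndarray:
    """64-bit key for an integer lattice cell under a (seed, stream) pair."""
    s = _U64((int(seed) & 0xFFFFFFFF) ^ (int(stream) << 32))
    ix = np.asarray(ix, dtype=np.int64).astype(_U64)
    iy = np.asarray(iy, dtype=np.int64).astype(_U64)
    iz = np.asarray(iz, dtype=np.int64).astype(_U64)
    with np.errstate(over="ignore"):
        mixed = ix * _PX ^ iy * _PY ^ iz * _PZ ^ _splitmix64(np.array(s))
    return _splitmix64(mixed)


def _to_unit(h: np.ndarray) -> np.ndarray:
    """Map uint64 hash to a float64 uniform in (0, 1)."""
    return ((h >> _U64(11)).astype(np.float64) + 0.5) * 2.0 ** -53


def cell_uniform(ix, iy, iz, seed: int, stream: int = 0) -> np.ndarray:
    """Uniform(0, 1) deterministic per lattice cell."""
    return _to_unit(_cell_key(ix, iy, iz, seed, stream))


def cell_phasor(ix, iy, iz, seed: int, stream: int = 0) -> np.ndarray:
    """Circular complex Gaussian (unit variance) per lattice cell.

    Box–Muller on two decorrelated hash streams; fully developed speckle
    arises from summing many such phasors per resolution cell.
    """
    u1 = cell_uniform(ix, iy, iz, seed, stream)
    u2 = cell_uniform(ix, iy, iz, seed, stream + 7919)
    r = np.sqrt(-np.log(u1))  # Rayleigh(1/sqrt(2)) * sqrt(2); |phasor|^2 ~ Exp(1)
    return r * np.exp(2j * np.pi * u2)


def value_noise(points_mm: np.ndarray, scale_mm: float, seed: int,
                stream: int = 0) -> np.ndarray:
    """Smooth value noise in [-1, 1] at the given points (n, 3), lattice pitch
    ``scale_mm``.  Trilinear interpolation of per-corner uniforms."""
    p = np.asarray(points_mm, dtype=np.float64) / float(scale_mm)
    i0 = np.floor(p).astype(np.int64)
    f = p - i0
    # smoothstep for C1 continuity
    w = f * f * (3.0 - 2.0 * f)
    out = np.zeros(p.shape[0])
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                corner = cell_uniform(i0[:, 0] + dx, i0[:, 1] + dy,
                                      i0[:, 2] + dz, seed, stream) * 2.0 - 1.0
                wx = w[:, 0] if dx else 1.0 - w[:, 0]
                wy = w[:, 1] if dy else 1.0 - w[:, 1]
                wz = w[:, 2] if dz else 1.0 - w[:, 2]
                out += corner * wx * wy * wz
    return out


def fractal_noise(points_mm: np.ndarray, scale_mm: float, seed: int,
                  octaves: int = 2, stream: int = 0) -> np.ndarray:
    """Sum of value-noise octaves (each half the scale, half the weight)."""
    total = np.zeros(np.asarray(points_mm).shape[0])
    amp, norm = 1.0, 0.0
    for o in range(octaves):
        total += amp * value_noise(points_mm, scale_mm / (2 ** o), seed,
                                   stream=stream + 101 * o)
        norm += amp
        amp *= 0.5
    return total / norm
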