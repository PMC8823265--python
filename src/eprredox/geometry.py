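"""Gradient-direction schedules on the unit sphere.

Field-gradient directions for 3D EPR projection imaging are generated with
the two-golden-means construction: index ``i`` (1-based) maps to

* polar coordinate  ``z = 2 frac(i phi1) - 1``  (full sphere), and
* azimuth           ``beta = 2 pi frac(i phi2)``,

where ``phi1 = 1/lambda^2 ~ 0.46557`` and ``phi2 = 1/lambda ~ 0.68233`` are
the 3D golden means derived from the real root ``lambda`` of
``lambda^3 = lambda^2 + 1`` (the eigen-construction of the modified
3x3 Fibonacci matrix; Chan et al., Magn. Reson. Med. 61:354-363, 2009).

The schedule is deterministic and *nested*: the first ``m`` directions of an
``n``-point schedule equal the ``m``-point schedule, so any prefix of an
acquisition is itself a quasi-uniform set.  This is the property that makes
retrospective sub-sampling of a measured projection set meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# real root of x^3 - x^2 - 1 = 0
_roots = np.roots([1.0, -1.0, 0.0, -1.0])
_LAMBDA = float(np.real(_roots[np.isreal(_roots)][0]))

#: 3D golden means (Chan et al. 2009): phi1 = 1/lambda^2, phi2 = 1/lambda.
GOLDEN_MEAN_1: float = 1.0 / _LAMBDA**2
GOLDEN_MEAN_2: float = 1.0 / _LAMBDA

#: standard full-sphere projection counts of the acquisition protocol
STANDARD_COUNTS = (64, 128, 256, 512, 1024, 2048)


@dataclass
class DirectionSet:
    """Ordered unit vectors defining gradient directions.

    Invariants: every row of ``vectors`` has unit Euclidean norm (1e-12);
    any prefix is itself a valid set (see :meth:`subset`).
    """

    vectors: np.ndarray
    scheme: str = "explicit"

    def __post_init__(self) -> None:
        self.vectors = np.ascontiguousarray(np.asarray(self.vectors, dtype=np.float64))
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must have shape (n, 3)")
        if self.vectors.shape[0] < 1:
            raise ValueError("a DirectionSet needs at least one direction")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("all direction vectors must have unit norm")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def subset(self, m: int) -> "DirectionSet":
        """First ``m`` directions (a valid schedule by the nesting property)."""
        if not 1 <= m <= self.n:
            raise ValueError(f"subset size {m} outside [1, {self.n}]")
        return DirectionSet(self.vectors[:m].copy(), self.scheme)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.vectors, delimiter=",", fmt="%.17g")

    @classmethod
    def from_csv(cls, path, scheme: str = "explicit") -> "DirectionSet":
        vec = np.loadtxt(path, delimiter=",", ndmin=2)
        return cls(vec, scheme)


def golden_mean_directions(n: int) -> DirectionSet:
    """Deterministic quasi-uniform schedule of ``n`` directions on the sphere.

    Parameters
    ----------
    n:
        Number of directions, >= 1.  The standard acquisition schedules use
        ``n in {64, 128, 256, 512, 1024, 2048}`` but any count is valid.

    Returns
    -------
    DirectionSet
        ``golden_mean_directions(n).vectors[:m]`` equals
        ``golden_mean_directions(m).vectors`` exactly for any ``m < n``.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError("n must be a positive integer")
    i = np.arange(1, n + 1, dtype=np.float64)
    z = 2.0 * np.mod(i * GOLDEN_MEAN_1, 1.0) - 1.0
    beta = 2.0 * np.pi * np.mod(i * GOLDEN_MEAN_2, 1.0)
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    vec = np.column_stack([rho * np.cos(beta), rho * np.sin(beta), z])
    # re-normalize to keep norms exact to 1e-12 regardless of rounding
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return DirectionSet(vec, scheme="golden_mean")


def random_directions(n: int, seed: int) -> DirectionSet:
    """Uniform random directions; the benchmark the golden-mean set must beat."""
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    vec = rng.standard_normal((n, 3))
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return DirectionSet(vec, scheme="explicit")


def uniformity_score(d: DirectionSet) -> float:
    """Coefficient of variation of nearest-neighbour angular distances.

    Zero for perfectly regular arrangements; lower means a more uniform
    angular coverage of the sphere.
    """
    if d.n < 2:
        raise ValueError("uniformity_score needs at least two directions")
    g = np.clip(d.vectors @ d.vectors.T, -1.0, 1.0)
    ang = np.arccos(g)
    np.fill_diagonal(ang, np.inf)
    nn = ang.min(axis=1)
    mean = nn.mean()
    if mean == 0.0:
        return 0.0
    return float(nn.std() / mean)
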