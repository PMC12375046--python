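"""Analytic test surfaces: desk-scale backends with known stationary points.

The zoo:

``double_well``
    A diatomic whose bond-stretch profile is the symmetric quartic double well
    E(r) = A ((r − c)² − w²)².  Minima at r = c ± w with E = 0, saddle at r = c
    with the closed-form barrier A w⁴ — a one-coordinate bond break/form event.

``triatomic_exchange``
    A collinear A–B···C exchange surface in the two bond distances,
    E = A (q² − w²)² + k (Q − Q₀)² + k_b (r₁₂ + r₂₃ − r₁₃),
    with q = r₁₂ − r₂₃ and Q = (r₁₂ + r₂₃)/2.  The last term vanishes exactly on
    collinear arrangements and grows quadratically with bending, so the minima
    (q = ±w) and the saddle (q = 0, barrier A w⁴) are all collinear and the
    saddle carries exactly one imaginary (asymmetric-stretch) frequency.

``pseudo_reaction``
    A U-style potential whose designated *reactive pairs* replace the harmonic
    spring by a radial double well with a bonded and a nonbonded minimum, so a
    proposed form/break event along such a pair crosses a genuine barrier while
    every spectator bond stays harmonic.

``upotential``
    U itself as a calculator over a frozen bond list (distance-only, used for
    enantiomer-energy symmetry checks and cheap toy species).

All of these depend on the coordinates only through interatomic distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calculator import Calculator
from .structure import Structure
from .u import UParams, u_energy_gradient


class DistanceFunctionPotential(Calculator):
    """Base for potentials E = f(r_1, ..., r_m) of selected interatomic distances.

    Subclasses define ``pairs`` (the distances the energy reads) and
    ``_terms(r) -> (E, dE/dr array)``; the Cartesian gradient follows by chain rule.
    """

    pairs: list[tuple[int, int]]

    def _terms(self, r: np.ndarray) -> tuple[float, np.ndarray]:
        raise NotImplementedError

    def _distances(self, s: Structure) -> np.ndarray:
        c = s.coords
        return np.array([np.linalg.norm(c[i] - c[j]) for i, j in self.pairs])

    def energy(self, s: Structure) -> float:
        return float(self._terms(self._distances(s))[0])

    def gradient(self, s: Structure) -> np.ndarray:
        c = s.coords
        r = self._distances(s)
        _, dEdr = self._terms(r)
        g = np.zeros_like(c)
        for (i, j), rr, de in zip(self.pairs, r, dEdr):
            u = (c[i] - c[j]) / rr
            g[i] += de * u
            g[j] -= de * u
        return g


@dataclass
class DoubleWellDiatomic(DistanceFunctionPotential):
    """Symmetric quartic double well in the bond length of a diatomic."""

    elements: tuple[str, str] = ("C", "C")
    A: float = 0.16        # Hartree/Å⁴
    c: float = 1.8         # well midpoint, Å
    w: float = 0.6         # half well separation, Å
    name: str = "double_well"
    pairs: list = field(default_factory=lambda: [(0, 1)])

    @property
    def r_min_short(self) -> float:
        return self.c - self.w

    @property
    def r_min_long(self) -> float:
        return self.c + self.w

    @property
    def barrier(self) -> float:
        """Closed-form saddle height above either (equal-energy) well: A w⁴."""
        return self.A * self.w**4

    def _terms(self, r):
        x = r[0] - self.c
        q = x * x - self.w**2
        return self.A * q * q, np.array([4.0 * self.A * q * x])

    def minimum_structure(self, which: str = "short") -> Structure:
        r = self.r_min_short if which == "short" else self.r_min_long
        return Structure(list(self.elements), np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
                         label=f"double_well_{which}")

    def profile(self, r: np.ndarray) -> np.ndarray:
        q = (r - self.c) ** 2 - self.w**2
        return self.A * q * q


@dataclass
class TriatomicExchange(DistanceFunctionPotential):
    """Collinear atom-exchange surface with a tabulated (grid-verified) saddle."""

    elements: tuple[str, str, str] = ("C", "C", "C")
    A: float = 0.08        # Hartree/Å⁴, asymmetric-stretch quartic
    w: float = 0.8         # Å; minima at q = ±w
    Q0: float = 1.5        # Å; equilibrium mean bond distance
    k: float = 0.5         # Hartree/Å², symmetric stretch
    kb: float = 0.3        # Hartree/Å, collinearity restraint
    name: str = "triatomic_exchange"
    pairs: list = field(default_factory=lambda: [(0, 1), (1, 2), (0, 2)])

    @property
    def barrier(self) -> float:
        return self.A * self.w**4

    def _terms(self, r):
        r01, r12, r02 = r
        q = r01 - r12
        Q = 0.5 * (r01 + r12)
        s = q * q - self.w**2
        e = self.A * s * s + self.k * (Q - self.Q0) ** 2 + self.kb * (r01 + r12 - r02)
        dq = 4.0 * self.A * s * q
        dQ = 2.0 * self.k * (Q - self.Q0)
        return e, np.array([dq + 0.5 * dQ + self.kb, -dq + 0.5 * dQ + self.kb, -self.kb])

    def energy_collinear(self, r01, r12):
        """Vectorized energy on collinear geometries (grid-scan helper)."""
        q = np.asarray(r01) - np.asarray(r12)
        s = q * q - self.w**2
        Q = 0.5 * (np.asarray(r01) + np.asarray(r12))
        return self.A * s * s + self.k * (Q - self.Q0) ** 2

    def minimum_structure(self, which: str = "left") -> Structure:
        # "left": 0-1 long (unbound), 1-2 short (bonded); "right": exchanged.
        long_, short = self.Q0 + self.w / 2, self.Q0 - self.w / 2
        r01, r12 = (long_, short) if which == "left" else (short, long_)
        x = np.array([[0.0, 0.0, 0.0], [r01, 0.0, 0.0], [r01 + r12, 0.0, 0.0]])
        return Structure(list(self.elements), x, label=f"triatomic_{which}")

    def saddle_structure(self) -> Structure:
        x = np.array([[0.0, 0.0, 0.0], [self.Q0, 0.0, 0.0], [2 * self.Q0, 0.0, 0.0]])
        return Structure(list(self.elements), x, label="triatomic_saddle")


@dataclass
class ReactivePairTerm:
    """Radial double well on one pair: minima near r_bond and r_nonbond, optional tilt.

    Beyond the outer (nonbonded) minimum the term is held constant, so atoms that
    drift apart see a flat nonbonded plateau instead of an unphysical quartic wall;
    the inner repulsive branch keeps its quartic growth.  C¹ everywhere (the plateau
    starts where the derivative vanishes).
    """

    i: int
    j: int
    A: float = 0.15          # Hartree/Å⁴
    r_bond: float = 1.5      # Å
    r_nonbond: float = 3.0   # Å
    tilt: float = 0.0        # Hartree/Å, linear asymmetry (nonzero makes ΔE ≠ 0)

    def __post_init__(self):
        # outer stationary point of A((r-c)² - w²)² + tilt·(r-c): real cubic root near +w
        roots = np.roots([4.0 * self.A, 0.0, -4.0 * self.A * self.halfwidth**2, self.tilt])
        real = roots[np.abs(roots.imag) < 1e-10].real
        self._x_outer = float(real[np.argmin(np.abs(real - self.halfwidth))])

    @property
    def center(self) -> float:
        return 0.5 * (self.r_bond + self.r_nonbond)

    @property
    def halfwidth(self) -> float:
        return 0.5 * (self.r_nonbond - self.r_bond)

    @property
    def r_outer(self) -> float:
        """Radius at which the flat nonbonded plateau begins."""
        return self.center + self._x_outer

    def value(self, r):
        x = np.minimum(np.asarray(r) - self.center, self._x_outer)
        q = x * x - self.halfwidth**2
        return self.A * q * q + self.tilt * x

    def deriv(self, r):
        x = r - self.center
        if x >= self._x_outer:
            return 0.0
        q = x * x - self.halfwidth**2
        return 4.0 * self.A * q * x + self.tilt


@dataclass
class PseudoReactionPotential(DistanceFunctionPotential):
    """Harmonic spectator bonds plus switchable double-well reactive pairs."""

    elements: list[str]
    bonds: list[tuple[int, int, float, float]]  # (i, j, r0 Å, a Hartree/Å²)
    reactive: list[ReactivePairTerm]
    name: str = "pseudo_reaction"

    def __post_init__(self):
        self.pairs = [(b[0], b[1]) for b in self.bonds] + [(t.i, t.j) for t in self.reactive]

    def _terms(self, r):
        e = 0.0
        de = np.zeros_like(r)
        nb = len(self.bonds)
        for k, (_, _, r0, a) in enumerate(self.bonds):
            dr = r[k] - r0
            e += a * dr * dr
            de[k] = 2.0 * a * dr
        for k, t in enumerate(self.reactive):
            e += float(t.value(r[nb + k]))
            de[nb + k] = t.deriv(r[nb + k])
        return e, de

    def reactive_term(self, pair: tuple[int, int]) -> ReactivePairTerm:
        key = tuple(sorted(pair))
        for t in self.reactive:
            if tuple(sorted((t.i, t.j))) == key:
                return t
        raise KeyError(f"no reactive term on pair {pair}")


@dataclass
class UPotentialBackend(Calculator):
    """Function U over a frozen bond list, exposed as a calculator."""

    bonds: list[tuple[int, int]]
    params: UParams = field(default_factory=UParams)
    name: str = "upotential"

    def energy(self, s: Structure) -> float:
        return u_energy_gradient(s, self.bonds, self.params)[0]

    def gradient(self, s: Structure) -> np.ndarray:
        return u_energy_gradient(s, self.bonds, self.params)[1]


_REGISTRY = {
    "double_well": DoubleWellDiatomic,
    "triatomic_exchange": TriatomicExchange,
    "pseudo_reaction": PseudoReactionPotential,
    "upotential": UPotentialBackend,
}


def analytic_backend(name: str, **kwargs) -> Calculator:
    """Instantiate a built-in analytic backend by registry token."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; available: {sorted(_REGISTRY)}") from None
    return cls(**kwargs)
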