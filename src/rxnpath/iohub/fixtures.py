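"""Deterministic fixture generation: toy seeds, toy rule libraries, analytic
backends and the grid-scan oracle answers the tests compare against.

Every scenario emits a complete, runnable bundle, so the whole pipeline is
testable without any external data or engine.  Oracles are computed by dense
grid scans over the surface's reactive coordinate(s) at build time — a search
path entirely independent of the sampler they are used to check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..potentials.backends import (
    DoubleWellDiatomic,
    PseudoReactionPotential,
    ReactivePairTerm,
    TriatomicExchange,
    UPotentialBackend,
)
from ..potentials.calculator import Calculator
from ..potentials.structure import Structure
from ..potentials.u import UParams
from ..rules import ReactionRule, RuleLibrary

SCENARIOS = ("double_well", "triatomic_exchange", "pseudo_cycloaddition", "chiral_pair")


@dataclass
class FixtureSpec:
    scenario: str
    seed: int = 0
    size: int = 0  # scenario-specific size knob (unused by the current scenarios)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    seeds: list[Structure]
    rules: RuleLibrary
    backend: Calculator
    backend_name: str
    uparams: UParams
    oracle: dict = field(default_factory=dict)


# ----- grid-scan oracles --------------------------------------------------


def double_well_grid_oracle(backend: DoubleWellDiatomic, npts: int = 20001) -> dict:
    """Dense 1-D scan of the bond-stretch profile: wells, saddle, barrier."""
    r = np.linspace(backend.c - 2.0 * backend.w, backend.c + 2.0 * backend.w, npts)
    e = backend.profile(r)
    lo = r <= backend.c
    i_left = int(np.argmin(e[lo]))
    i_right = int(np.argmin(np.where(lo, np.inf, e)))
    inner = (r > r[lo][i_left]) & (r < r[i_right])
    i_saddle = int(np.argmax(np.where(inner, e, -np.inf)))
    return {
        "r_min_short": float(r[lo][i_left]), "r_min_long": float(r[i_right]),
        "r_saddle": float(r[i_saddle]), "e_min": float(e[lo][i_left]),
        "e_saddle": float(e[i_saddle]),
        "barrier": float(e[i_saddle] - e[lo][i_left]),
    }


def triatomic_grid_oracle(backend: TriatomicExchange, npts: int = 801) -> dict:
    """Dense 2-D scan over the two collinear bond distances."""
    span = np.linspace(backend.Q0 - 1.2 * backend.w, backend.Q0 + 1.2 * backend.w, npts)
    R01, R12 = np.meshgrid(span, span, indexing="ij")
    E = backend.energy_collinear(R01, R12)
    # minima: r01 > r12 branch and r01 < r12 branch
    left = np.where(R01 > R12, E, np.inf)
    i = np.unravel_index(np.argmin(left), E.shape)
    e_min = float(left[i])
    # saddle: minimum along the ridge q = 0 (shared boundary of the two basins)
    diag = backend.energy_collinear(span, span)
    j = int(np.argmin(diag))
    return {
        "r01_min": float(R01[i]), "r12_min": float(R12[i]), "e_min": e_min,
        "r_saddle": float(span[j]), "e_saddle": float(diag[j]),
        "barrier": float(diag[j] - e_min),
    }


def pseudo_pair_grid_oracle(term: ReactivePairTerm, npts: int = 20001) -> dict:
    """1-D scan of one reactive pair's radial double well (the surface is separable:
    spectator springs relax to zero independently of the pair distance)."""
    r = np.linspace(term.r_bond - 0.5, term.r_nonbond + 0.5, npts)
    e = term.value(r)
    mid = term.center
    i_b = int(np.argmin(np.where(r < mid, e, np.inf)))
    i_nb = int(np.argmin(np.where(r > mid, e, np.inf)))
    inner = (r > r[i_b]) & (r < r[i_nb])
    i_s = int(np.argmax(np.where(inner, e, -np.inf)))
    return {
        "r_bonded": float(r[i_b]), "r_nonbonded": float(r[i_nb]),
        "r_saddle": float(r[i_s]),
        "e_bonded": float(e[i_b]), "e_nonbonded": float(e[i_nb]),
        "e_saddle": float(e[i_s]),
        "barrier_from_nonbonded": float(e[i_s] - e[i_nb]),
        "barrier_from_bonded": float(e[i_s] - e[i_b]),
        "delta_e_form": float(e[i_b] - e[i_nb]),
    }


# ----- scenarios ----------------------------------------------------------


def _rule(rule_id, smarts, action, notes=""):
    return ReactionRule(rule_id=rule_id, name=rule_id, smarts=smarts, action=action,
                        mapped_pair=(1, 2), provenance="system_specific", notes=notes)


def _double_well_bundle(spec: FixtureSpec) -> FixtureBundle:
    backend = DoubleWellDiatomic()
    seed = backend.minimum_structure("short")
    rules = RuleLibrary(rules=[_rule("dw_break", "[#6:1]~[#6:2]", "break",
                                     "stretch the C-C bond into the outer well")],
                        version="fixture")
    return FixtureBundle(spec=spec, seeds=[seed], rules=rules, backend=backend,
                         backend_name="double_well", uparams=UParams(),
                         oracle=double_well_grid_oracle(backend))


def _triatomic_bundle(spec: FixtureSpec) -> FixtureBundle:
    backend = TriatomicExchange()
    seed = backend.minimum_structure("left")  # 0-1 unbound, 1-2 bonded
    rules = RuleLibrary(rules=[_rule("tx_form", "[#6;X0:1].[#6;X1:2]", "form",
                                     "bond the free atom to the diatomic")],
                        version="fixture")
    return FixtureBundle(spec=spec, seeds=[seed], rules=rules, backend=backend,
                         backend_name="triatomic_exchange", uparams=UParams(),
                         oracle=triatomic_grid_oracle(backend))


def _pseudo_cycloaddition_bundle(spec: FixtureSpec) -> FixtureBundle:
    # two C2 fragments facing each other; two reactive cross pairs with
    # different barriers so the printed thresholds (0.04/0.05/0.08 Hartree)
    # partition the channels
    elements = ["C", "C", "C", "C"]
    coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                       [0.0, 3.0, 0.0], [1.5, 3.0, 0.0]])
    term_low = ReactivePairTerm(i=0, j=2, A=0.145, r_bond=1.5, r_nonbond=3.0)
    term_high = ReactivePairTerm(i=1, j=3, A=0.22, r_bond=1.5, r_nonbond=3.0)
    backend = PseudoReactionPotential(
        elements=elements,
        bonds=[(0, 1, 1.5, 1.0), (2, 3, 1.5, 1.0)],
        reactive=[term_low, term_high],
    )
    seed = Structure(elements, coords, label="pseudo_cycloaddition_seed")
    rules = RuleLibrary(rules=[_rule("pc_form", "[#6;X1:1].[#6;X1:2]", "form",
                                     "cross-fragment carbon-carbon bond formation")],
                        version="fixture")
    oracle = {
        "pair_low": {"pair": (0, 2), **pseudo_pair_grid_oracle(term_low)},
        "pair_high": {"pair": (1, 3), **pseudo_pair_grid_oracle(term_high)},
    }
    return FixtureBundle(spec=spec, seeds=[seed], rules=rules, backend=backend,
                         backend_name="pseudo_reaction", uparams=UParams(),
                         oracle=oracle)


def _chiral_pair_bundle(spec: FixtureSpec) -> FixtureBundle:
    # a single stereocenter: C bonded to H, F, Cl, Br at tetrahedral directions
    elements = ["C", "H", "F", "Cl", "Br"]
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], float)
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    p = UParams()
    lengths = [p.reference_length("C", e) for e in elements[1:]]
    coords = np.vstack([[0.0, 0.0, 0.0]] + [d * L for d, L in zip(dirs, lengths)])
    seed = Structure(elements, coords, label="chiral_seed_R")
    mirror = seed.mirrored()
    mirror.label = "chiral_seed_S"
    bonds = [(0, k) for k in range(1, 5)]
    backend = UPotentialBackend(bonds=bonds, params=p)
    rules = RuleLibrary(rules=[_rule("ch_break", "[#6:1]~[#9,#17,#35:2]", "break",
                                     "carbon-halogen cleavage")],
                        version="fixture")
    return FixtureBundle(spec=spec, seeds=[seed, mirror], rules=rules, backend=backend,
                         backend_name="upotential", uparams=p,
                         oracle={"n_stereocenters": 1})


_BUILDERS = {
    "double_well": _double_well_bundle,
    "triatomic_exchange": _triatomic_bundle,
    "pseudo_cycloaddition": _pseudo_cycloaddition_bundle,
    "chiral_pair": _chiral_pair_bundle,
}


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Build a scenario bundle; deterministic under ``spec.seed``."""
    return _BUILDERS[spec.scenario](spec)


# ----- the toy-reaction battery ------------------------------------------


@dataclass
class BatteryCase:
    """One toy reaction with a grid-verified saddle for the TS-sampler benchmark."""

    name: str
    backend: Calculator
    structure: Structure          # the reactant-side minimum (IN)
    pair: tuple[int, int]
    action: str
    oracle_saddle_energy: float   # Hartree, from the grid scan
    oracle_barrier: float
    uparams: UParams = field(default_factory=UParams)


def ts_battery(n_cases: int = 24, seed: int = 0) -> list[BatteryCase]:
    """A battery of ≥ 20 toy reactions with genuine barriers, grid oracles attached.

    Mix: diatomic double wells (break and form directions, varied well geometry),
    collinear triatomic exchanges, and separable pseudo-reaction form events with
    tilted (asymmetric) double wells.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    cases: list[BatteryCase] = []
    kinds = ["dw_break", "dw_form", "triatomic", "pseudo_form"]
    for k in range(n_cases):
        kind = kinds[k % len(kinds)]
        if kind in ("dw_break", "dw_form"):
            c = float(rng.uniform(1.7, 1.9))
            w = float(rng.uniform(0.5, 0.65))
            barrier = float(rng.uniform(0.01, 0.05))
            backend = DoubleWellDiatomic(A=barrier / w**4, c=c, w=w)
            oracle = double_well_grid_oracle(backend)
            which = "short" if kind == "dw_break" else "long"
            action = "break" if kind == "dw_break" else "form"
            s = backend.minimum_structure(which)
            cases.append(BatteryCase(
                name=f"{kind}_{k}", backend=backend, structure=s, pair=(0, 1),
                action=action, oracle_saddle_energy=oracle["e_saddle"],
                oracle_barrier=oracle["e_saddle"] - oracle["e_min"]))
        elif kind == "triatomic":
            w = float(rng.uniform(0.7, 0.9))
            Q0 = float(rng.uniform(1.5, 1.6))
            A = float(rng.uniform(0.05, 0.10))
            backend = TriatomicExchange(A=A, w=w, Q0=Q0)
            oracle = triatomic_grid_oracle(backend)
            s = backend.minimum_structure("left")
            cases.append(BatteryCase(
                name=f"triatomic_{k}", backend=backend, structure=s, pair=(0, 1),
                action="form", oracle_saddle_energy=oracle["e_saddle"],
                oracle_barrier=oracle["barrier"]))
        else:
            A = float(rng.uniform(0.10, 0.25))
            tilt = float(rng.uniform(-0.01, 0.01))
            term = ReactivePairTerm(i=0, j=2, A=A, r_bond=1.5, r_nonbond=3.0, tilt=tilt)
            backend = PseudoReactionPotential(
                elements=["C", "C", "C", "C"],
                bonds=[(0, 1, 1.5, 1.0), (2, 3, 1.5, 1.0)],
                reactive=[term])
            oracle = pseudo_pair_grid_oracle(term)
            coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0],
                               [0.0, oracle["r_nonbonded"], 0.0],
                               [1.5, oracle["r_nonbonded"], 0.0]])
            s = Structure(["C", "C", "C", "C"], coords, label=f"pseudo_{k}")
            cases.append(BatteryCase(
                name=f"pseudo_form_{k}", backend=backend, structure=s, pair=(0, 2),
                action="form", oracle_saddle_energy=oracle["e_saddle"],
                oracle_barrier=oracle["barrier_from_nonbonded"]))
    return cases
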