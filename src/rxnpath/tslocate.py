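"""Active-learning transition-state location.

For one proposed bond form/break event the sampler (i) builds the product-side
intermediate with the pseudo-potential U (bypassing any direct saddle search),
(ii) probes the linear path between the input minimum (IN, s = 0) and the
intermediate (IM, s = 1) starting at the golden-section point nearer IN,
each probe constraint-optimized with the active-pair distance frozen,
(iii) fits the three consecutive probes bracketing the running energy maximum
to a parabola, refines the structure built at the parabola's vertex to a saddle
by eigenvector following, and (iv) validates it in two steps — the active pair's
weight in the imaginary eigenvector must rank in the top ten of all atom-pair
weights, and the frequency analysis must show exactly one imaginary mode.
A candidate that fails validation is recycled as a new probe point at its
projection onto the IN→IM segment, and the loop repeats up to the iteration cap.
A validated saddle is finally connected to its two minima by a damped
steepest-descent intrinsic-reaction-coordinate walk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import GOLDEN_S
from .geometry import superpose
from .potentials.calculator import Calculator, VibrationalResult
from .potentials.species import bond_list, canonical_species_id, labeled_bond_set
from .potentials.structure import Structure
from .potentials.u import UParams, u_relax
from .rules import ActivePair

PAIR_WEIGHT_RANK_MAX = 10  # top-10 rule of the two-step validation


class UnreactivePairError(RuntimeError):
    """The proposed event relaxes back into the reactant basin: no step exists."""


class BracketError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


@dataclass
class ProbePoint:
    """A constraint-optimized structure at path parameter s ∈ [0, 1] (0 = IN, 1 = IM)."""

    s: float
    structure: Structure
    energy: float

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"probe parameter s={self.s} outside [0, 1]")


@dataclass
class TSCandidate:
    structure: Structure
    energy: float
    nimag: int = -1
    imag_mode: np.ndarray | None = None
    pair_weight_rank: int = -1
    validated: bool = False


@dataclass
class TSFailure:
    reason: str
    probes: list[ProbePoint] = field(default_factory=list)
    iterations: int = 0

    def record(self) -> dict:
        """JSON-serializable post-mortem."""
        return {
            "reason": self.reason,
            "iterations": self.iterations,
            "probes": [{"s": p.s, "energy": p.energy} for p in
                       sorted(self.probes, key=lambda q: q.s)],
        }


@dataclass
class TSSearchResult:
    candidate: TSCandidate | None = None
    failure: TSFailure | None = None
    probes: list[ProbePoint] = field(default_factory=list)
    intermediate: Structure | None = None

    @property
    def ok(self) -> bool:
        return self.candidate is not None and self.candidate.validated


@dataclass
class ElementaryStep:
    """A validated edge of the reaction network: reactant → (TS) → product."""

    reactant_id: str
    product_id: str
    reactant: Structure
    product: Structure
    ts: TSCandidate
    barrier: float   # E(ts) − E(reactant), Hartree
    delta_e: float   # E(product) − E(reactant), Hartree
    pair: ActivePair


# ----- intermediate proposal ---------------------------------------------


def propose_intermediate(
    inp: Structure,
    pair: ActivePair,
    p: UParams,
    calc: Calculator,
    bias_strength: float = 2.0,
) -> Structure:
    """Product-side minimum for one form/break event, found with U then the calculator.

    form: the pair joins the U bond list (the spring pulls the atoms together);
    break: the pair leaves the bond list and a repulsive bias pushes them apart.
    The U-relaxed guess is then minimized on the real surface; if its species id
    still equals the reactant's the pair is unreactive and no step exists.
    """
    bonds = bond_list(inp)
    key = (pair.i, pair.j)
    reactant_bonds = labeled_bond_set(inp)
    if pair.action == "form":
        if key in bonds:
            raise UnreactivePairError(f"pair {key} already bonded; nothing to form")
        guess = u_relax(inp, p, bonds=bonds + [key])
    else:
        if key not in bonds:
            raise UnreactivePairError(f"pair {key} not bonded; nothing to break")
        guess = u_relax(inp, p, bonds=[b for b in bonds if b != key],
                        bias_pairs=[key], bias_strength=bias_strength)
    # commit to the event direction: a small symmetric nudge of the pair keeps a
    # symmetry-poised guess (e.g. an exchange ridge) from relaxing ambiguously
    c = guess.coords.copy()
    u = c[pair.i] - c[pair.j]
    r = np.linalg.norm(u)
    if r > 1e-9:
        sign = -1.0 if pair.action == "form" else +1.0
        shift = 0.5 * sign * 0.05 * (u / r)
        c[pair.i] += shift
        c[pair.j] -= shift
        guess = guess.with_coords(c)
    im = calc.minimize(guess)
    # labeled (indexed-atom) bonds, not the canonical id: a degenerate exchange
    # changes which atoms are bonded without changing the species graph
    if labeled_bond_set(im) == reactant_bonds:
        raise UnreactivePairError(f"pair {key} ({pair.action}) relaxed back to the reactant")
    return im


# ----- path probes --------------------------------------------------------


def interpolate(IN: Structure, IM: Structure, s: float) -> Structure:
    """Linear Cartesian blend (1−s)·IN + s·IM after rigid alignment of IM onto IN."""
    aligned = superpose(IM.coords, IN.coords)
    return IN.with_coords((1.0 - s) * IN.coords + s * aligned)


def golden_probe(IN: Structure, IM: Structure, calc: Calculator,
                 pair: ActivePair, s: float = GOLDEN_S) -> ProbePoint:
    """Constraint-optimized probe at the golden-section point nearer IN (s = 2 − φ)."""
    geom = interpolate(IN, IM, s)
    opt = calc.constrained_minimize(geom, (pair.i, pair.j))
    return ProbePoint(s=s, structure=opt, energy=opt.meta["energy"])


def quadratic_extremum(p1: ProbePoint, p2: ProbePoint, p3: ProbePoint) -> float:
    """Vertex of the parabola through three consecutive probes bracketing a maximum.

    Requires p1.s < p2.s < p3.s with the middle point the energy maximum; the
    vertex −B/(2A) of the interpolating E = A s² + B s + C then lies strictly
    inside (p1.s, p3.s).
    """
    s1, s2, s3 = p1.s, p2.s, p3.s
    if not (s1 < s2 < s3):
        raise BracketError("probe parameters must be strictly increasing")
    e1, e2, e3 = p1.energy, p2.energy, p3.energy
    if not (e2 > e1 and e2 > e3):
        raise BracketError("no bracket: middle probe is not the energy maximum")
    denom = (s1 - s2) * (s1 - s3) * (s2 - s3)
    A = (s3 * (e2 - e1) + s2 * (e1 - e3) + s1 * (e3 - e2)) / denom
    B = (s3 * s3 * (e1 - e2) + s2 * s2 * (e3 - e1) + s1 * s1 * (e2 - e3)) / denom
    if abs(A) < 1e-300:
        raise DegenerateFitError("degenerate fit: collinear energies")
    return float(-B / (2.0 * A))


def _project_onto_path(x: Structure, IN: Structure, IM: Structure,
                       eps: float = 1e-3) -> float:
    """Path parameter of a structure: orthogonal projection onto the aligned
    IN→IM segment, clipped into (0, 1)."""
    aligned_im = superpose(IM.coords, IN.coords)
    d = (aligned_im - IN.coords).ravel()
    denom = float(d @ d)
    if denom < 1e-12:
        return 0.5
    aligned_x = superpose(x.coords, IN.coords)
    s = float((aligned_x - IN.coords).ravel() @ d) / denom
    return float(np.clip(s, eps, 1.0 - eps))


# ----- validation ---------------------------------------------------------


def pair_weight_rank(mode: np.ndarray, pair: ActivePair, basis: str = "pair") -> int:
    """Rank of the active pair's weight in an imaginary-mode eigenvector.

    Per-atom weight is the squared norm of the atom's 3-vector component of the
    (mass-weighted) eigenvector.  With ``basis='pair'`` the pair's weight
    w(i) + w(j) is ranked (descending, ties share the better rank) against every
    atom pair; with ``basis='atom'`` the better-ranked of the two atoms' own
    weights is used instead.
    """
    w = (np.asarray(mode).reshape(-1, 3) ** 2).sum(axis=1)
    n = w.size
    if basis == "atom":
        target = max(w[pair.i], w[pair.j])
        return 1 + int((w > target + 1e-15).sum())
    if basis != "pair":
        raise ValueError(f"unknown rank basis {basis!r}")
    target = w[pair.i] + w[pair.j]
    better = 0
    for a in range(n):
        for b in range(a + 1, n):
            if w[a] + w[b] > target + 1e-15:
                better += 1
    return 1 + better


def validate_ts(
    c: TSCandidate,
    pair: ActivePair,
    calc: Calculator,
    rank_max: int = PAIR_WEIGHT_RANK_MAX,
    rank_basis: str = "pair",
    freqs: VibrationalResult | None = None,
) -> bool:
    """Two-step validation; sets nimag / pair_weight_rank / validated on the candidate.

    Step 1: the active pair's vibration weight in the eigenvector of the negative
    eigenvalue must rank within the top ``rank_max``.  Step 2 (only if step 1
    passes): full frequency analysis must show exactly one imaginary mode.
    """
    if c.imag_mode is None:
        if freqs is None:
            freqs = calc.frequencies(c.structure)
        c.imag_mode = freqs.imaginary_mode
    c.pair_weight_rank = pair_weight_rank(c.imag_mode, pair, basis=rank_basis)
    if c.pair_weight_rank > rank_max:
        c.validated = False
        return False
    if freqs is None:
        freqs = calc.frequencies(c.structure)
    c.nimag = freqs.n_imaginary()
    c.imag_mode = freqs.imaginary_mode
    c.validated = c.nimag == 1
    return c.validated


# ----- the sampler --------------------------------------------------------


def locate_ts(
    IN: Structure,
    pair: ActivePair,
    calc: Calculator,
    p: UParams,
    max_iter: int = 8,
    rank_basis: str = "pair",
    IM: Structure | None = None,
) -> TSSearchResult:
    """Golden-section / quadratic active-learning saddle search for one event.

    Deterministic: identical inputs produce a bitwise-identical probe sequence.
    On failure the result carries a post-mortem record with every probe.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    try:
        if IM is None:
            IM = propose_intermediate(IN, pair, p, calc)
    except UnreactivePairError as exc:
        return TSSearchResult(failure=TSFailure(reason=f"no product basin: {exc}"))

    e_in = IN.meta.get("energy", calc.energy(IN))
    e_im = IM.meta.get("energy", calc.energy(IM))
    probes = [ProbePoint(0.0, IN, e_in), ProbePoint(1.0, IM, e_im)]
    probes.append(golden_probe(IN, IM, calc, pair))

    last_reason = "no bracket"
    for it in range(1, max_iter + 1):
        probes.sort(key=lambda q: q.s)
        energies = [q.energy for q in probes]
        m = int(np.argmax(energies))
        if m == 0 or m == len(probes) - 1:
            # running maximum at a path end: no interior bracket yet — densify
            # the interval adjacent to the maximum at its golden point.
            last_reason = "no bracket"
            lo, hi = (probes[0].s, probes[1].s) if m == 0 else (probes[-2].s, probes[-1].s)
            s_new = lo + GOLDEN_S * (hi - lo) if m == 0 else hi - GOLDEN_S * (hi - lo)
            probes.append(golden_probe(IN, IM, calc, pair, s=s_new))
            continue
        try:
            s_star = quadratic_extremum(probes[m - 1], probes[m], probes[m + 1])
        except DegenerateFitError:
            last_reason = "degenerate fit"
            s_star = 0.5 * (probes[m - 1].s + probes[m + 1].s)
        geom = interpolate(IN, IM, s_star)
        start = calc.constrained_minimize(geom, (pair.i, pair.j))
        refined = calc.saddle_refine(start)
        freqs = calc.frequencies(refined)
        cand = TSCandidate(structure=refined, energy=refined.meta["energy"],
                           imag_mode=freqs.imaginary_mode)
        if validate_ts(cand, pair, calc, rank_basis=rank_basis, freqs=freqs):
            return TSSearchResult(candidate=cand, probes=sorted(probes, key=lambda q: q.s),
                                  intermediate=IM)
        # failed candidate recycled as a new probe point at its path projection
        last_reason = f"validation failed (rank {cand.pair_weight_rank}, nimag {cand.nimag})"
        s_fail = _project_onto_path(refined, IN, IM)
        if any(abs(q.s - s_fail) < 1e-6 for q in probes):
            s_fail = min(0.999, s_fail + 1e-3)
        probes.append(ProbePoint(s_fail, refined, cand.energy))

    return TSSearchResult(
        failure=TSFailure(reason=last_reason, probes=sorted(probes, key=lambda q: q.s),
                          iterations=max_iter),
        probes=sorted(probes, key=lambda q: q.s), intermediate=IM)


# ----- IRC connection -----------------------------------------------------


class IRCError(RuntimeError):
    pass


def irc_connect(
    c: TSCandidate,
    calc: Calculator,
    displacement: float = 0.05,
    step_cap: float = 0.02,
    max_steps: int = 3000,
    gtol: float = 1e-5,
) -> tuple[Structure, Structure]:
    """Connect a validated saddle to its two minima.

    The saddle is displaced ±``displacement`` Å along the imaginary mode
    (converted from mass-weighted to Cartesian displacement) and walked downhill
    by damped steepest descent (step capped at ``step_cap`` Å), then polished by
    the calculator's minimizer.  Raises ``IRCError`` when both endpoints share a
    species id — the saddle does not connect distinct minima.
    """
    if c.imag_mode is None:
        c.imag_mode = calc.frequencies(c.structure).imaginary_mode
    masses = c.structure.masses()
    cart = np.asarray(c.imag_mode).reshape(-1, 3) / np.sqrt(masses)[:, None]
    cart /= np.linalg.norm(cart)

    def descend(sign: float) -> Structure:
        cur = c.structure.with_coords(c.structure.coords + sign * displacement * cart)
        for _ in range(max_steps):
            g = calc.gradient(cur)
            gnorm = float(np.abs(g).max())
            if gnorm < gtol:
                break
            step = -g
            n = float(np.linalg.norm(step))
            if n > step_cap:
                step *= step_cap / n
            cur = cur.with_coords(cur.coords + step)
        return calc.minimize(cur)

    back, fwd = descend(-1.0), descend(+1.0)
    back.meta["species_id"] = canonical_species_id(back)
    fwd.meta["species_id"] = canonical_species_id(fwd)
    if labeled_bond_set(back) == labeled_bond_set(fwd):
        raise IRCError("TS does not connect distinct minima")
    return back, fwd


def assemble_step(
    IN: Structure,
    pair: ActivePair,
    result: TSSearchResult,
    calc: Calculator,
    chiral: bool = False,
) -> ElementaryStep:
    """Run the IRC connection for a validated search result and build the network edge.

    The endpoint whose species id matches the input minimum becomes the reactant;
    if neither matches (the constrained probes drifted), the lower-energy endpoint
    does.  The barrier is taken relative to the connected reactant minimum.
    """
    if not result.ok:
        raise ValueError("cannot assemble a step from a failed TS search")
    back, fwd = irc_connect(result.candidate, calc)
    in_bonds = labeled_bond_set(IN)
    if labeled_bond_set(fwd) == in_bonds and labeled_bond_set(back) != in_bonds:
        back, fwd = fwd, back
    elif labeled_bond_set(back) != in_bonds and labeled_bond_set(fwd) != in_bonds:
        if fwd.meta["energy"] < back.meta["energy"]:
            back, fwd = fwd, back
    reactant, product = back, fwd
    r_id = canonical_species_id(reactant, chiral=chiral)
    p_id = canonical_species_id(product, chiral=chiral)
    if r_id == p_id:
        raise IRCError("degenerate step: both endpoints are the same species")
    e_r = reactant.meta["energy"]
    e_p = product.meta["energy"]
    return ElementaryStep(
        reactant_id=r_id, product_id=p_id, reactant=reactant, product=product,
        ts=result.candidate, barrier=result.candidate.energy - e_r,
        delta_e=e_p - e_r, pair=pair)
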