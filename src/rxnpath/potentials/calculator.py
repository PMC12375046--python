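"""The pluggable energy backend contract and its shared numerical engines.

Every numerical stage of the pipeline (relaxation, constrained probes, saddle
refinement, frequency analysis, IRC descent) talks to a ``Calculator`` and
nothing else, so the exploration logic is independent of where energies come
from.  Subclasses must provide ``energy`` (and should provide an analytic
``gradient``); minimization, Hessians, normal modes and eigenvector-following
saddle refinement are implemented here once, on top of those two calls.

All built-in backends depend on coordinates only through interatomic distances,
which makes their energies exactly invariant under rotation, translation and
mirror reflection — the property the chirality machinery relies on.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _sp_minimize

from ..constants import FREQ_AU_TO_CM, IMAG_FREQ_NOISE_CM
from .structure import Structure

CAPABILITIES = frozenset(
    {"energy", "gradient", "frequencies", "minimize", "constrained_minimize", "saddle_refine"}
)


@dataclass
class VibrationalResult:
    """Harmonic analysis: wavenumbers (cm⁻¹, imaginary encoded as negative, ascending)
    and the matching mass-weighted displacement modes, one (N, 3) array per frequency."""

    frequencies: np.ndarray
    modes: np.ndarray  # (nfreq, N, 3), orthonormal in mass-weighted coordinates

    def n_imaginary(self, noise_cm: float = IMAG_FREQ_NOISE_CM) -> int:
        return int((self.frequencies < -noise_cm).sum())

    @property
    def imaginary_mode(self) -> np.ndarray:
        """Mass-weighted displacement of the most negative frequency."""
        return self.modes[int(np.argmin(self.frequencies))]


def external_mode_basis(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal basis (3N × k) of rigid translations and rotations.

    If ``masses`` is given the basis is built in mass-weighted coordinates.
    k is 6 for nonlinear systems, 5 for linear ones, fewer for 1–2 atoms.
    """
    n = coords.shape[0]
    w = np.sqrt(masses) if masses is not None else np.ones(n)
    com = (coords * w[:, None] ** 2).sum(0) / (w**2).sum()
    x = coords - com
    vecs = []
    for ax in range(3):  # translations
        v = np.zeros((n, 3))
        v[:, ax] = w
        vecs.append(v.ravel())
    for ax in range(3):  # rotations about Cartesian axes through the COM
        e = np.zeros(3)
        e[ax] = 1.0
        v = np.cross(np.broadcast_to(e, (n, 3)), x) * w[:, None]
        vecs.append(v.ravel())
    basis = np.array(vecs).T
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


def internal_basis(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal complement of the translation/rotation space (3N × n_int)."""
    ext = external_mode_basis(coords, masses)
    n3 = coords.size
    proj = np.eye(n3) - ext @ ext.T
    evals, evecs = np.linalg.eigh(proj)
    return evecs[:, evals > 0.5]


class Calculator(ABC):
    """Energy/gradient backend contract."""

    name: str = "calculator"
    capabilities: frozenset = CAPABILITIES
    fd_step: float = 0.005  # Å, finite-difference displacement

    @abstractmethod
    def energy(self, s: Structure) -> float: ...

    def gradient(self, s: Structure) -> np.ndarray:
        """dE/dx (N, 3). Default: central finite differences of ``energy``."""
        g = np.zeros_like(s.coords)
        h = self.fd_step
        for i in range(s.natoms):
            for k in range(3):
                cp, cm = s.coords.copy(), s.coords.copy()
                cp[i, k] += h
                cm[i, k] -= h
                g[i, k] = (self.energy(s.with_coords(cp)) - self.energy(s.with_coords(cm))) / (2 * h)
        return g

    def hessian(self, s: Structure) -> np.ndarray:
        """Cartesian Hessian (3N, 3N) by central differences of the gradient."""
        n3 = 3 * s.natoms
        h = self.fd_step
        H = np.zeros((n3, n3))
        flat = s.coords.ravel()
        for k in range(n3):
            xp, xm = flat.copy(), flat.copy()
            xp[k] += h
            xm[k] -= h
            gp = self.gradient(s.with_coords(xp)).ravel()
            gm = self.gradient(s.with_coords(xm)).ravel()
            H[:, k] = (gp - gm) / (2 * h)
        return 0.5 * (H + H.T)

    # ----- minimization ---------------------------------------------------

    def minimize(
        self,
        s: Structure,
        fixed: set[int] | frozenset[int] = frozenset(),
        gtol: float = 1e-6,
        maxiter: int = 2000,
    ) -> Structure:
        fixed = frozenset(fixed)
        free = np.array([i for i in range(s.natoms) if i not in fixed], dtype=int)
        if free.size == 0:
            out = s.copy()
            out.meta["energy"] = self.energy(out)
            return out
        base = s.coords.copy()

        def fun(x):
            c = base.copy()
            c[free] = x.reshape(-1, 3)
            st = s.with_coords(c)
            return self.energy(st), self.gradient(st)[free].ravel()

        res = _sp_minimize(fun, base[free].ravel(), jac=True, method="L-BFGS-B",
                           options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14})
        coords = base.copy()
        coords[free] = res.x.reshape(-1, 3)
        out = s.with_coords(coords)
        out.meta["energy"] = float(res.fun)
        out.meta["min_converged"] = bool(res.success) or float(np.abs(res.jac).max()) < 10 * gtol
        return out

    def constrained_minimize(
        self,
        s: Structure,
        pair: tuple[int, int],
        distance: float | None = None,
        gtol: float = 1e-8,
        maxiter: int = 500,
    ) -> Structure:
        """Minimize with the pair distance frozen at ``distance`` (default: its input value).

        After the SLSQP solve the pair distance is restored exactly by a symmetric
        displacement along the pair axis, so the constraint holds to machine precision.
        """
        i, j = pair
        d0 = float(distance) if distance is not None else s.distance(i, j)

        def fun(x):
            st = s.with_coords(x)
            return self.energy(st), self.gradient(st).ravel()

        def con(x):
            c = x.reshape(-1, 3)
            return float(np.linalg.norm(c[i] - c[j]) - d0)

        def con_jac(x):
            c = x.reshape(-1, 3)
            u = c[i] - c[j]
            u = u / np.linalg.norm(u)
            jrow = np.zeros_like(c)
            jrow[i] = u
            jrow[j] = -u
            return jrow.ravel()

        res = _sp_minimize(fun, s.coords.ravel(), jac=True, method="SLSQP",
                           constraints=[{"type": "eq", "fun": con, "jac": con_jac}],
                           options={"maxiter": maxiter, "ftol": 1e-12})
        coords = res.x.reshape(-1, 3)
        # exact restoration of the constrained distance
        u = coords[i] - coords[j]
        r = np.linalg.norm(u)
        if r > 1e-12:
            shift = 0.5 * (d0 - r) * (u / r)
            coords[i] += shift
            coords[j] -= shift
        out = s.with_coords(coords)
        out.meta["energy"] = self.energy(out)
        out.meta["constrained_pair"] = (int(i), int(j))
        out.meta["constrained_distance"] = d0
        return out

    # ----- second-order machinery ----------------------------------------

    def frequencies(self, s: Structure) -> VibrationalResult:
        """Mass-weighted harmonic analysis with translation/rotation projected out."""
        masses = s.masses()
        H = self.hessian(s)
        w = np.repeat(np.sqrt(masses), 3)
        Hm = H / np.outer(w, w)
        B = internal_basis(s.coords, masses)
        Ht = B.T @ Hm @ B
        evals, evecs = np.linalg.eigh(Ht)
        modes = (B @ evecs).T.reshape(-1, s.natoms, 3)
        freqs = np.sign(evals) * np.sqrt(np.abs(evals)) * FREQ_AU_TO_CM
        order = np.argsort(freqs)
        return VibrationalResult(frequencies=freqs[order], modes=modes[order])

    def saddle_refine(
        self,
        s: Structure,
        gtol: float = 1e-4,
        maxiter: int = 100,
        trust: float = 0.1,
    ) -> Structure:
        """Eigenvector-following refinement to a first-order saddle point.

        Partitioned rational-function step in the internal-coordinate subspace:
        energy is maximized along the lowest Hessian eigenmode and minimized along
        all others, with the step norm capped at the trust radius.  Converges when
        the largest internal gradient component drops below ``gtol``.
        """
        cur = s.copy()
        converged = False
        for _ in range(maxiter):
            g = self.gradient(cur).ravel()
            B = internal_basis(cur.coords)
            gi = B.T @ g
            if np.abs(gi).max() < gtol:
                converged = True
                break
            H = self.hessian(cur)
            Ht = B.T @ H @ B
            evals, evecs = np.linalg.eigh(Ht)
            gm = evecs.T @ gi

            step = np.zeros_like(gm)
            e0, g0 = evals[0], gm[0]
            # RFO shift for maximization along the lowest mode
            lam0 = 0.5 * (e0 + np.sqrt(e0 * e0 + 4.0 * g0 * g0))
            denom0 = e0 - lam0
            step[0] = -g0 / denom0 if abs(denom0) > 1e-10 else 0.2 * trust
            if evals.size > 1:
                rest_e = evals[1:]
                lam1 = min(0.0, rest_e.min() - 1e-2)
                step[1:] = -gm[1:] / (rest_e - lam1)
            norm = np.linalg.norm(step)
            if norm > trust:
                step *= trust / norm
            cur = cur.with_coords(cur.coords + (B @ (evecs @ step)).reshape(-1, 3))
        cur.meta["energy"] = self.energy(cur)
        cur.meta["saddle_converged"] = converged
        return cur
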