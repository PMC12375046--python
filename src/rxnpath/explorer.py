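"""Recursive, parallel multi-step exploration and the reaction network it builds.

Per depth level, every frontier species is screened against the rule library
for active pairs; pairs fan out (worker pool ``npool``) into active-site
conformers, each conformer fans out (worker pool ``npool_tes``) into a TS
search + IRC connection, and the surviving elementary steps are barrier-filtered,
deduplicated, and merged into a species/step multigraph whose new products seed
the next depth.  Both pools are pure maps over independent tasks collected in
task order, so a serial run and a parallel run of the same configuration build
the same network.
"""

from __future__ import annotations

import itertools
import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass

import networkx as nx

from .conformers import RotationGrid, rotate_conformers, rotation_test_classify
from .constants import HARTREE_TO_KCALMOL
from .potentials.calculator import Calculator
from .potentials.species import canonical_species_id
from .potentials.structure import Structure
from .potentials.u import UParams
from .rules import RuleLibrary, enumerate_active_pairs
from .tslocate import ElementaryStep, assemble_step, locate_ts, IRCError

TS_ENERGY_BUCKET = 1e-4  # Hartree; edge-key granularity for duplicate channels


@dataclass
class ExplorationConfig:
    """One exploration run's knobs (energies in Hartree, lengths in Å)."""

    max_depth: int = 1
    barrier_thresh: float = 0.05
    conformer_e_thresh: float = 0.01
    rmsd_thresh: float = 0.1
    npool: int = 1
    npool_tes: int = 1
    chiral: bool = False
    seed: int = 0
    backend: str = "upotential"
    max_iter_ts: int = 8
    spin_steps: int = 6
    orbit_steps: int = 6
    energy_window: float | None = 0.15  # frontier admission above the lowest species; None = off
    filter_mode: str = "report"         # 'report': keep high-barrier edges, flag them; 'prune': drop

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.barrier_thresh <= 0 or self.conformer_e_thresh <= 0 or self.rmsd_thresh <= 0:
            raise ValueError("thresholds must be positive")
        if self.npool < 1 or self.npool_tes < 1:
            raise ValueError("worker counts must be >= 1")
        if self.filter_mode not in ("report", "prune"):
            raise ValueError("filter_mode must be 'report' or 'prune'")

    def grid(self) -> RotationGrid:
        return RotationGrid(spin_steps=self.spin_steps, orbit_steps=self.orbit_steps)


@dataclass
class SpeciesRecord:
    species_id: str
    structure: Structure
    energy: float
    depth: int


class ReactionNetwork:
    """Species-node / step-edge multigraph with provenance."""

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()
        self.provenance: list[dict] = []

    # -- species ----------------------------------------------------------

    @property
    def species(self) -> dict[str, SpeciesRecord]:
        return {n: d["record"] for n, d in self.graph.nodes(data=True)}

    def add_species(self, rec: SpeciesRecord) -> bool:
        if rec.species_id in self.graph:
            return False
        self.graph.add_node(rec.species_id, record=rec)
        return True

    def depth_of(self, species_id: str) -> int:
        return self.graph.nodes[species_id]["record"].depth

    # -- steps ------------------------------------------------------------

    @staticmethod
    def edge_key(step: ElementaryStep) -> int:
        return int(round(step.ts.energy / TS_ENERGY_BUCKET))

    def steps(self) -> list[ElementaryStep]:
        return [d["step"] for *_, d in self.graph.edges(data=True)]

    def edge_set(self) -> set[tuple[str, str, int]]:
        return set(self.graph.edges(keys=True))

    def add_step(self, step: ElementaryStep, **attrs) -> None:
        self.graph.add_edge(step.reactant_id, step.product_id, key=self.edge_key(step),
                            step=step, barrier=step.barrier, delta_e=step.delta_e, **attrs)

    def log(self, **event) -> None:
        self.provenance.append(event)

    def provenance_json(self) -> str:
        return json.dumps(self.provenance, indent=1, sort_keys=True)


# ----- step-level predicates ---------------------------------------------


def filter_step(step: ElementaryStep, cfg: ExplorationConfig) -> bool:
    """Keep iff the barrier does not exceed the threshold (ties kept)."""
    return step.barrier <= cfg.barrier_thresh


def dedup_step(network: ReactionNetwork, step: ElementaryStep,
               chiral: bool = False) -> tuple[str, ElementaryStep | None]:
    """('new', None) or ('duplicate_of', existing step).

    Duplicate: an existing edge with the same endpoint ids whose TS energy agrees
    within the bucket width.  With chirality on, the rotation test refines the
    call — mirror-image channels stay distinct (tagged 'enantiomeric').
    """
    u, v = step.reactant_id, step.product_id
    if network.graph.has_edge(u, v):
        for _key, data in network.graph[u][v].items():
            other = data["step"]
            if abs(other.ts.energy - step.ts.energy) < TS_ENERGY_BUCKET:
                if chiral:
                    verdict = rotation_test_classify(step, other)
                    if verdict == "enantiomeric":
                        return "new", None
                    if verdict == "distinct":
                        return "new", None
                return "duplicate_of", other
    return "new", None


# ----- worker tasks (module-level: picklable for the process pools) -------


def _conformer_task(args):
    (sid, structure, pair, grid, p, e_thresh, rmsd_thresh, calc) = args
    try:
        confs = rotate_conformers(structure, pair, grid, p, e_thresh, rmsd_thresh, calc)
        return sid, pair, [c for c in confs], None
    except Exception as exc:  # noqa: BLE001 — worker errors become provenance, not crashes
        return sid, pair, [], f"{type(exc).__name__}: {exc}"


def _ts_task(args):
    (sid, pair, conformer, calc, p, max_iter, rank_basis, chiral) = args
    # the U-relaxed pose is only a starting arrangement: bring it to a genuine
    # minimum of the real surface before the saddle search
    conformer = calc.minimize(conformer)
    result = locate_ts(conformer, pair, calc, p, max_iter=max_iter, rank_basis=rank_basis)
    if not result.ok:
        return sid, pair, None, result.failure.record() if result.failure else {"reason": "unknown"}
    try:
        step = assemble_step(conformer, pair, result, calc, chiral=chiral)
    except IRCError as exc:
        return sid, pair, None, {"reason": str(exc)}
    return sid, pair, step, None


def _pmap(fn, items, nworkers: int):
    items = list(items)
    if nworkers <= 1 or len(items) <= 1:
        return [fn(x) for x in items]
    with ProcessPoolExecutor(max_workers=nworkers) as ex:
        return list(ex.map(fn, items, chunksize=1))


# ----- the recursion ------------------------------------------------------


def explore(
    seeds: list[Structure],
    lib: RuleLibrary,
    cfg: ExplorationConfig,
    calc: Calculator,
    p: UParams,
) -> ReactionNetwork:
    """Breadth-wise recursive exploration from the seed species to ``cfg.max_depth``."""
    if not seeds:
        raise ValueError("at least one seed structure is required")
    net = ReactionNetwork()
    frontier: list[str] = []
    for seed in seeds:
        opt = calc.minimize(seed)
        sid = canonical_species_id(opt, chiral=cfg.chiral)
        if net.add_species(SpeciesRecord(sid, opt, opt.meta["energy"], depth=0)):
            frontier.append(sid)
            net.log(event="seed", species=sid, energy=opt.meta["energy"], depth=0)

    grid = cfg.grid()
    for depth in range(1, cfg.max_depth + 1):
        # stage 1: active pairs on the frontier, then conformers (npool)
        pair_tasks = []
        for sid in sorted(frontier):
            rec = net.species[sid]
            pairs = enumerate_active_pairs(rec.structure, lib)
            net.log(event="pairs_enumerated", depth=depth, species=sid, n_pairs=len(pairs))
            for pair in pairs:
                pair_tasks.append((sid, rec.structure, pair, grid, p,
                                   cfg.conformer_e_thresh, cfg.rmsd_thresh, calc))
        conf_results = _pmap(_conformer_task, pair_tasks, cfg.npool)

        # stage 2: TS search + IRC per conformer (npool_tes)
        ts_tasks = []
        for sid, pair, confs, err in conf_results:
            if err is not None:
                net.log(event="conformers_failed", depth=depth, species=sid,
                        pair=[pair.i, pair.j, pair.action], error=err)
                continue
            net.log(event="conformers", depth=depth, species=sid,
                    pair=[pair.i, pair.j, pair.action], n_conformers=len(confs))
            for conf in confs:
                ts_tasks.append((sid, pair, conf, calc, p, cfg.max_iter_ts, "pair", cfg.chiral))
        ts_results = _pmap(_ts_task, ts_tasks, cfg.npool_tes)

        # stage 3: filter, dedup, admit — strictly in task order (determinism)
        attempted = kept = dropped = 0
        new_frontier: list[str] = []
        emin = min((r.energy for r in net.species.values()), default=0.0)
        for sid, pair, step, failure in ts_results:
            if step is None:
                net.log(event="ts_failed", depth=depth, species=sid,
                        pair=[pair.i, pair.j, pair.action], failure=failure)
                continue
            attempted += 1
            passes = filter_step(step, cfg)
            if cfg.filter_mode == "prune" and not passes:
                dropped += 1
                net.log(event="step_filtered", depth=depth, species=sid,
                        pair=[pair.i, pair.j, pair.action],
                        barrier=step.barrier, thresh=cfg.barrier_thresh)
                continue
            verdict, dup = dedup_step(net, step, chiral=cfg.chiral)
            if verdict == "duplicate_of":
                kept += 1  # counted as processed; edge already present
                net.log(event="step_duplicate", depth=depth, species=sid,
                        reactant=step.reactant_id, product=step.product_id,
                        ts_energy=step.ts.energy)
                continue
            for endpoint, st in (("reactant", step.reactant), ("product", step.product)):
                eid = canonical_species_id(st, chiral=cfg.chiral)
                if eid not in net.graph:
                    e = st.meta.get("energy", calc.energy(st))
                    admit = cfg.energy_window is None or e <= emin + cfg.energy_window
                    net.add_species(SpeciesRecord(eid, st, e, depth=depth))
                    net.log(event="species_discovered", depth=depth, species=eid,
                            energy=e, admitted=admit, via=endpoint)
                    if admit:
                        new_frontier.append(eid)
            net.add_step(step, depth=depth, passes_filter=passes)
            kept += 1
            net.log(event="step_kept", depth=depth, species=sid,
                    reactant=step.reactant_id, product=step.product_id,
                    barrier=step.barrier, delta_e=step.delta_e,
                    thresh=cfg.barrier_thresh, passes_filter=passes)
        net.log(event="depth_summary", depth=depth, attempted=attempted,
                kept=kept, dropped=dropped)
        frontier = sorted(set(new_frontier))
        if not frontier:
            break
    if not net.steps():
        net.log(event="empty_network_warning",
                note="no elementary steps found at any depth")
    return net


# ----- pathway extraction -------------------------------------------------


@dataclass
class Pathway:
    steps: list[ElementaryStep]
    span: float      # max over edges of E(ts) − E(source), Hartree
    delta_e: float   # total reaction energy along the path, Hartree

    @property
    def species(self) -> list[str]:
        return [self.steps[0].reactant_id] + [s.product_id for s in self.steps]


def extract_pathways(
    network: ReactionNetwork,
    source_id: str,
    sink_id: str | None = None,
    max_steps: int = 6,
    barrier_thresh: float | None = None,
    max_paths: int = 500,
) -> list[Pathway]:
    """Simple paths from the source (to the sink, or to anywhere), every edge under
    the barrier threshold, ranked by effective span ascending (ties by total ΔE).

    Parallel edges between the same species are enumerated as distinct channels,
    capped at ``max_paths`` total.
    """
    g = network.graph
    if source_id not in g:
        raise KeyError(f"unknown source species {source_id!r}")
    e_source = network.species[source_id].energy
    allowed = {}
    for u, v, k, d in g.edges(keys=True, data=True):
        if barrier_thresh is not None and d["barrier"] > barrier_thresh:
            continue
        allowed.setdefault((u, v), []).append(d["step"])

    adj: dict[str, list[str]] = {}
    for (u, v) in allowed:
        adj.setdefault(u, []).append(v)

    node_paths: list[list[str]] = []

    def dfs(node, path):
        if sink_id is not None and node == sink_id and len(path) > 1:
            node_paths.append(list(path))
            return
        if sink_id is None and len(path) > 1:
            node_paths.append(list(path))
        if len(path) - 1 >= max_steps:
            return
        for nxt in sorted(adj.get(node, [])):
            if nxt in path:
                continue
            path.append(nxt)
            dfs(nxt, path)
            path.pop()

    dfs(source_id, [source_id])

    pathways: list[Pathway] = []
    for nodes in node_paths:
        hop_choices = [allowed[(nodes[i], nodes[i + 1])] for i in range(len(nodes) - 1)]
        for combo in itertools.product(*hop_choices):
            span = max(s.ts.energy - e_source for s in combo)
            delta = sum(s.delta_e for s in combo)
            pathways.append(Pathway(steps=list(combo), span=span, delta_e=delta))
            if len(pathways) >= max_paths:
                break
        if len(pathways) >= max_paths:
            break
    pathways.sort(key=lambda pw: (pw.span, pw.delta_e))
    return pathways


# ----- export -------------------------------------------------------------


def network_to_graphml(network: ReactionNetwork, path) -> None:
    """GraphML export with primitive species/step attributes (Hartree and kcal/mol)."""
    g = nx.MultiDiGraph()
    for sid, rec in network.species.items():
        g.add_node(sid, energy_hartree=rec.energy,
                   energy_kcalmol=rec.energy * HARTREE_TO_KCALMOL, depth=rec.depth,
                   formula="".join(sorted(rec.structure.elements)))
    for u, v, k, d in network.graph.edges(keys=True, data=True):
        step: ElementaryStep = d["step"]
        g.add_edge(u, v, key=k,
                   barrier_hartree=step.barrier,
                   barrier_kcalmol=step.barrier * HARTREE_TO_KCALMOL,
                   delta_e_hartree=step.delta_e,
                   ts_energy_hartree=step.ts.energy,
                   rule_ids=",".join(sorted(step.pair.rule_ids)),
                   pair=f"{step.pair.i}-{step.pair.j}:{step.pair.action}")
    nx.write_graphml(g, path)


def network_to_json(network: ReactionNetwork) -> dict:
    """Full-provenance JSON document (structures as element/coordinate lists)."""
    def struct(s: Structure):
        return {"elements": s.elements, "coords": s.coords.tolist(),
                "charge": s.charge, "multiplicity": s.multiplicity,
                "energy": s.meta.get("energy")}

    return {
        "species": {sid: {"energy": rec.energy, "depth": rec.depth,
                          "structure": struct(rec.structure)}
                    for sid, rec in network.species.items()},
        "steps": [{"reactant": s.reactant_id, "product": s.product_id,
                   "barrier": s.barrier, "delta_e": s.delta_e,
                   "ts_energy": s.ts.energy,
                   "pair": [s.pair.i, s.pair.j, s.pair.action],
                   "rule_ids": sorted(s.pair.rule_ids),
                   "ts_structure": struct(s.ts.structure)}
                  for s in network.steps()],
        "provenance": network.provenance,
    }
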