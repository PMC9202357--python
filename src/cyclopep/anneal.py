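"""Restrained simulated annealing for macrocycle closure.

The cyclization protocol runs the energy surrogate through two annealing
passes:

* **Distance reduction** — starting from the beta and polyproline-II
  linear conformers, restrained annealing pulls the bond-forming atoms
  together.  The peptide is fully flexible in every phase, electrostatics
  is off during annealing, and the run finishes with a restrained
  minimisation.  400 models per run by default.
* **Cycle closure** — cluster representatives whose closure geometry meets
  the thresholds (N–C within 3.5 Å for head-to-tail, Sγ–Sγ within 4 Å for
  a disulfide) have the covalent bond(s) added to the topology.  The
  restraints act only in the first two annealing phases; the final phase
  is an unrestrained relaxation with doubled step budget.

Four annealing phases mirror the semiflexible-refinement stages with all
step counts multiplied by four: (500, 500, 1000, 1000) × 4 =
(2000, 2000, 4000, 4000), cooling geometrically from 1000 to 50 thermal
units.  Reduced step/model counts are used throughout the test suite.

Each model draws its velocities from a counter-based random stream
``(master_seed, model_index)`` so runs are reproducible and order
independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .builder import build_linear_peptide, end_to_end_distance
from .clustering import cluster_by_rmsd, select_representatives
from .core import (BackboneState, Conformation, Cyclization, CyclopepError,
                   PeptideSpec, RestraintKind, RestraintSet)
from .energy import CompiledTerms, EnergyModel, compile_terms, evaluate
from .geometry import dihedral
from .restraints import cyclization_restraints

__all__ = ["Stage", "AnnealingSchedule", "reduce_distance_step2",
           "close_cycle_step3", "generate_ensemble", "score_table", "relax",
           "closure_satisfied", "close_topology", "compile_closed_terms",
           "CLOSURE_CN_MAX", "CLOSURE_SS_MAX"]

CLOSURE_CN_MAX = 3.5      # Å, max N-C distance for head-to-tail bond formation
CLOSURE_SS_MAX = 4.0      # Å, max Sγ-Sγ distance for disulfide formation

_SIDECHAIN_EXCLUDE = ("N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3")


@dataclass(frozen=True)
class Stage:
    """One annealing phase: step count, cooling window, flexibility,
    restraint scaling and the electrostatics flag."""

    steps: int
    t_start: float
    t_end: float
    move: str = "all"                 # all | side_chains | backbone_side_chains | none
    restraint_scale: float = 1.0
    electrostatics: bool = False


@dataclass(frozen=True)
class AnnealingSchedule:
    stages: tuple[Stage, ...]
    final_minimize: bool = True
    final_restraints: bool = True     # keep restraints during final relaxation
    final_maxiter: int = 200
    dt: float = 0.02
    friction: float = 0.85
    kb: float = 0.005                 # thermal-unit -> energy conversion
    grad_clip: float = 200.0          # per-atom gradient norm cap

    @classmethod
    def cyclization(cls, step_scale: float = 1.0, *,
                    restraints_in_all: bool = True) -> "AnnealingSchedule":
        """The four-phase cyclization schedule.

        ``step_scale=1`` gives the production (2000, 2000, 4000, 4000)
        phases; smaller values scale the sampling down proportionally.
        ``restraints_in_all=False`` restricts the restraints to the first
        two phases and doubles the final relaxation budget (cycle-closure
        variant).
        """
        base = (2000, 2000, 4000, 4000)
        temps = [1000.0 * (50.0 / 1000.0) ** (k / 4.0) for k in range(5)]
        scales = (1.0, 1.0, 1.0, 1.0) if restraints_in_all else (1.0, 1.0, 0.0, 0.0)
        stages = tuple(
            Stage(steps=max(1, int(round(s * step_scale))), t_start=temps[k],
                  t_end=temps[k + 1], move="all", restraint_scale=scales[k])
            for k, s in enumerate(base))
        return cls(stages=stages,
                   final_restraints=restraints_in_all,
                   final_maxiter=200 if restraints_in_all else 400)

    @property
    def total_steps(self) -> int:
        return sum(s.steps for s in self.stages)


def _move_mask(conf: Conformation, move: str) -> np.ndarray:
    if move == "all":
        return np.ones(conf.n_atoms, bool)
    if move == "none":
        return np.zeros(conf.n_atoms, bool)
    side = ~np.isin(conf.atom_name, _SIDECHAIN_EXCLUDE)
    if move == "side_chains":
        return side
    if move == "backbone_side_chains":
        return np.ones(conf.n_atoms, bool)
    raise CyclopepError(f"unknown flexibility mode {move!r}")


def _anneal_once(conf: Conformation, terms: CompiledTerms, model: EnergyModel,
                 schedule: AnnealingSchedule, rng: np.random.Generator) -> np.ndarray:
    """Langevin-style annealing in Cartesian space; returns new coordinates."""
    x = conf.coords.copy()
    v = np.zeros_like(x)
    dt, c1 = schedule.dt, schedule.friction
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    started = False
    for stage in schedule.stages:
        if stage.steps <= 0:
            continue
        mask = _move_mask(conf, stage.move)[:, None]
        stage_model = replace(model, electrostatics=stage.electrostatics)
        if not started:
            v = rng.standard_normal(x.shape) * np.sqrt(schedule.kb * stage.t_start)
            started = True
        temps = np.geomspace(stage.t_start, stage.t_end, stage.steps)
        for step in range(stage.steps):
            _, g = evaluate(x, terms, stage_model,
                            restraint_scale=stage.restraint_scale)
            norms = np.linalg.norm(g, axis=1, keepdims=True)
            g = np.where(norms > schedule.grad_clip,
                         g * (schedule.grad_clip / np.maximum(norms, 1e-12)), g)
            sigma = np.sqrt(schedule.kb * temps[step])
            v = c1 * (v - dt * g) + c2 * sigma * rng.standard_normal(x.shape)
            x = x + dt * v * mask
    if schedule.final_minimize:
        scale = 1.0 if schedule.final_restraints else 0.0
        x = relax(x, terms, model, restraint_scale=scale,
                  maxiter=schedule.final_maxiter)
    return x


def relax(coords: np.ndarray, terms: CompiledTerms, model: EnergyModel,
          restraint_scale: float = 0.0, maxiter: int = 200) -> np.ndarray:
    """Final-refinement surrogate: L-BFGS minimisation with the
    distance-dependent-dielectric electrostatics switched on.

    The minimiser never returns a higher-energy point than its input.
    """
    final_model = replace(model, electrostatics=True)
    shape = np.asarray(coords).shape

    def fun(flat):
        e, g = evaluate(flat.reshape(shape), terms, final_model,
                        restraint_scale=restraint_scale)
        return e, g.ravel()

    e0 = fun(np.asarray(coords).ravel())[0]
    res = minimize(fun, np.asarray(coords).ravel(), jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    if res.fun > e0:           # safeguard: keep the input if no progress
        return np.asarray(coords).reshape(shape)
    return res.x.reshape(shape)


def _score(coords, terms, model) -> tuple[float, dict]:
    e, _, parts = evaluate(coords, terms, model, breakdown=True)
    return e, parts


def reduce_distance_step2(start_ensemble: list[Conformation], spec: PeptideSpec,
                          seed: int, n_models: int = 400,
                          schedule: AnnealingSchedule | None = None,
                          model: EnergyModel | None = None,
                          restraints: RestraintSet | None = None
                          ) -> list[Conformation]:
    """Distance-reduction annealing: pull the cyclization atoms together.

    Starting members alternate between the ensemble's conformers; each of
    the ``n_models`` models uses its own velocity stream derived from
    ``seed``.  Models carry an ``energy`` label (internal + restraint
    score) and the measured closure distances.
    """
    if not start_ensemble:
        raise CyclopepError("empty starting ensemble")
    schedule = schedule or AnnealingSchedule.cyclization()
    model = model or EnergyModel()
    restraints = restraints if restraints is not None else cyclization_restraints(spec)
    _check_restraint_kind(restraints, spec)
    terms = compile_terms(start_ensemble[0], model, restraints)
    if schedule.total_steps == 0 and not schedule.final_minimize:
        out = []
        for m in range(n_models):
            c = start_ensemble[m % len(start_ensemble)].copy()
            c.labels.update(model_id=m, seed=seed, stage="step2")
            out.append(c)
        return out
    out = []
    for m in range(n_models):
        start = start_ensemble[m % len(start_ensemble)]
        rng = np.random.default_rng([int(seed), int(m)])
        coords = _anneal_once(start, terms, model, schedule, rng)
        energy, parts = _score(coords, terms, model)
        new = start.with_coords(coords)
        new.labels.update(model_id=m, seed=seed, stage="step2",
                          energy=energy, terms={k: round(v, 3) for k, v in parts.items()},
                          closure=_closure_distances(new, spec))
        out.append(new)
    return out


def _closure_distances(conf: Conformation, spec: PeptideSpec) -> dict:
    d = {}
    if spec.cyclization in (Cyclization.BACKBONE, Cyclization.COMBINED):
        d["n_c"] = round(end_to_end_distance(conf, "backbone"), 3)
    if spec.cyclization in (Cyclization.DISULFIDE, Cyclization.COMBINED):
        d["sg_sg"] = round(end_to_end_distance(conf, "disulfide"), 3)
    return d


def _check_restraint_kind(restraints: RestraintSet, spec: PeptideSpec):
    expected = {Cyclization.BACKBONE: RestraintKind.BACKBONE_CYCLE,
                Cyclization.DISULFIDE: RestraintKind.DISULFIDE_CYCLE,
                Cyclization.COMBINED: RestraintKind.COMBINED_CYCLE}[spec.cyclization]
    if restraints.kind is not expected:
        raise CyclopepError(
            f"restraint kind {restraints.kind.value} does not match "
            f"cyclization mode {spec.cyclization.value}")


# -- cycle closure -------------------------------------------------------

def closure_satisfied(conf: Conformation, spec: PeptideSpec) -> bool:
    """Closure criteria: N-C within 3.5 Å and/or Sγ-Sγ within 4 Å."""
    ok = True
    if spec.cyclization in (Cyclization.BACKBONE, Cyclization.COMBINED):
        ok &= end_to_end_distance(conf, "backbone") <= CLOSURE_CN_MAX
    if spec.cyclization in (Cyclization.DISULFIDE, Cyclization.COMBINED):
        ok &= end_to_end_distance(conf, "disulfide") <= CLOSURE_SS_MAX
    return bool(ok)


def close_topology(conf: Conformation, spec: PeptideSpec) -> Conformation:
    """Edit the covalent topology to the closed form.

    Head-to-tail closure removes the C-terminal carboxylate OXT and two of
    the three N-terminal amine hydrogens (the survivor becomes the amide
    H), then bonds C(last) to N(first).  Disulfide closure bonds the two
    Sγ (their thiol hydrogens are absent for a declared pair already).
    """
    new = conf.copy()
    if spec.cyclization in (Cyclization.BACKBONE, Cyclization.COMBINED):
        first = spec.resid_of(1)
        last = spec.resid_of(spec.n_residues)
        remove = ((new.resid == last) & (new.atom_name == "OXT")) | \
                 ((new.resid == first) & np.isin(new.atom_name, ("H2", "H3")))
        new = new.subset(~remove)
        h1 = (new.resid == first) & (new.atom_name == "H1")
        new.atom_name[h1] = "H"
        bond = [new.index_of(last, "C"), new.index_of(first, "N")]
        new.bonds = np.vstack([new.bonds, bond])
    if spec.cyclization in (Cyclization.DISULFIDE, Cyclization.COMBINED):
        i, j = (spec.resid_of(p) for p in spec.disulfide_pair)
        bond = [new.index_of(i, "SG"), new.index_of(j, "SG")]
        new.bonds = np.vstack([new.bonds, bond])
    new.labels["closed"] = spec.cyclization.value
    return new


_CLOSURE_BOND = {"C-N": 1.329, "SG-SG": 2.04}
_CLOSURE_ANGLE = {("CA", "C", "N"): 116.2, ("O", "C", "N"): 123.0,
                  ("C", "N", "CA"): 121.7, ("C", "N", "H"): 119.2,
                  ("C", "N", "CD"): 121.0, ("CB", "SG", "SG"): 104.2}


def _closure_overrides(ref_closed: Conformation, spec: PeptideSpec) -> dict:
    """Equilibrium values for terms spanning the new bond(s).

    Bond lengths and angles come from ideal amide/disulfide geometry;
    improper equilibria at the rebonded centres are measured by analogy
    from the chemically identical junction between residues 1 and 2 of
    the linear reference.
    """
    overrides: dict = {}
    closure_atoms: list[tuple[int, int]] = []   # (index, analog resid)
    first = spec.resid_of(1)
    last = spec.resid_of(spec.n_residues)
    if spec.cyclization in (Cyclization.BACKBONE, Cyclization.COMBINED):
        closure_atoms.append((ref_closed.index_of(last, "C"), first))
        closure_atoms.append((ref_closed.index_of(first, "N"), first + 1))
    adj = [[] for _ in range(ref_closed.n_atoms)]
    for i, j in ref_closed.bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))

    spanning = set()
    if spec.cyclization in (Cyclization.BACKBONE, Cyclization.COMBINED):
        c_idx = ref_closed.index_of(last, "C")
        n_idx = ref_closed.index_of(first, "N")
        spanning.add((min(c_idx, n_idx), max(c_idx, n_idx)))
        overrides[frozenset((c_idx, n_idx))] = _CLOSURE_BOND["C-N"]
        # angles around the new bond
        for centre, other_end in ((c_idx, n_idx), (n_idx, c_idx)):
            for nb in adj[centre]:
                if nb == other_end:
                    continue
                key = (str(ref_closed.atom_name[nb]), str(ref_closed.atom_name[centre]),
                       str(ref_closed.atom_name[other_end]))
                val = _CLOSURE_ANGLE.get(key, _CLOSURE_ANGLE.get(key[::-1], 120.0))
                overrides[frozenset((nb, centre, other_end))] = val
        # impropers at the rebonded centres, by analogy with the 1->2 junction
        analog_resid = {c_idx: first, n_idx: first + 1}
        for centre in (c_idx, n_idx):
            if len(adj[centre]) < 3:
                continue
            n1, n2, n3 = sorted(adj[centre])[:3]
            try:
                analog = [_analog_atom(ref_closed, k, centre, analog_resid[centre],
                                       first, last) for k in (centre, n1, n2, n3)]
                val = dihedral(*(ref_closed.coords[a] for a in analog))
            except CyclopepError:
                val = None                      # drop the term
            overrides[frozenset((centre, n1, n2, n3))] = val
    if spec.cyclization in (Cyclization.DISULFIDE, Cyclization.COMBINED):
        i, j = (spec.resid_of(p) for p in spec.disulfide_pair)
        si = ref_closed.index_of(i, "SG")
        sj = ref_closed.index_of(j, "SG")
        overrides[frozenset((si, sj))] = _CLOSURE_BOND["SG-SG"]
        for centre, other in ((si, sj), (sj, si)):
            for nb in adj[centre]:
                if nb != other:
                    overrides[frozenset((nb, centre, other))] = _CLOSURE_ANGLE[("CB", "SG", "SG")]
    return overrides


def _analog_atom(conf: Conformation, idx: int, centre: int, analog_resid: int,
                 first: int, last: int) -> int:
    """Map a closure-junction atom to its analog at the 1->2 junction."""
    resid = int(conf.resid[idx])
    name = str(conf.atom_name[idx])
    if resid == last:
        return conf.index_of(first, name)
    if resid == first:
        return conf.index_of(first + 1, name)
    raise CyclopepError(f"no junction analog for atom {name} of residue {resid}")


def compile_closed_terms(spec: PeptideSpec, model: EnergyModel,
                         restraints: RestraintSet | None = None
                         ) -> tuple[Conformation, CompiledTerms]:
    """Closed-topology reference conformation and its energy terms.

    The linear beta build provides ideal equilibria for every local term;
    terms spanning the new bond(s) take ideal closure values.
    """
    ref = build_linear_peptide(spec, BackboneState.BETA)
    ref_closed = close_topology(ref, spec)
    overrides = _closure_overrides(ref_closed, spec)
    terms = compile_terms(ref_closed, model, restraints, term_overrides=overrides)
    return ref_closed, terms


def close_cycle_step3(representatives: list[Conformation], spec: PeptideSpec,
                      seed: int, n_models: int = 400,
                      schedule: AnnealingSchedule | None = None,
                      model: EnergyModel | None = None) -> list[Conformation]:
    """Form the covalent cycle on eligible representatives and relax.

    Representatives failing the closure criteria are skipped; if none
    passes, the run aborts with advice to rerun the distance-reduction
    step.  ``n_models`` models are distributed round-robin over the
    eligible representatives, each with its own velocity stream.
    """
    model = model or EnergyModel()
    schedule = schedule or AnnealingSchedule.cyclization(restraints_in_all=False)
    eligible = [r for r in representatives if closure_satisfied(r, spec)]
    if not eligible:
        raise CyclopepError(
            "no representative satisfies the closure criteria "
            f"(N-C <= {CLOSURE_CN_MAX} Å / S-S <= {CLOSURE_SS_MAX} Å); "
            "rerun the distance-reduction step with more sampling")
    restraints = cyclization_restraints(spec)
    _, terms = compile_closed_terms(spec, model, restraints)
    out = []
    for m in range(n_models):
        start = close_topology(eligible[m % len(eligible)], spec)
        rng = np.random.default_rng([int(seed), 1, int(m)])
        coords = _anneal_once(start, terms, model, schedule, rng)
        energy, parts = _score(coords, terms, model)
        new = start.with_coords(coords)
        new.labels.update(model_id=m, seed=seed, stage="step3",
                          energy=energy, terms={k: round(v, 3) for k, v in parts.items()},
                          closure=_closure_distances(new, spec))
        out.append(new)
    return out


def generate_ensemble(spec: PeptideSpec, n_seeds: int, master_seed: int = 0,
                      n_models: int = 400, cluster_cutoff: float = 2.5,
                      max_representatives: int = 10,
                      schedule_step2: AnnealingSchedule | None = None,
                      schedule_step3: AnnealingSchedule | None = None,
                      model: EnergyModel | None = None) -> list[Conformation]:
    """Full cyclization pipeline: build → reduce → close, once per seed.

    Each seed's models are clustered (2.5 Å backbone RMSD) and up to
    ``max_representatives`` cluster centers contribute to the ensemble, so
    the ensemble holds at most ``10 × n_seeds`` conformations.  Members
    carry ``(seed, cluster rank)`` tags.
    """
    if n_seeds < 1:
        raise CyclopepError("n_seeds must be >= 1")
    starts = [build_linear_peptide(spec, s) for s in (BackboneState.BETA,
                                                      BackboneState.POLYPRO)]
    step2 = reduce_distance_step2(starts, spec, seed=master_seed,
                                  n_models=n_models, schedule=schedule_step2,
                                  model=model)
    sel2 = step2[0].backbone_mask()
    clusters2 = cluster_by_rmsd(step2, cluster_cutoff, sel2)
    reps2 = select_representatives(clusters2, step2, max_representatives)
    ensemble: list[Conformation] = []
    for k in range(n_seeds):
        seed_k = master_seed + 1 + k
        models3 = close_cycle_step3(reps2, spec, seed=seed_k,
                                    n_models=n_models, schedule=schedule_step3,
                                    model=model)
        sel3 = models3[0].backbone_mask()
        clusters3 = cluster_by_rmsd(models3, cluster_cutoff, sel3)
        reps3 = select_representatives(clusters3, models3, max_representatives)
        for rep in reps3:
            rep.labels["ensemble_seed"] = seed_k
        ensemble.extend(reps3)
    return ensemble


def score_table(models: list[Conformation]) -> str:
    """Per-model TSV: id, energy terms, restraint energy, closure distances."""
    term_keys = sorted({k for m in models for k in m.labels.get("terms", {})})
    closure_keys = sorted({k for m in models for k in m.labels.get("closure", {})})
    header = ["model_id", "stage", "energy"] + term_keys + closure_keys
    lines = ["\t".join(header)]
    for m in models:
        lab = m.labels
        row = [str(lab.get("model_id", "")), str(lab.get("stage", "")),
               f"{lab.get('energy', float('nan')):.3f}"]
        row += [f"{lab.get('terms', {}).get(k, float('nan')):.3f}" for k in term_keys]
        row += [f"{lab.get('closure', {}).get(k, float('nan')):.3f}" for k in closure_keys]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
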