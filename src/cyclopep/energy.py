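"""Desk-scale molecular-mechanics surrogate used by the cyclization engine.

The protocol's physics requirements are modest: preserve covalent geometry
and chirality while distance restraints reshape the backbone.  The energy
model therefore has five weighted terms

* harmonic bonds and angles whose equilibria are *measured from the
  as-built ideal-geometry conformer* (template terms),
* periodic torsion/improper terms, ``k (1 - cos(phi - phi0))`` — trans
  amide planarity plus one improper per >=3-coordinated centre, which
  locks chirality and ring planarity,
* a purely repulsive truncated-and-shifted Lennard-Jones contact term
  (C1-continuous, zero beyond the contact radius),
* optional Coulomb electrostatics with a distance-dependent dielectric
  and coarse formal-charge-derived partial charges (off during the
  annealing phases of the protocol),
* a flat-bottom "soft-square" restraint penalty: zero inside
  ``[d - d-, d + d+]``, harmonic outside, switching to a linear asymptote
  beyond a switch offset.

All gradients are analytic; a finite-difference cross-check lives in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Conformation, CyclopepError, DistanceRestraint, RestraintSet

__all__ = ["EnergyModel", "CompiledTerms", "compile_terms", "energy_and_gradient",
           "assign_charges"]

_VDW_RADIUS = {"H": 1.0, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}
_COULOMB = 332.0636       # kcal mol^-1 Å e^-2


@dataclass
class EnergyModel:
    """Term weights (force constants) of the surrogate force field."""

    k_bond: float = 300.0          # kcal/mol/Å^2
    k_angle: float = 60.0          # kcal/mol/rad^2
    k_torsion: float = 15.0        # kcal/mol, periodic amide/closure torsions
    k_improper: float = 40.0       # kcal/mol, chirality / planarity
    eps_repulsive: float = 1.0     # kcal/mol, contact repulsion depth scale
    contact_scale: float = 0.85    # fraction of summed vdW radii
    k_restraint: float = 50.0      # kcal/mol/Å^2
    restraint_switch: float = 2.0  # Å, harmonic->linear switch offset
    electrostatics: bool = False
    dielectric_scale: float = 4.0  # epsilon(r) = scale * r


@dataclass
class CompiledTerms:
    """Indexed term lists with equilibria, bound to one topology."""

    n_atoms: int
    bond_idx: np.ndarray            # (nb, 2)
    bond_r0: np.ndarray
    angle_idx: np.ndarray           # (na, 3)
    angle_t0: np.ndarray            # radians
    torsion_idx: np.ndarray         # (nt, 4) periodic: amide omega etc.
    torsion_p0: np.ndarray          # radians
    improper_idx: np.ndarray        # (ni, 4) central atom first
    improper_p0: np.ndarray         # radians
    nb_pairs: np.ndarray            # (np, 2) non-excluded pairs
    nb_rmin: np.ndarray
    charges: np.ndarray
    restraint_pairs: list = field(default_factory=list)
    # each entry: (idx_i (k,), idx_j (m,), lo, hi) resolved atom indices


def _neighbour_lists(n_atoms: int, bonds: np.ndarray):
    adj = [[] for _ in range(n_atoms)]
    for i, j in bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    return adj


def _angles_from_bonds(adj):
    out = []
    for j, nbrs in enumerate(adj):
        srt = sorted(nbrs)
        for a in range(len(srt)):
            for b in range(a + 1, len(srt)):
                out.append((srt[a], j, srt[b]))
    return out


def _exclusions(adj, n_atoms: int):
    """1-2, 1-3 and 1-4 pairs as a set of sorted tuples."""
    excl = set()
    for i in range(n_atoms):
        for j in adj[i]:
            excl.add((min(i, j), max(i, j)))
            for k in adj[j]:
                if k != i:
                    excl.add((min(i, k), max(i, k)))
                    for l in adj[k]:
                        if l not in (i, j):
                            excl.add((min(i, l), max(i, l)))
    return excl


def assign_charges(conf: Conformation) -> np.ndarray:
    """Coarse partial charges: formal charges of titratable groups only."""
    q = np.zeros(conf.n_atoms)
    for resid in conf.residue_ids:
        sel = conf.resid == resid
        names = set(conf.atom_name[sel])
        resname = conf.resname[sel][0]
        def set_q(name, value):
            q[sel & (conf.atom_name == name)] = value
        if {"H1", "H2"} <= names:               # protonated N-terminus
            set_q("N", 1.0)
        if {"O", "OXT"} <= names and "HXT" not in names:
            set_q("O", -0.5)
            set_q("OXT", -0.5)
        if resname == "ASP" and "HD2" not in names:
            set_q("OD1", -0.5), set_q("OD2", -0.5)
        elif resname == "GLU" and "HE2" not in names:
            set_q("OE1", -0.5), set_q("OE2", -0.5)
        elif resname == "LYS" and "HZ3" in names:
            set_q("NZ", 1.0)
        elif resname == "ARG":
            set_q("NH1", 0.5), set_q("NH2", 0.5)
    return q


def compile_terms(conf: Conformation, model: EnergyModel | None = None,
                  restraints: RestraintSet | None = None,
                  term_overrides: dict | None = None) -> CompiledTerms:
    """Derive all term lists from a conformation's covalent topology.

    Equilibrium values are measured from ``conf.coords`` — the caller is
    expected to pass an ideal-geometry (as-built) conformer.
    ``term_overrides`` maps a frozenset of atom indices to an equilibrium
    value (Å for bonds, degrees for angles/torsions), used for bonds that
    do not yet have ideal geometry in ``conf`` (cycle-closure terms).
    """
    model = model or EnergyModel()
    overrides = term_overrides or {}
    x = conf.coords
    n = conf.n_atoms
    bonds = np.asarray(conf.bonds, int)
    if len(bonds) == 0:
        raise CyclopepError("conformation has no covalent topology")
    adj = _neighbour_lists(n, bonds)

    def override_or(key_atoms, measured, convert=float):
        key = frozenset(int(a) for a in key_atoms)
        return convert(overrides[key]) if key in overrides else measured

    bond_r0 = []
    for i, j in bonds:
        d = float(np.linalg.norm(x[i] - x[j]))
        bond_r0.append(override_or((i, j), d))

    angle_list, angle_t0 = [], []
    for a, j, b in _angles_from_bonds(adj):
        key = frozenset((a, j, b))
        if key in overrides:
            if overrides[key] is None:
                continue
            angle_list.append((a, j, b))
            angle_t0.append(np.deg2rad(overrides[key]))
            continue
        u = x[a] - x[j]
        v = x[b] - x[j]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        angle_list.append((a, j, b))
        angle_t0.append(float(np.arccos(np.clip(cos, -1, 1))))

    # periodic torsions: one per amide (and closure) bond keeping omega trans
    torsion_list, torsion_p0 = [], []
    name = conf.atom_name
    for i, j in bonds:
        ni, nj = name[i], name[j]
        if {ni, nj} == {"C", "N"} and conf.resid[i] != conf.resid[j]:
            c, nn = (i, j) if ni == "C" else (j, i)
            ca_c = [k for k in adj[c] if name[k] in ("CA", "CH3")]
            ca_n = [k for k in adj[nn] if name[k] in ("CA", "C")
                    and conf.resid[k] == conf.resid[nn] and k != c]
            if ca_c and ca_n:
                torsion_list.append((ca_c[0], c, nn, ca_n[0]))
                torsion_p0.append(np.pi)
        if {ni, nj} == {"SG", "SG"}:
            cb_i = [k for k in adj[i] if name[k] == "CB"]
            cb_j = [k for k in adj[j] if name[k] == "CB"]
            if cb_i and cb_j:
                torsion_list.append((cb_i[0], i, j, cb_j[0]))
                torsion_p0.append(np.deg2rad(90.0))

    # impropers: every >=3-coordinated centre, neighbours in index order
    improper_list, improper_p0 = [], []
    from .geometry import dihedral
    for c in range(n):
        if len(adj[c]) >= 3:
            n1, n2, n3 = sorted(adj[c])[:3]
            key = frozenset((c, n1, n2, n3))
            if key in overrides:
                if overrides[key] is None:
                    continue
                measured = np.deg2rad(overrides[key])
            else:
                measured = np.deg2rad(dihedral(x[c], x[n1], x[n2], x[n3]))
            improper_list.append((c, n1, n2, n3))
            improper_p0.append(measured)

    excl = _exclusions(adj, n)
    radii = np.array([_VDW_RADIUS.get(str(e), 1.7) for e in conf.element])
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if (i, j) not in excl]
    nb_pairs = np.array(pairs, int).reshape(-1, 2)
    nb_rmin = model.contact_scale * (radii[nb_pairs[:, 0]] + radii[nb_pairs[:, 1]])

    restraint_pairs = []
    if restraints is not None:
        for r in restraints:
            ii = r.sel_i.atom_indices(conf, heavy_only=r.sel_i.name is None)
            jj = np.concatenate([
                s.atom_indices(conf, heavy_only=s.name is None) for s in r.sel_j])
            if len(ii) == 0 or len(jj) == 0:
                raise CyclopepError(f"restraint matches no atoms: {r}")
            lo, hi = r.bounds
            restraint_pairs.append((ii, jj, lo, hi))

    return CompiledTerms(
        n_atoms=n,
        bond_idx=bonds, bond_r0=np.array(bond_r0),
        angle_idx=np.array(angle_list, int).reshape(-1, 3),
        angle_t0=np.array(angle_t0),
        torsion_idx=np.array(torsion_list, int).reshape(-1, 4),
        torsion_p0=np.array(torsion_p0),
        improper_idx=np.array(improper_list, int).reshape(-1, 4),
        improper_p0=np.array(improper_p0),
        nb_pairs=nb_pairs, nb_rmin=nb_rmin,
        charges=assign_charges(conf),
        restraint_pairs=restraint_pairs,
    )


def _torsion_value_grad(x, idx):
    """Dihedral angles and analytic gradients for an (m, 4) index array.

    Returns ``(phi (m,), dphi (m, 4, 3))`` with phi in radians.
    """
    p0, p1, p2, p3 = (x[idx[:, k]] for k in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    n1sq = np.sum(n1 * n1, axis=1)
    n2sq = np.sum(n2 * n2, axis=1)
    cosphi = np.sum(n1 * n2, axis=1)
    sinphi = np.sum(np.cross(n1, n2) * b2, axis=1) / np.maximum(b2n, 1e-12)
    phi = np.arctan2(sinphi, cosphi)

    dphi = np.zeros((len(idx), 4, 3))
    g0 = -(b2n / np.maximum(n1sq, 1e-12))[:, None] * n1
    g3 = (b2n / np.maximum(n2sq, 1e-12))[:, None] * n2
    s12 = (np.sum(b1 * b2, axis=1) / np.maximum(b2n ** 2, 1e-12))[:, None]
    s32 = (np.sum(b3 * b2, axis=1) / np.maximum(b2n ** 2, 1e-12))[:, None]
    dphi[:, 0] = g0
    dphi[:, 1] = -(1.0 + s12) * g0 + s32 * g3
    dphi[:, 2] = s12 * g0 - (1.0 + s32) * g3
    dphi[:, 3] = g3
    return phi, dphi


def _periodic_term(x, idx, p0, k, grad):
    if len(idx) == 0:
        return 0.0
    phi, dphi = _torsion_value_grad(x, idx)
    delta = phi - p0
    e = k * np.sum(1.0 - np.cos(delta))
    coef = k * np.sin(delta)
    for slot in range(4):
        np.add.at(grad, idx[:, slot], coef[:, None] * dphi[:, slot])
    return float(e)


def _restraint_energy(x, terms: CompiledTerms, model: EnergyModel, grad,
                      scale: float):
    e = 0.0
    k = model.k_restraint * scale
    s = model.restraint_switch
    for ii, jj, lo, hi in terms.restraint_pairs:
        diff = x[ii][:, None, :] - x[jj][None, :, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        if d.size == 1:
            deff = float(d[0, 0])
        else:
            deff = float(np.sum(d ** -6.0) ** (-1.0 / 6.0))
        if lo <= deff <= hi:
            continue
        v = (lo - deff) if deff < lo else (deff - hi)
        sign = -1.0 if deff < lo else 1.0
        if v <= s:
            e += k * v * v
            dE_ddeff = 2.0 * k * v * sign
        else:
            e += k * (s * s + 2.0 * s * (v - s))
            dE_ddeff = 2.0 * k * s * sign
        # d(deff)/d(d_p) = (deff / d_p)^7 for the r^-6 soft minimum
        if d.size == 1:
            w = np.ones_like(d)
        else:
            w = (deff / d) ** 7.0
        unit = diff / d[..., None]
        contrib = dE_ddeff * w[..., None] * unit
        np.add.at(grad, ii, contrib.sum(axis=1))
        np.add.at(grad, jj, -contrib.sum(axis=0))
    return float(e)


def evaluate(coords: np.ndarray, terms: CompiledTerms,
             model: EnergyModel | None = None, restraint_scale: float = 1.0,
             breakdown: bool = False):
    """Total energy and per-atom gradient at ``coords``.

    Returns ``(energy, gradient)`` or, with ``breakdown=True``,
    ``(energy, gradient, dict_of_terms)``.
    """
    model = model or EnergyModel()
    x = np.asarray(coords, float)
    if not np.all(np.isfinite(x)):
        raise CyclopepError("non-finite coordinates")
    grad = np.zeros_like(x)
    parts: dict[str, float] = {}

    # bonds
    bi = terms.bond_idx
    d = x[bi[:, 0]] - x[bi[:, 1]]
    r = np.linalg.norm(d, axis=1)
    dev = r - terms.bond_r0
    parts["bond"] = float(model.k_bond * np.sum(dev ** 2))
    coef = (2.0 * model.k_bond * dev / np.maximum(r, 1e-12))[:, None] * d
    np.add.at(grad, bi[:, 0], coef)
    np.add.at(grad, bi[:, 1], -coef)

    # angles
    ai = terms.angle_idx
    if len(ai):
        u = x[ai[:, 0]] - x[ai[:, 1]]
        v = x[ai[:, 2]] - x[ai[:, 1]]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        cos = np.clip(np.sum(uh * vh, axis=1), -1.0, 1.0)
        theta = np.arccos(cos)
        sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
        dev = theta - terms.angle_t0
        parts["angle"] = float(model.k_angle * np.sum(dev ** 2))
        coef = 2.0 * model.k_angle * dev / sin
        gi = (coef / nu)[:, None] * (cos[:, None] * uh - vh)
        gk = (coef / nv)[:, None] * (cos[:, None] * vh - uh)
        np.add.at(grad, ai[:, 0], gi)
        np.add.at(grad, ai[:, 2], gk)
        np.add.at(grad, ai[:, 1], -(gi + gk))
    else:
        parts["angle"] = 0.0

    parts["torsion"] = _periodic_term(x, terms.torsion_idx, terms.torsion_p0,
                                      model.k_torsion, grad)
    parts["improper"] = _periodic_term(x, terms.improper_idx, terms.improper_p0,
                                       model.k_improper, grad)

    # purely repulsive truncated+shifted LJ
    pi_, pj_ = terms.nb_pairs[:, 0], terms.nb_pairs[:, 1]
    dvec = x[pi_] - x[pj_]
    r = np.linalg.norm(dvec, axis=1)
    inside = r < terms.nb_rmin
    parts["repulsion"] = 0.0
    if np.any(inside):
        rr = r[inside]
        rm = terms.nb_rmin[inside]
        s6 = (rm / rr) ** 6
        parts["repulsion"] = float(model.eps_repulsive * np.sum(s6 * s6 - 2.0 * s6 + 1.0))
        dEdr = model.eps_repulsive * (-12.0 * (s6 * s6 - s6) / rr)
        coef = (dEdr / rr)[:, None] * dvec[inside]
        np.add.at(grad, pi_[inside], coef)
        np.add.at(grad, pj_[inside], -coef)

    # electrostatics, distance-dependent dielectric eps(r) = a*r
    parts["coulomb"] = 0.0
    if model.electrostatics:
        qq = terms.charges[pi_] * terms.charges[pj_]
        active = qq != 0.0
        if np.any(active):
            rr = r[active]
            e_pair = _COULOMB * qq[active] / (model.dielectric_scale * rr ** 2)
            parts["coulomb"] = float(np.sum(e_pair))
            dEdr = -2.0 * e_pair / rr
            coef = (dEdr / rr)[:, None] * dvec[active]
            np.add.at(grad, pi_[active], coef)
            np.add.at(grad, pj_[active], -coef)

    parts["restraint"] = _restraint_energy(x, terms, model, grad, restraint_scale)

    total = float(sum(parts.values()))
    if breakdown:
        return total, grad, parts
    return total, grad


def energy_and_gradient(conf: Conformation, model: EnergyModel | None = None,
                        restraints: RestraintSet | None = None):
    """Energy and analytic gradient of a conformation (terms compiled from
    its own topology, equilibria measured from its coordinates except for
    restraints)."""
    model = model or EnergyModel()
    terms = compile_terms(conf, model, restraints)
    return evaluate(conf.coords, terms, model)
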