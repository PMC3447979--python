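"""Rigid-body relaxation of a pentamer under distance restraints.

A desk-scale test bed for the restraint machinery: each subunit moves as a
rigid body (licensed by the observation that adjacent TM helix pairs move
with little relative deformation during gating), and a greedy, seeded
stochastic minimiser lowers the total restraint energy window by window along
a lambda schedule.  This module tests that the restraints *drive structures
where they should*; it does not simulate physics -- no thermostat, no lipids,
no thermodynamics.

A weak harmonic "membrane" term keeps TM backbone z coordinates near their
starting values to prevent degenerate sliding along the pore axis; it is
plumbing, not science, and is documented as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .restraints import DistanceRestraint, LambdaSchedule, RestraintError
from .structure import CGStructure, DomainMap


class RelaxError(ValueError):
    pass


@dataclass
class _CompiledRestraints:
    """Vectorised view of a restraint list against one structure's beads."""

    idx_i: np.ndarray
    idx_j: np.ndarray
    kind_flat: np.ndarray  # boolean mask: flat_bottom vs lower_half_harmonic
    target: np.ndarray
    width: np.ndarray
    k: np.ndarray

    def energy(self, coords: np.ndarray, lam: float = 1.0) -> float:
        d = np.linalg.norm(coords[self.idx_i] - coords[self.idx_j], axis=1)
        dev = np.abs(d - self.target)
        excess = np.where(
            self.kind_flat,
            np.maximum(dev - self.width, 0.0),  # flat bottom
            np.maximum(self.target - d, 0.0),  # lower bound
        )
        return float(lam * np.sum(0.5 * self.k * excess**2))


def compile_restraints(
    s: CGStructure, restraints: Sequence[DistanceRestraint]
) -> _CompiledRestraints:
    """Resolve restraints to bead index pairs (backbone bead of the residue)."""
    df = s.beads
    lookup = {
        (int(r.subunit), int(r.residue)): i
        for i, r in df[df["role"] == "BB"].iterrows()
    }
    idx_i, idx_j, flat, target, width, k = [], [], [], [], [], []
    for r in restraints:
        i, j = r.subunit_pair
        try:
            idx_i.append(lookup[(i, r.residue)])
            idx_j.append(lookup[(j, r.residue)])
        except KeyError:
            raise RelaxError(
                f"restrained residue {r.residue} missing a backbone bead in "
                f"subunit pair {r.subunit_pair}"
            ) from None
        flat.append(r.kind == "flat_bottom")
        target.append(r.target)
        width.append(r.width)
        k.append(r.k)
    return _CompiledRestraints(
        idx_i=np.array(idx_i, dtype=int),
        idx_j=np.array(idx_j, dtype=int),
        kind_flat=np.array(flat, dtype=bool),
        target=np.array(target, dtype=float),
        width=np.array(width, dtype=float),
        k=np.array(k, dtype=float),
    )


def total_energy(
    s: CGStructure, restraints: Sequence[DistanceRestraint], lam: float = 1.0
) -> float:
    """Sum of all distance-restraint energies at the current coordinates.

    Linear lambda coupling: the energy at coupling ``lam`` is exactly
    ``lam`` times the fully coupled energy at the same coordinates.
    """
    if not restraints:
        return 0.0
    compiled = compile_restraints(s, restraints)
    e = compiled.energy(s.coords, lam=lam)
    if not np.isfinite(e):
        raise RelaxError("non-finite restraint energy")
    return e


def relax(
    s: CGStructure,
    restraints: Sequence[DistanceRestraint],
    schedule: LambdaSchedule,
    max_iter: int = 3000,
    seed: int = 0,
    step_translation: float = 0.05,
    step_rotation_deg: float = 2.0,
    membrane_k: float = 1.0,
    domain_map: DomainMap | None = None,
) -> tuple[CGStructure, pd.DataFrame]:
    """Greedy rigid-body minimisation of the restraint energy along a lambda ramp.

    Per window, random single-subunit rigid moves (translation + small
    rotation about the subunit centroid) are proposed and accepted only when
    they strictly lower the objective ``lam * E_restraint + E_membrane``, so
    the energy trace is non-increasing within each window and a structure that
    already satisfies its restraints is returned unmoved.  Deterministic under
    ``seed``.

    Returns the relaxed structure and a trace frame with columns
    ``window, lam, iteration, e_restraint, energy``.
    """
    if max_iter < 0:
        raise RelaxError("max_iter must be >= 0")
    rng = np.random.default_rng(seed)
    dm = domain_map or DomainMap.default()
    coords = s.coords.copy()
    compiled = compile_restraints(s, restraints) if restraints else None

    df = s.beads
    subunit_rows = {su: np.flatnonzero(df["subunit"].to_numpy() == su) for su in s.subunits}

    tm_mask = np.zeros(len(df), dtype=bool)
    for name in ("TM1", "TM2"):
        a, b = dm.interval(name)
        tm_mask |= (
            (df["residue"].to_numpy() >= a)
            & (df["residue"].to_numpy() <= b)
            & (df["role"].to_numpy() == "BB")
        )
    z0 = coords[tm_mask, 2].copy()

    def objective(c: np.ndarray, lam: float) -> tuple[float, float]:
        e_rest = compiled.energy(c, lam=1.0) if compiled is not None else 0.0
        e_mem = 0.5 * membrane_k * float(np.sum((c[tm_mask, 2] - z0) ** 2))
        total = lam * e_rest + e_mem
        if not np.isfinite(total):
            raise RelaxError("non-finite energy during relaxation")
        return total, e_rest

    n_windows = len(schedule)
    iters_per_window = max(1, max_iter // n_windows) if max_iter else 0
    trace = []
    for w, lam in enumerate(schedule):
        step_t = step_translation
        step_r = np.deg2rad(step_rotation_deg)
        e, e_rest = objective(coords, lam)
        trace.append(
            {"window": w, "lam": lam, "iteration": 0, "e_restraint": e_rest, "energy": e}
        )
        rejected_streak = 0
        for it in range(1, iters_per_window + 1):
            su = int(rng.integers(len(subunit_rows)))
            rows = subunit_rows[su]
            proposal = coords.copy()
            shift = rng.normal(0.0, step_t, 3)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot = Rotation.from_rotvec(axis * rng.normal(0.0, step_r))
            centroid = proposal[rows].mean(axis=0)
            proposal[rows] = rot.apply(proposal[rows] - centroid) + centroid + shift
            e_new, e_rest_new = objective(proposal, lam)
            if e_new < e:
                coords = proposal
                e, e_rest = e_new, e_rest_new
                rejected_streak = 0
            else:
                rejected_streak += 1
                if rejected_streak >= 50:
                    step_t = max(step_t * 0.7, 1e-4)
                    step_r = max(step_r * 0.7, 1e-5)
                    rejected_streak = 0
            trace.append(
                {
                    "window": w,
                    "lam": lam,
                    "iteration": it,
                    "e_restraint": e_rest,
                    "energy": e,
                }
            )
    return s.with_coords(coords), pd.DataFrame(trace)
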