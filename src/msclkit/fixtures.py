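"""Parametric synthetic pentamers with known ground truth.

The generator emulates the architecture of a pentameric mechanosensitive
channel: five identical subunits at 72 degree intervals about the z axis, each
with two transmembrane helices (TM1 lining the pore, TM2 behind it), a
periplasmic loop connecting them, and cytoplasmic N- and C-terminal segments.
Helices are straight bead lines (the helical wrap is deliberately omitted:
at one backbone bead per residue none of the implemented metrics depends on
it).  Every geometric ground truth -- gate ring radius, helix tilt, kink angle
and position -- is a generator parameter, which makes all structural metrics
and the toy relaxer testable without any external structure.

Geometry convention: helices tilt in the radial-z plane with the tilt pivot at
the helix's gate-centre (TM1) or mid-point (TM2) residue.  The per-residue ring
radii are then linear in the residue index and symmetric about the pivot, so
the mean apothem over the gate residues 20-28 equals cos(36 deg) times
``gate_circumradius`` exactly, for any tilt.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .structure import CGStructure, DomainMap, N_SUBUNITS

COS36 = np.cos(np.pi / 5)

_GATE_CENTER = 24  # central residue of the hydrophobic gate 20-28


@dataclass(frozen=True)
class FixtureParams:
    """Parametric description of a synthetic pentamer.

    All lengths in nm, angles in degrees.  Identical parameters and seed give
    bit-identical structures.
    """

    n_residues_tm1: int = 31
    n_residues_tm2: int = 33
    gate_circumradius: float = 1.0513  # closed convention: apothem 8.5 A
    tilt_tm1: float = 42.0
    tilt_tm2: float = 28.0
    kink_angle: float = 0.0
    kink_residue: int | None = None
    loop_radial_extension: float = 0.5
    tm2_radial_offset: float = 1.0
    rise_per_residue: float = 0.36
    noise_sigma: float = 0.0
    seed: int = 0
    with_sidechains: bool = False
    box: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.gate_circumradius <= 0:
            raise ValueError("gate_circumradius must be > 0")
        for name in ("tilt_tm1", "tilt_tm2"):
            t = getattr(self, name)
            if not 0 <= t < 90:
                raise ValueError(f"{name} must be in [0, 90), got {t}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.rise_per_residue <= 0:
            raise ValueError("rise_per_residue must be > 0")

    def domain_map(self) -> DomainMap:
        """Domain intervals consistent with this fixture's residue layout."""
        tm1_first = 15
        tm1_last = tm1_first + self.n_residues_tm1 - 1
        loop_first, loop_last = tm1_last + 1, tm1_last + 29
        tm2_first = loop_last + 1
        tm2_last = tm2_first + self.n_residues_tm2 - 1
        return DomainMap(
            {
                "N_terminal": (1, tm1_first - 1),
                "TM1": (tm1_first, tm1_last),
                "periplasmic_loop": (loop_first, loop_last),
                "TM2": (tm2_first, tm2_last),
                "C_terminal": (tm2_last + 1, tm2_last + 29),
                "hydrophobic_gate": (20, 28),
            }
        )

    @classmethod
    def closed(cls, **kw) -> "FixtureParams":
        """Closed-state convention: gate apothem 8.5 A, TM tilts 42/28 deg."""
        return cls(**kw)

    @classmethod
    def open_state(cls, **kw) -> "FixtureParams":
        """Open-state convention: gate apothem 15 A, larger TM tilts."""
        defaults = dict(gate_circumradius=1.5 / COS36, tilt_tm1=62.0, tilt_tm2=43.0)
        defaults.update(kw)
        return cls(**defaults)


def _subunit_coords(p: FixtureParams, dm: DomainMap) -> tuple[np.ndarray, np.ndarray]:
    """Build one subunit at azimuth 0 (radial direction +x); returns (residues, coords)."""
    rise = p.rise_per_residue
    t1 = np.deg2rad(p.tilt_tm1)
    t2 = np.deg2rad(p.tilt_tm2)
    kink = np.deg2rad(p.kink_angle)

    tm1_first, tm1_last = dm.interval("TM1")
    loop_first, loop_last = dm.interval("periplasmic_loop")
    tm2_first, tm2_last = dm.interval("TM2")
    nt_first, nt_last = dm.interval("N_terminal")
    ct_first, ct_last = dm.interval("C_terminal")

    if p.kink_residue is not None and not tm1_first <= p.kink_residue <= tm1_last:
        raise ValueError(
            f"kink_residue {p.kink_residue} outside TM1 [{tm1_first}, {tm1_last}]"
        )

    pos: dict[int, np.ndarray] = {}

    # TM1: straight line through the gate anchor, tilted radially; optional kink
    d1 = np.array([np.sin(t1), 0.0, np.cos(t1)])
    anchor = np.array([p.gate_circumradius, 0.0, 0.0])
    for i in range(tm1_first, tm1_last + 1):
        pos[i] = anchor + (i - _GATE_CENTER) * rise * d1
    if p.kink_residue is not None and p.kink_angle != 0.0:
        d1k = np.array([np.sin(t1 + kink), 0.0, np.cos(t1 + kink)])
        pivot = pos[p.kink_residue]
        for i in range(p.kink_residue + 1, tm1_last + 1):
            pos[i] = pivot + (i - p.kink_residue) * rise * d1k

    # TM2: antiparallel, outer ring, top aligned with the top of TM1
    d2 = np.array([np.sin(t2), 0.0, -np.cos(t2)])
    z_top = pos[tm1_last][2]
    mid = (tm2_first + tm2_last) / 2.0
    r_tm2 = p.gate_circumradius + p.tm2_radial_offset
    anchor2 = np.array([r_tm2, 0.0, z_top + (mid - tm2_first) * rise * np.cos(t2)])
    for i in range(tm2_first, tm2_last + 1):
        pos[i] = anchor2 + (i - mid) * rise * d2

    # periplasmic loop: arc between the helix tops, bulging radially outward
    a, b = pos[tm1_last], pos[tm2_first]
    n_loop = loop_last - loop_first + 1
    for j, i in enumerate(range(loop_first, loop_last + 1), start=1):
        t = j / (n_loop + 1)
        bulge = np.sin(np.pi * t)
        pos[i] = a + t * (b - a) + np.array(
            [p.loop_radial_extension * bulge, 0.0, 0.4 * bulge]
        )

    # N-terminal: amphipathic segment along the membrane inner surface
    base = pos[tm1_first]
    for i in range(nt_first, nt_last + 1):
        pos[i] = base + (tm1_first - i) * rise * np.array([0.0, -1.0, 0.0])

    # C-terminal: bundle descending near the axis
    start = pos[tm2_last]
    end = np.array([0.5, 0.0, start[2] - 4.0])
    n_ct = ct_last - ct_first + 1
    for j, i in enumerate(range(ct_first, ct_last + 1), start=1):
        pos[i] = start + (j / n_ct) * (end - start)

    residues = np.array(sorted(pos))
    coords = np.stack([pos[i] for i in residues])
    return residues, coords


def generate_pentamer(p: FixtureParams) -> CGStructure:
    """Generate a C5 pentamer from ``p``; deterministic under ``p.seed``.

    Before noise, the backbone beads of the gate residues 20-28 ring the pore
    such that the mean gate apothem equals ``cos(36 deg) * gate_circumradius``.
    """
    dm = p.domain_map()
    residues, base = _subunit_coords(p, dm)

    rows_sub, rows_res, rows_role, coords = [], [], [], []
    for su in range(N_SUBUNITS):
        ang = np.deg2rad(72.0 * su)
        rot = np.array(
            [
                [np.cos(ang), -np.sin(ang), 0.0],
                [np.sin(ang), np.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        xyz = base @ rot.T
        coords.append(xyz)
        rows_sub.extend([su] * len(residues))
        rows_res.extend(residues.tolist())
        rows_role.extend(["BB"] * len(residues))
        if p.with_sidechains:
            radial = xyz[:, :2]
            norms = np.linalg.norm(radial, axis=1, keepdims=True)
            norms[norms < 1e-9] = 1.0
            sc = xyz + 0.25 * np.hstack([radial / norms, np.zeros((len(xyz), 1))])
            coords.append(sc)
            rows_sub.extend([su] * len(residues))
            rows_res.extend(residues.tolist())
            rows_role.extend(["SC1"] * len(residues))

    xyz = np.vstack(coords)
    if p.noise_sigma > 0:
        rng = np.random.default_rng(p.seed)
        xyz = xyz + rng.normal(0.0, p.noise_sigma, xyz.shape)

    import pandas as pd

    df = pd.DataFrame(
        {
            "subunit": rows_sub,
            "residue": rows_res,
            "role": rows_role,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    ).sort_values(["subunit", "residue", "role"], kind="stable")
    return CGStructure(df, box=p.box, label=f"fixture(seed={p.seed})").validate_pentamer()


def closed_open_pair(
    closed: FixtureParams, open: FixtureParams
) -> tuple[CGStructure, CGStructure]:
    """Generate a closed/open pair with matched bead identity."""
    if (closed.n_residues_tm1, closed.n_residues_tm2) != (
        open.n_residues_tm1,
        open.n_residues_tm2,
    ):
        raise ValueError("closed and open fixtures must have matching residue counts")
    if closed.with_sidechains != open.with_sidechains:
        raise ValueError("closed and open fixtures must agree on side chains")
    return generate_pentamer(closed), generate_pentamer(open)


def kinked(p: FixtureParams, kink_angle: float, kink_residue: int = 40) -> FixtureParams:
    """Convenience: copy of ``p`` with a kink planted in TM1."""
    return replace(p, kink_angle=kink_angle, kink_residue=kink_residue)
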