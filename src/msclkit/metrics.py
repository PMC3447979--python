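"""Structural observables for CG pentamers.

Implements the analysis suite used to characterise gating of a pentameric
channel: the inscribed-pentagon pore radius over the hydrophobic gate, radial
position profiles, principal-axis helix tilt, whole-protein / per-domain /
per-segment RMSD, kink detection in TM1, and a C5 symmetry-deviation measure.

All inputs and outputs are in nm and degrees; conversion to Angstrom happens
only at the reporting boundary (CLI / report helpers).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .structure import CGStructure, DomainMap, StructureError

COS36 = np.cos(np.pi / 5)


class MetricError(ValueError):
    """Invalid input to a structural metric."""


# ---------------------------------------------------------------------------
# Pentagon geometry
# ---------------------------------------------------------------------------


def _project(points: np.ndarray, plane: str) -> np.ndarray:
    """Project 5 points to 2D, either onto the xy plane or a least-squares plane."""
    pts = np.asarray(points, dtype=float)
    if plane == "xy":
        return pts[:, :2]
    if plane == "fit":
        c = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - c)
        # rows of vt: in-plane basis (largest variance) then the normal
        return (pts - c) @ vt[:2].T
    raise MetricError(f"unknown plane {plane!r}; use 'xy' or 'fit'")


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        u, v = b - a, c - a
        return np.sign(u[0] * v[1] - u[1] * v[0])

    return (
        orient(p1, p2, p3) * orient(p1, p2, p4) < 0
        and orient(p3, p4, p1) * orient(p3, p4, p2) < 0
    )


def pentagon_apothem(points: Sequence[Sequence[float]], plane: str = "xy") -> float:
    """Inscribed-circle radius of the (possibly irregular) pentagon of 5 beads.

    The five points, ordered by subunit ring index, are projected to 2D and the
    minimum distance from their centroid to the five edge *segments* is
    returned.  For a regular pentagon of circumradius R this equals
    ``R * cos(36 deg)`` exactly.  A self-intersecting projection is flagged
    with a warning but the value is still returned.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape != (5, 3):
        raise MetricError(f"expected 5 3-vectors, got shape {pts.shape}")
    for i in range(5):
        for j in range(i + 1, 5):
            if np.linalg.norm(pts[i] - pts[j]) < 1e-9:
                raise MetricError(f"coincident points {i} and {j}")
    p2 = _project(pts, plane)
    centroid = p2.mean(axis=0)
    # simplicity check over non-adjacent edge pairs
    edges = [(p2[i], p2[(i + 1) % 5]) for i in range(5)]
    for i in range(5):
        for j in range(i + 2, 5):
            if i == 0 and j == 4:
                continue  # adjacent around the ring
            if _segments_cross(*edges[i], *edges[j]):
                warnings.warn("self-intersecting pentagon projection", stacklevel=2)
                break
    return min(_point_segment_distance(centroid, a, b) for a, b in edges)


@dataclass
class PoreProfile:
    """Per-residue pore apothem (nm) and their mean over the gate residues."""

    per_residue: dict[int, float]
    gate_radius: float
    axis: str = "z"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue": list(self.per_residue), "apothem_nm": list(self.per_residue.values())}
        )


def pore_radius(
    s: CGStructure,
    residues: Iterable[int] | None = None,
    plane: str = "xy",
    domain_map: DomainMap | None = None,
) -> PoreProfile:
    """Pore radius at the hydrophobic gate.

    For each residue the apothem of the pentagon formed by that residue's five
    backbone beads is computed; ``gate_radius`` is the unweighted mean over the
    requested residues (default: the hydrophobic gate, residues 20-28).
    """
    dm = domain_map or DomainMap.default()
    residues = list(residues) if residues is not None else list(dm.residues("hydrophobic_gate"))
    per = {}
    for r in residues:
        pts = s.positions(r, role="BB")
        per[r] = pentagon_apothem(pts, plane=plane)
    return PoreProfile(per_residue=per, gate_radius=float(np.mean(list(per.values()))), axis=plane)


def radial_profile(s: CGStructure, domain_map: DomainMap | None = None) -> pd.DataFrame:
    """Distance of every backbone bead from the pore axis.

    The axis is the z line through the centroid of all TM backbone beads, so
    the profile is invariant under global translation.  Returns a tidy frame
    with columns ``residue, subunit, r_nm``.
    """
    dm = domain_map or DomainMap.default()
    bb = s.backbone().beads
    tm = pd.concat(
        [
            bb[(bb["residue"] >= a) & (bb["residue"] <= b)]
            for a, b in (dm.interval("TM1"), dm.interval("TM2"))
        ]
    )
    if tm.empty:
        raise MetricError("no TM backbone beads to define the pore axis")
    cx, cy = tm["x"].mean(), tm["y"].mean()
    out = bb[["residue", "subunit"]].copy()
    out["r_nm"] = np.hypot(bb["x"] - cx, bb["y"] - cy)
    return out.sort_values(["residue", "subunit"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Helix axes and tilt
# ---------------------------------------------------------------------------


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal axis, oriented along increasing bead order."""
    c = coords - coords.mean(axis=0)
    if np.allclose(c, 0.0):
        raise MetricError("degenerate (all-coincident) coordinates")
    _, _, vt = np.linalg.svd(c)
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis


def helix_tilt(
    s: CGStructure,
    helix: str | tuple[int, int] = "TM1",
    subunit: int | None = None,
    domain_map: DomainMap | None = None,
) -> float:
    """Angle between a helix's principal axis and the membrane normal (+z).

    Folded to [0, 90] degrees.  With ``subunit=None`` the mean over the five
    subunits is returned.
    """
    if subunit is None:
        return float(
            np.mean([helix_tilt(s, helix, su, domain_map) for su in s.subunits])
        )
    sel = s.select(domain=helix, subunit=subunit, role="BB", domain_map=domain_map)
    coords = sel.beads.sort_values("residue")[["x", "y", "z"]].to_numpy()
    if len(coords) < 4:
        raise MetricError(f"need >= 4 backbone beads for a helix axis, got {len(coords)}")
    axis = _principal_axis(coords)
    cosang = abs(float(axis[2]) / np.linalg.norm(axis))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------


def _matched_coords(
    a: CGStructure, b: CGStructure
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Coordinates of the beads shared by a and b, in a canonical order."""
    key = ["subunit", "residue", "role"]
    da = a.beads.set_index(key)[["x", "y", "z"]]
    db = b.beads.set_index(key)[["x", "y", "z"]]
    if not da.index.equals(db.index):
        if set(da.index) != set(db.index):
            raise MetricError("mismatched bead sets between the two structures")
        db = db.loc[da.index]
    ids = da.index.to_frame(index=False)
    return da.to_numpy(), db.to_numpy(), ids


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[Rotation, np.ndarray, np.ndarray]:
    """Least-squares superposition (proper rotation) of ``mobile`` onto ``target``.

    Returns ``(R, c_mobile, c_target)`` so that the fitted coordinates are
    ``R.apply(x - c_mobile) + c_target``.
    """
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    return rot, cm, ct


def _rmsd(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((x - y) ** 2, axis=1))))


def domain_rmsd(
    a: CGStructure,
    b: CGStructure,
    domain: str | tuple[int, int] | None = None,
    align: str = "whole",
    domain_map: DomainMap | None = None,
) -> float:
    """RMSD of a domain after optimal superposition.

    ``align='whole'`` superposes on every shared bead of the two structures
    and evaluates the RMSD on the domain; ``align='domain'`` superposes on the
    domain beads themselves.
    """
    if align not in ("whole", "domain"):
        raise MetricError(f"align must be 'whole' or 'domain', got {align!r}")
    dom_a = a.select(domain=domain, domain_map=domain_map) if domain is not None else a
    dom_b = b.select(domain=domain, domain_map=domain_map) if domain is not None else b
    if align == "whole":
        ref_t, ref_m, _ = _matched_coords(a, b)
    else:
        ref_t, ref_m, _ = _matched_coords(dom_a, dom_b)
    dom_t, dom_m, _ = _matched_coords(dom_a, dom_b)
    rot, cm, ct = superpose(ref_m, ref_t)
    fitted = rot.apply(dom_m - cm) + ct
    return _rmsd(dom_t, fitted)


@dataclass
class RMSDProfile:
    """Tidy per-(subunit, residue) RMSD values with the alignment mode used."""

    values: pd.DataFrame  # columns: subunit, residue, rmsd_nm
    mode: str

    def per_residue(self) -> pd.Series:
        return self.values.groupby("residue")["rmsd_nm"].mean()


def segment_rmsd(
    a: CGStructure,
    b: CGStructure,
    window: int = 5,
    stride: int | None = None,
    domain: str | tuple[int, int] | None = None,
    domain_map: DomainMap | None = None,
) -> RMSDProfile:
    """Per-segment RMSD separating internal deformation from rigid-body motion.

    For each subunit, consecutive ``window``-residue backbone segments (default
    non-overlapping, anchored at the first residue of the selection) of ``b``
    are individually superposed onto the equivalent segments of ``a``; the
    segment RMSD is recorded at the segment's central residue.  A domain moved
    as a rigid body scores ~0 everywhere, while internal deformation (e.g. a
    helix kink) is elevated only in segments spanning it.
    """
    if window < 3:
        raise MetricError("window must be >= 3")
    stride = stride or window
    sa = a.select(domain=domain, role="BB", domain_map=domain_map)
    sb = b.select(domain=domain, role="BB", domain_map=domain_map)
    rows = []
    for su in sa.subunits:
        res = sa.residues(subunit=su)
        if window > len(res):
            raise MetricError(f"window {window} longer than selection ({len(res)} residues)")
        pa = sa.select(subunit=su).beads.sort_values("residue")[["x", "y", "z"]].to_numpy()
        pb = sb.select(subunit=su).beads.sort_values("residue")[["x", "y", "z"]].to_numpy()
        if len(pa) != len(res) or len(pb) != len(res):
            raise MetricError("expected exactly one backbone bead per residue")
        for start in range(0, len(res) - window + 1, stride):
            seg = slice(start, start + window)
            rot, cm, ct = superpose(pb[seg], pa[seg])
            fitted = rot.apply(pb[seg] - cm) + ct
            rows.append(
                {
                    "subunit": su,
                    "residue": res[start + window // 2],
                    "rmsd_nm": _rmsd(pa[seg], fitted),
                }
            )
    return RMSDProfile(values=pd.DataFrame(rows), mode=f"per_segment(window={window})")


# ---------------------------------------------------------------------------
# Kink detection
# ---------------------------------------------------------------------------


@dataclass
class SubunitKink:
    subunit: int
    kink_present: bool
    kink_residue: int | None
    kink_angle: float  # degrees
    max_displacement: float  # nm, vs reference after sub-kink alignment


@dataclass
class KinkReport:
    subunits: list[SubunitKink]
    fraction: float  # percent of subunits kinked
    histogram: Counter = field(default_factory=Counter)  # kink_residue -> count

    def __iter__(self):
        return iter(self.subunits)


def _line_ssr(points: np.ndarray, axis: np.ndarray) -> float:
    """Sum of squared perpendicular distances of points to their best-fit line."""
    c = points - points.mean(axis=0)
    along = c @ axis
    return float(np.sum(np.sum(c**2, axis=1) - along**2))


def _helix_coords(s: CGStructure, su: int, helix, domain_map) -> tuple[list[int], np.ndarray]:
    sel = s.select(domain=helix, subunit=su, role="BB", domain_map=domain_map)
    res = sel.residues()
    coords = sel.beads.sort_values("residue")[["x", "y", "z"]].to_numpy()
    return res, coords


def detect_kink(
    s: CGStructure,
    ref: CGStructure,
    helix: str | tuple[int, int] = "TM1",
    angle_threshold: float = 20.0,
    displacement_threshold: float = 0.15,
    domain_map: DomainMap | None = None,
) -> KinkReport:
    """Detect helix kinks per subunit against a straight-helix reference.

    The helix is split at every candidate residue (at least 4 beads on each
    side); one principal axis is fitted below and one above the split, the
    split with the lowest combined straight-line fit residual is taken as the
    kink position, and the kink angle is the angle between its two axes.  A kink is *present* when that angle reaches
    ``angle_threshold`` and, additionally, the helix genuinely deviates from
    the reference: after aligning the sub-kink part of the helix onto the
    reference, the largest per-residue displacement above the kink must exceed
    ``displacement_threshold``.  (The displacement test is what separates a
    real kink from a rigidly re-oriented straight helix, which also shows no
    deviation from the reference helix shape.)
    """
    reports = []
    hist: Counter = Counter()
    for su in s.subunits:
        res, coords = _helix_coords(s, su, helix, domain_map)
        if len(res) < 8:
            raise MetricError(f"helix interval too short to split ({len(res)} residues)")
        ref_res, ref_coords = _helix_coords(ref, su, helix, domain_map)
        if ref_res != res:
            raise MetricError("reference helix does not cover the same residues")
        # choose the split by the best two-straight-segment fit (total least
        # squares residual), then read the kink angle off the two fitted axes;
        # picking the angle-maximising split instead is biased upward by noise
        best_ssr, best_angle, best_split = np.inf, 0.0, None
        for split in range(4, len(res) - 3):
            # the vertex bead lies on both arms, so it joins both fits
            lo_pts, hi_pts = coords[:split], coords[split - 1 :]
            lo = _principal_axis(lo_pts)
            hi = _principal_axis(hi_pts)
            ssr = _line_ssr(lo_pts, lo) + _line_ssr(hi_pts, hi)
            if ssr < best_ssr:
                ang = float(np.degrees(np.arccos(np.clip(lo @ hi, -1.0, 1.0))))
                best_ssr, best_angle, best_split = ssr, ang, split
        kink_residue = res[best_split - 1]
        # displacement of the supra-kink part after aligning the sub-kink part
        rot, cm, ct = superpose(coords[:best_split], ref_coords[:best_split])
        fitted_hi = rot.apply(coords[best_split:] - cm) + ct
        disp = float(np.max(np.linalg.norm(fitted_hi - ref_coords[best_split:], axis=1)))
        present = best_angle >= angle_threshold and disp >= displacement_threshold
        reports.append(
            SubunitKink(
                subunit=su,
                kink_present=present,
                kink_residue=kink_residue if present else None,
                kink_angle=best_angle,
                max_displacement=disp,
            )
        )
        if present:
            hist[kink_residue] += 1
    frac = 100.0 * sum(r.kink_present for r in reports) / len(reports)
    return KinkReport(subunits=reports, fraction=frac, histogram=hist)


def kink_fraction(
    structures: Sequence[CGStructure],
    ref: CGStructure,
    helix: str | tuple[int, int] = "TM1",
    angle_threshold: float = 20.0,
    displacement_threshold: float = 0.15,
    domain_map: DomainMap | None = None,
) -> float:
    """Percentage of subunits kinked across an ensemble of structures."""
    if not structures:
        raise MetricError("empty structure list")
    kinked = total = 0
    for s in structures:
        rep = detect_kink(
            s,
            ref,
            helix=helix,
            angle_threshold=angle_threshold,
            displacement_threshold=displacement_threshold,
            domain_map=domain_map,
        )
        kinked += sum(r.kink_present for r in rep.subunits)
        total += len(rep.subunits)
    return 100.0 * kinked / total


# ---------------------------------------------------------------------------
# Helix-pair RMSD and symmetry
# ---------------------------------------------------------------------------


def relative_helix_rmsd(
    a: CGStructure,
    b: CGStructure,
    pairing: str = "same_subunit",
    domain_map: DomainMap | None = None,
    exclude_subunits: Sequence[int] = (),
) -> float:
    """Mean RMSD of TM helix pairs, each pair aligned on itself.

    ``same_subunit`` pairs TM1 and TM2 of one subunit, ``neighbour_subunit``
    pairs TM1 of subunit i with TM2 of subunit i+1, and ``all_TM`` aligns all
    ten helices at once.  A low neighbour-pair RMSD with a high all-TM RMSD is
    the signature of helix pairs moving as rigid units.
    """
    dm = domain_map or DomainMap.default()

    def pair_structure(s: CGStructure, su1: int, su2: int) -> CGStructure:
        p1 = s.select(domain="TM1", subunit=su1, role="BB", domain_map=dm)
        p2 = s.select(domain="TM2", subunit=su2, role="BB", domain_map=dm)
        return CGStructure(pd.concat([p1.beads, p2.beads]))

    if pairing == "all_TM":
        tm_a = CGStructure(
            pd.concat(
                [
                    a.select(domain=d, role="BB", domain_map=dm).beads
                    for d in ("TM1", "TM2")
                ]
            )
        )
        tm_b = CGStructure(
            pd.concat(
                [
                    b.select(domain=d, role="BB", domain_map=dm).beads
                    for d in ("TM1", "TM2")
                ]
            )
        )
        return domain_rmsd(tm_a, tm_b, align="domain")
    if pairing not in ("same_subunit", "neighbour_subunit"):
        raise MetricError(f"unknown pairing {pairing!r}")
    values = []
    for su in a.subunits:
        if su in exclude_subunits:
            continue
        su2 = su if pairing == "same_subunit" else (su + 1) % len(a.subunits)
        pa = pair_structure(a, su, su2)
        pb = pair_structure(b, su, su2)
        values.append(domain_rmsd(pa, pb, align="domain"))
    return float(np.mean(values))


def symmetry_deviation(s: CGStructure, per_subunit: bool = False):
    """RMSD between a pentamer and its best-fit C5-symmetrised counterpart.

    The five subunits are rotated into a common frame (by multiples of 72
    degrees about the z axis through the structure centroid), averaged bead by
    bead, and the symmetric counterpart is rebuilt and optimally superposed
    onto the input.  Exactly C5 structures score 0.
    """
    df = s.beads
    key = ["residue", "role"]
    per_su = {su: g.set_index(key)[["x", "y", "z"]] for su, g in df.groupby("subunit")}
    index = per_su[0].index
    for su, g in per_su.items():
        if not set(g.index) == set(index):
            raise MetricError("subunits do not share a residue/role set")
        per_su[su] = g.loc[index]
    centroid = df[["x", "y", "z"]].mean().to_numpy()

    def rz(deg: float) -> np.ndarray:
        a = np.deg2rad(deg)
        return np.array(
            [[np.cos(a), -np.sin(a), 0.0], [np.sin(a), np.cos(a), 0.0], [0.0, 0.0, 1.0]]
        )

    coords = {su: per_su[su].to_numpy() - centroid for su in per_su}
    avg = np.mean([coords[su] @ rz(-72.0 * su).T for su in coords], axis=0)
    sym = {su: avg @ rz(72.0 * su).T for su in coords}

    orig = np.vstack([coords[su] for su in sorted(coords)])
    symm = np.vstack([sym[su] for su in sorted(coords)])
    rot, cm, ct = superpose(symm, orig)
    fitted = rot.apply(symm - cm) + ct
    if not per_subunit:
        return _rmsd(orig, fitted)
    n = len(index)
    return {
        su: _rmsd(orig[i * n : (i + 1) * n], fitted[i * n : (i + 1) * n])
        for i, su in enumerate(sorted(coords))
    }
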