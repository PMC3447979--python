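"""Turn experimental distances and accessibility changes into CG restraints.

Two classes of experimental input are supported:

* **Inter-subunit distances** between equivalent residues of the pentamer.
  FRET measurements give an open-state target distance with an uncertainty and
  become *flat-bottom* harmonic potentials (zero inside the uncertainty band,
  harmonic outside).  EPR measurements give a lower bound and become
  *lower half-harmonic* potentials (harmonic below the bound, zero above).
  On a pentamer one measured distance expands into 10 pairwise restraints:
  5 between adjacent subunits at the measured distance and 5 between
  second-neighbour subunits at phi = (1 + sqrt 5)/2 times it, the
  second-neighbour/adjacent distance ratio of a regular pentagon.

* **Accessibility changes** (the combined lipid/water parameter dPi) for
  residues whose hydrophobic environment changes upon gating.  Each
  significant residue yields one solvent patch per subunit: a new side-chain
  particle type whose interaction strength with water is scaled by a
  configurable, dPi-dependent factor while all other interactions are left
  untouched.

Restraints are introduced gradually via a lambda schedule (linear coupling of
force constants and epsilon shifts) and can be emitted as engine-ready
tabulated-potential files plus a topology patch fragment.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0  # second-neighbour / adjacent ratio
ADJACENT_PAIRS = ((0, 1), (1, 2), (2, 3), (3, 4), (0, 4))
SECOND_PAIRS = ((0, 2), (1, 3), (2, 4), (0, 3), (1, 4))

DEFAULT_K = 10.0  # kJ mol^-1 nm^-2
DEFAULT_EPR_BOUND = 1.5  # nm, from the >= 15 A open-state statement
DEFAULT_DR = 0.002  # nm, table grid spacing
DEFAULT_R_MAX = 6.0  # nm


class RestraintError(ValueError):
    """Invalid restraint input."""


# ---------------------------------------------------------------------------
# Data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceDatum:
    """One experimental per-residue inter-subunit distance (nm).

    FRET data carry a target and an uncertainty ``width``; EPR data are pure
    lower bounds and must have ``width == 0``.
    """

    residue: int
    d_open: float
    width: float = 0.0
    source: str = "FRET"

    def __post_init__(self) -> None:
        if self.d_open <= 0:
            raise RestraintError(f"d_open must be > 0, got {self.d_open}")
        if self.width < 0:
            raise RestraintError("width must be >= 0")
        if self.source not in ("FRET", "EPR"):
            raise RestraintError(f"source must be FRET or EPR, got {self.source!r}")
        if self.source == "EPR" and self.width != 0:
            raise RestraintError("EPR data are pure lower bounds: width must be 0")


@dataclass(frozen=True)
class DistanceRestraint:
    """One pairwise potential on the pentamer derived from a DistanceDatum."""

    residue: int
    subunit_pair: tuple[int, int]
    neighbour_order: str  # "adjacent" | "second"
    kind: str  # "flat_bottom" | "lower_half_harmonic"
    target: float  # nm (bound for half-harmonic)
    width: float  # nm
    k: float  # kJ mol^-1 nm^-2
    table_id: str
    source: str = "FRET"


@dataclass(frozen=True)
class AccessibilityDatum:
    """Per-residue combined lipid/water accessibility change (signed dPi)."""

    residue: int
    delta_pi: float
    region: str = "TM"  # "TM" | "loop"
    significant: bool = True

    def __post_init__(self) -> None:
        if self.region not in ("TM", "loop"):
            raise RestraintError(f"region must be TM or loop, got {self.region!r}")


@dataclass(frozen=True)
class SolventPatch:
    """A per-(residue, subunit) particle-type substitution scaling the
    side-chain/water interaction strength; all other interactions unchanged."""

    residue: int
    subunit: int
    new_type_name: str
    epsilon_water_scale: float


@dataclass
class TabulatedPotential:
    """(r, U, F) grid for one restraint class; F = -dU/dr."""

    r: np.ndarray  # nm, strictly increasing
    U: np.ndarray  # kJ/mol
    F: np.ndarray  # kJ/mol/nm
    table_id: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if len(r) < 2 or np.any(np.diff(r) <= 0):
            raise RestraintError("r grid must be strictly increasing")


@dataclass(frozen=True)
class LambdaSchedule:
    """Monotone coupling values in [0, 1] scaling restraint strength."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if len(v) < 2 or v[0] != 0.0 or v[-1] != 1.0 or np.any(np.diff(v) < 0):
            raise RestraintError(
                "lambda schedule must be monotone non-decreasing from 0 to 1"
            )

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class RestraintSet:
    """All restraints built from one experimental dataset, with provenance."""

    distance_restraints: list[DistanceRestraint] = field(default_factory=list)
    solvent_patches: list[SolventPatch] = field(default_factory=list)
    counts_by_source: dict[str, int] = field(default_factory=dict)

    @property
    def n_distance(self) -> int:
        return len(self.distance_restraints)

    @property
    def n_solvent(self) -> int:
        return len(self.solvent_patches)

    def totals(self) -> tuple[int, int]:
        return self.n_distance, self.n_solvent


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------


def flat_bottom(r, target: float, width: float, k: float):
    """Flat-bottom harmonic potential and its force.

    U = 0 for |r - target| <= width, else 0.5 k (|r - target| - width)^2.
    Both U and F = -dU/dr are continuous at the band edges.
    """
    if width < 0 or k < 0:
        raise RestraintError("width and k must be >= 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise RestraintError("negative distance")
    dev = np.abs(r - target)
    excess = np.maximum(dev - width, 0.0)
    U = 0.5 * k * excess**2
    F = -k * excess * np.sign(r - target)
    if U.ndim == 0:
        return float(U), float(F)
    return U, F


def lower_half_harmonic(r, bound: float, k: float):
    """Lower-bound half-harmonic: U = 0.5 k (r - bound)^2 below the bound, else 0."""
    if bound <= 0:
        raise RestraintError("bound must be > 0")
    if k < 0:
        raise RestraintError("k must be >= 0")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise RestraintError("negative distance")
    deficit = np.maximum(bound - r, 0.0)
    U = 0.5 * k * deficit**2
    F = k * deficit  # pushes outward (towards larger r)
    if U.ndim == 0:
        return float(U), float(F)
    return U, F


def restraint_energy(restraint: DistanceRestraint, r) -> tuple[float, float]:
    """(U, F) of one DistanceRestraint at distance r (nm)."""
    if restraint.kind == "flat_bottom":
        return flat_bottom(r, restraint.target, restraint.width, restraint.k)
    if restraint.kind == "lower_half_harmonic":
        return lower_half_harmonic(r, restraint.target, restraint.k)
    raise RestraintError(f"unknown restraint kind {restraint.kind!r}")


def tabulate(
    kind: str,
    params: dict,
    r_max: float = DEFAULT_R_MAX,
    dr: float = DEFAULT_DR,
    table_id: str = "",
) -> TabulatedPotential:
    """Tabulate a restraint potential on a regular grid from 0 to r_max."""
    if dr <= 0:
        raise RestraintError("dr must be > 0")
    if kind == "flat_bottom":
        flat_end = params["target"] + params["width"]
        fn = lambda r: flat_bottom(r, params["target"], params["width"], params["k"])
    elif kind == "lower_half_harmonic":
        flat_end = params["bound"]
        fn = lambda r: lower_half_harmonic(r, params["bound"], params["k"])
    else:
        raise RestraintError(f"unknown potential kind {kind!r}")
    if r_max <= flat_end:
        raise RestraintError(
            f"flat region ends at {flat_end} nm which exceeds r_max = {r_max} nm"
        )
    n = int(round(r_max / dr)) + 1
    r = np.arange(n) * dr
    U, F = fn(r)
    return TabulatedPotential(r=r, U=U, F=F, table_id=table_id)


# ---------------------------------------------------------------------------
# Expansion and building
# ---------------------------------------------------------------------------


def expand_distance(
    d: DistanceDatum, n_subunits: int = 5, k: float = DEFAULT_K
) -> list[DistanceRestraint]:
    """Expand one measured inter-subunit distance into the 10 pairwise
    restraints of the pentamer.

    5 adjacent pairs carry the measured distance; 5 second-neighbour pairs
    carry the golden-ratio multiple (with the width scaled likewise), under
    the regular-pentagon interpretation of the measurement.  The rule is
    specific to 5 subunits.
    """
    if n_subunits != 5:
        raise RestraintError("the pentamer expansion rule requires n_subunits = 5")
    kind = "flat_bottom" if d.source == "FRET" else "lower_half_harmonic"
    prefix = f"{d.source.lower()}_r{d.residue:03d}"
    out = []
    for order, pairs, scale in (
        ("adjacent", ADJACENT_PAIRS, 1.0),
        ("second", SECOND_PAIRS, GOLDEN_RATIO),
    ):
        for pair in pairs:
            out.append(
                DistanceRestraint(
                    residue=d.residue,
                    subunit_pair=pair,
                    neighbour_order=order,
                    kind=kind,
                    target=scale * d.d_open,
                    width=scale * d.width,
                    k=k,
                    table_id=f"{prefix}_{'adj' if order == 'adjacent' else 'sec'}",
                    source=d.source,
                )
            )
    return out


def build_distance_restraints(
    data: Iterable[DistanceDatum], k: float = DEFAULT_K
) -> list[DistanceRestraint]:
    """Expand a dataset; duplicate residues within one source are rejected."""
    data = list(data)
    for source in ("FRET", "EPR"):
        residues = [d.residue for d in data if d.source == source]
        if len(residues) != len(set(residues)):
            dup = sorted({r for r in residues if residues.count(r) > 1})
            raise RestraintError(f"duplicate {source} residues: {dup}")
    out: list[DistanceRestraint] = []
    for d in data:
        out.extend(expand_distance(d, k=k))
    return out


def default_epsilon_mapping(alpha: float = 0.5, lo: float = 0.5, hi: float = 2.0) -> Callable[[float], float]:
    """dPi -> water-interaction scale: clip(1 + alpha * dPi, lo, hi).

    Positive dPi (more water-exposed in the open state) strengthens the
    side-chain/water interaction; negative dPi weakens it.
    """

    def mapping(delta_pi: float) -> float:
        return float(np.clip(1.0 + alpha * delta_pi, lo, hi))

    return mapping


def build_solvent_patches(
    data: Iterable[AccessibilityDatum],
    mapping: Callable[[float], float] | None = None,
    n_subunits: int = 5,
) -> list[SolventPatch]:
    """One patch per (significant residue x subunit); insignificant data yield none."""
    mapping = mapping or default_epsilon_mapping()
    out = []
    for d in data:
        if not d.significant:
            continue
        scale = mapping(d.delta_pi)
        if scale <= 0:
            raise RestraintError(
                f"epsilon mapping produced non-positive scale {scale} for residue {d.residue}"
            )
        for su in range(n_subunits):
            out.append(
                SolventPatch(
                    residue=d.residue,
                    subunit=su,
                    new_type_name=f"SP{d.residue:03d}",
                    epsilon_water_scale=scale,
                )
            )
    return out


def build_all(
    distance_data: Iterable[DistanceDatum],
    accessibility_data: Iterable[AccessibilityDatum],
    k: float = DEFAULT_K,
    mapping: Callable[[float], float] | None = None,
) -> RestraintSet:
    """Build the full restraint set with per-source counts."""
    distance_data = list(distance_data)
    restraints = build_distance_restraints(distance_data, k=k)
    patches = build_solvent_patches(accessibility_data, mapping=mapping)
    counts = {
        "FRET": sum(r.source == "FRET" for r in restraints),
        "EPR": sum(r.source == "EPR" for r in restraints),
        "solvent": len(patches),
    }
    return RestraintSet(
        distance_restraints=restraints, solvent_patches=patches, counts_by_source=counts
    )


def make_lambda_schedule(n_windows: int, ramp: str = "linear") -> LambdaSchedule:
    """Evenly spaced coupling values 0 .. 1 over ``n_windows`` windows."""
    if n_windows < 2:
        raise RestraintError("need at least 2 lambda windows")
    if ramp != "linear":
        raise RestraintError(f"unknown ramp {ramp!r}")
    return LambdaSchedule(values=tuple(np.linspace(0.0, 1.0, n_windows).tolist()))


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------


def read_distance_csv(path: str | Path) -> list[DistanceDatum]:
    """CSV columns: residue, value (nm), uncertainty (nm), source (FRET|EPR)."""
    df = pd.read_csv(path)
    required = {"residue", "value", "uncertainty", "source"}
    if not required.issubset(df.columns):
        raise RestraintError(f"distance CSV needs columns {sorted(required)}")
    return [
        DistanceDatum(
            residue=int(row.residue),
            d_open=float(row.value),
            width=float(row.uncertainty),
            source=str(row.source),
        )
        for row in df.itertuples()
    ]


def read_accessibility_csv(path: str | Path) -> list[AccessibilityDatum]:
    """CSV columns: residue, delta_pi, region (TM|loop), significant (bool)."""
    df = pd.read_csv(path)
    required = {"residue", "delta_pi", "region", "significant"}
    if not required.issubset(df.columns):
        raise RestraintError(f"accessibility CSV needs columns {sorted(required)}")
    return [
        AccessibilityDatum(
            residue=int(row.residue),
            delta_pi=float(row.delta_pi),
            region=str(row.region),
            significant=bool(row.significant),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------


def _unique_tables(restraints: Sequence[DistanceRestraint]) -> dict[str, DistanceRestraint]:
    tables: dict[str, DistanceRestraint] = {}
    for r in restraints:
        tables.setdefault(r.table_id, r)
    return tables


def _format_table(tab: TabulatedPotential, dialect: str) -> str:
    buf = io.StringIO()
    buf.write(f"# tabulated potential {tab.table_id}\n")
    if dialect == "plain":
        buf.write("# r[nm]  U[kJ/mol]  F[kJ/mol/nm]\n")
        for r, u, f in zip(tab.r, tab.U, tab.F):
            buf.write(f"{r:.6f} {u:.10g} {f:.10g}\n")
    elif dialect == "extended":
        # 7-column bonded-table dialect: x, then three (g, -g') basis pairs;
        # the potential lives in the harmonic pair, the others are zeroed.
        buf.write("# r  1/r 1/r^2  -  -  U  F\n")
        for r, u, f in zip(tab.r, tab.U, tab.F):
            buf.write(f"{r:.6f} 0 0 0 0 {u:.10g} {f:.10g}\n")
    else:
        raise RestraintError(f"unknown table dialect {dialect!r}")
    return buf.getvalue()


def emit(
    restraint_set: RestraintSet,
    schedule: LambdaSchedule,
    out_dir: str | Path,
    dr: float = DEFAULT_DR,
    r_max: float = DEFAULT_R_MAX,
    dialect: str = "plain",
) -> dict:
    """Write tables, topology patch, schedule and manifest; returns the manifest.

    File naming and float formatting are deterministic: re-emission of the
    same restraint set is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables_dir = out / "tables"
    tables_dir.mkdir(exist_ok=True)

    table_files = {}
    for table_id, r in sorted(_unique_tables(restraint_set.distance_restraints).items()):
        # grow the grid when a flat region would not fit (large diagonals)
        flat_end = r.target + (r.width if r.kind == "flat_bottom" else 0.0)
        r_max_eff = max(r_max, float(np.ceil(flat_end + 1.0)))
        if r.kind == "flat_bottom":
            tab = tabulate(
                "flat_bottom",
                {"target": r.target, "width": r.width, "k": r.k},
                r_max=r_max_eff,
                dr=dr,
                table_id=table_id,
            )
        else:
            tab = tabulate(
                "lower_half_harmonic",
                {"bound": r.target, "k": r.k},
                r_max=r_max_eff,
                dr=dr,
                table_id=table_id,
            )
        fname = f"table_{table_id}.xvg"
        (tables_dir / fname).write_text(_format_table(tab, dialect))
        table_files[table_id] = f"tables/{fname}"

    # topology patch: bonded section (bead pair / table / k) + new particle types
    lines = ["; restraint topology patch (generated)", "[ bonds ]", "; ai aj funct table k"]
    for r in restraint_set.distance_restraints:
        i, j = r.subunit_pair
        lines.append(
            f"S{i}:R{r.residue:03d}:BB S{j}:R{r.residue:03d}:BB 9 {r.table_id} {r.k:.6g}"
        )
    lines += ["", "[ atomtypes ]", "; new particle types scaling the water interaction"]
    seen = set()
    for p in restraint_set.solvent_patches:
        if p.new_type_name in seen:
            continue
        seen.add(p.new_type_name)
        lines.append(f"{p.new_type_name} eps_water_scale {p.epsilon_water_scale:.6g}")
    lines += ["", "[ patches ]", "; residue subunit new_type"]
    for p in restraint_set.solvent_patches:
        lines.append(f"{p.residue} {p.subunit} {p.new_type_name}")
    (out / "restraints.itp").write_text("\n".join(lines) + "\n")

    (out / "lambda_schedule.dat").write_text(
        "".join(f"{i} {lam:.8f}\n" for i, lam in enumerate(schedule))
    )

    manifest = {
        "counts": dict(restraint_set.counts_by_source),
        "totals": {
            "distance": restraint_set.n_distance,
            "solvent": restraint_set.n_solvent,
        },
        "schedule": [float(v) for v in schedule],
        "tables": table_files,
        "distance_restraints": [
            {
                "residue": r.residue,
                "subunit_pair": list(r.subunit_pair),
                "neighbour_order": r.neighbour_order,
                "kind": r.kind,
                "target": float(r.target),
                "width": float(r.width),
                "k": float(r.k),
                "table_id": r.table_id,
                "source": r.source,
            }
            for r in restraint_set.distance_restraints
        ],
        "solvent_patches": [
            {
                "residue": p.residue,
                "subunit": p.subunit,
                "new_type_name": p.new_type_name,
                "epsilon_water_scale": float(p.epsilon_water_scale),
            }
            for p in restraint_set.solvent_patches
        ],
    }
    (out / "manifest.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False, default_flow_style=False)
    )
    return manifest


def load_manifest(out_dir: str | Path) -> tuple[RestraintSet, LambdaSchedule]:
    """Parse an emitted manifest back into a RestraintSet and schedule."""
    manifest = yaml.safe_load((Path(out_dir) / "manifest.yaml").read_text())
    restraints = [
        DistanceRestraint(
            residue=int(d["residue"]),
            subunit_pair=tuple(d["subunit_pair"]),
            neighbour_order=d["neighbour_order"],
            kind=d["kind"],
            target=float(d["target"]),
            width=float(d["width"]),
            k=float(d["k"]),
            table_id=d["table_id"],
            source=d["source"],
        )
        for d in manifest["distance_restraints"]
    ]
    patches = [
        SolventPatch(
            residue=int(p["residue"]),
            subunit=int(p["subunit"]),
            new_type_name=p["new_type_name"],
            epsilon_water_scale=float(p["epsilon_water_scale"]),
        )
        for p in manifest["solvent_patches"]
    ]
    schedule = LambdaSchedule(values=tuple(manifest["schedule"]))
    return (
        RestraintSet(
            distance_restraints=restraints,
            solvent_patches=patches,
            counts_by_source=dict(manifest["counts"]),
        ),
        schedule,
    )


# ---------------------------------------------------------------------------
# Deriving data from structures (used by tests and the toy relaxer workflow)
# ---------------------------------------------------------------------------


def data_from_structure(
    s,
    residues: Iterable[int],
    source: str = "FRET",
    width: float = 0.1,
) -> list[DistanceDatum]:
    """Measure mean adjacent inter-subunit backbone distances as DistanceData.

    For EPR the measured distance becomes the lower bound (width forced to 0).
    """
    out = []
    for res in residues:
        pts = s.positions(res, role="BB")
        dists = [np.linalg.norm(pts[i] - pts[j]) for i, j in ADJACENT_PAIRS]
        d = float(np.mean(dists))
        out.append(
            DistanceDatum(
                residue=res,
                d_open=d,
                width=0.0 if source == "EPR" else width,
                source=source,
            )
        )
    return out
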