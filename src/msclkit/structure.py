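"""Coarse-grained pentamer structures: container, domain annotations and PDB/GRO I/O.

The central container is :class:`CGStructure`, a thin, validated wrapper around a
pandas DataFrame of beads.  One bead carries a subunit index (0-4), a 1-based
residue number, a role name (``BB`` for the backbone particle, ``SC1``,
``SC2``, ... for side-chain particles) and a position in nanometres.  All
analysis and restraint code in this package consumes and produces this type.

File I/O is delegated to MDAnalysis; this module only maps between the
on-disk conventions (chain ids, Angstrom coordinates in PDB, fixed-column GRO)
and the in-memory nm-based representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import ClassVar, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NM_PER_ANGSTROM = 0.1
N_SUBUNITS = 5
_CHAIN_IDS = "ABCDE"

#: atom names recognised as the backbone particle when sniffing foreign files
BACKBONE_ALIASES = ("BB", "BAS", "CA", "B")


class StructureError(ValueError):
    """A structure violates the CG pentamer contract."""


class AmbiguityError(StructureError):
    """Subunit assignment cannot be inferred from the file."""


class FormatError(StructureError):
    """The file does not parse under the named standard."""


@dataclass(frozen=True)
class Bead:
    """One CG particle: subunit 0-4, 1-based residue, role, position in nm."""

    subunit: int
    residue: int
    role: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not 0 <= self.subunit < N_SUBUNITS:
            raise StructureError(f"subunit {self.subunit} outside 0..{N_SUBUNITS - 1}")
        if self.residue < 1:
            raise StructureError(f"residue {self.residue} must be >= 1")
        if not np.all(np.isfinite(self.position)):
            raise StructureError("bead position must be finite")


@dataclass
class DomainMap:
    """Named inclusive residue intervals for the functional domains.

    The hydrophobic gate (residues 20-28) and the kink-prone sub-intervals are
    fixed by the underlying experimental conventions; the remaining intervals
    are configurable defaults for the Eco-MscL layout.
    """

    intervals: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DomainMap.DEFAULTS))

    DEFAULTS: ClassVar[Mapping[str, tuple[int, int]]] = {
        "N_terminal": (1, 14),
        "TM1": (15, 45),
        "periplasmic_loop": (46, 74),
        "TM2": (75, 107),
        "C_terminal": (108, 136),
        "hydrophobic_gate": (20, 28),
    }
    ALIASES: ClassVar[Mapping[str, str]] = {
        "loop": "periplasmic_loop",
        "gate": "hydrophobic_gate",
        "N_term": "N_terminal",
        "C_term": "C_terminal",
    }

    def __post_init__(self) -> None:
        for name, (first, last) in self.intervals.items():
            if last < first:
                raise StructureError(f"domain {name!r}: empty interval [{first}, {last}]")

    @classmethod
    def default(cls) -> "DomainMap":
        return cls()

    def interval(self, name: str) -> tuple[int, int]:
        key = self.ALIASES.get(name, name)
        try:
            return self.intervals[key]
        except KeyError:
            raise StructureError(
                f"unknown domain {name!r}; known: {sorted(self.intervals)}"
            ) from None

    def residues(self, name: str) -> range:
        first, last = self.interval(name)
        return range(first, last + 1)

    def merged(self, overrides: Mapping[str, Sequence[int]] | None) -> "DomainMap":
        if not overrides:
            return self
        intervals = dict(self.intervals)
        for name, pair in overrides.items():
            first, last = int(pair[0]), int(pair[1])
            intervals[self.ALIASES.get(name, name)] = (first, last)
        return DomainMap(intervals)


class CGStructure:
    """Ordered collection of CG beads forming (part of) a pentamer.

    Parameters
    ----------
    beads:
        Either a DataFrame with columns ``subunit, residue, role, x, y, z``
        (coordinates in nm) or an iterable of :class:`Bead`.
    box:
        Optional orthorhombic box lengths in nm.
    label:
        Free-text label carried through selections.
    """

    COLUMNS = ("subunit", "residue", "role", "x", "y", "z")

    def __init__(
        self,
        beads: pd.DataFrame | Iterable[Bead],
        box: Sequence[float] | None = None,
        label: str = "",
    ) -> None:
        if isinstance(beads, pd.DataFrame):
            df = beads.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        else:
            rows = [(b.subunit, b.residue, b.role, *b.position) for b in beads]
            df = pd.DataFrame(rows, columns=list(self.COLUMNS))
        df["subunit"] = df["subunit"].astype(int)
        df["residue"] = df["residue"].astype(int)
        df["role"] = df["role"].astype(str)
        for c in "xyz":
            df[c] = df[c].astype(float)
        self._df = df
        self.box = None if box is None else tuple(float(v) for v in box)
        self.label = label
        self._validate_light()

    # -- validation ---------------------------------------------------------

    def _validate_light(self) -> None:
        df = self._df
        if len(df) and not np.isfinite(df[["x", "y", "z"]].to_numpy()).all():
            raise StructureError("non-finite coordinates")
        if len(df) and ((df["subunit"] < 0) | (df["subunit"] >= N_SUBUNITS)).any():
            raise StructureError("subunit index outside 0..4")
        if len(df) and (df["residue"] < 1).any():
            raise StructureError("residue numbers must be >= 1")
        if df.duplicated(["subunit", "residue", "role"]).any():
            dup = df[df.duplicated(["subunit", "residue", "role"])].iloc[0]
            raise StructureError(
                f"duplicate bead (subunit={dup.subunit}, residue={dup.residue}, role={dup.role!r})"
            )

    def validate_pentamer(self) -> "CGStructure":
        """Assert the full-pentamer invariants (5 equal subunits, BB per residue)."""
        df = self._df
        if df.empty:
            raise StructureError("structure has no beads")
        subunits = sorted(df["subunit"].unique())
        if subunits != list(range(N_SUBUNITS)):
            raise StructureError(f"expected subunits 0..4, found {subunits}")
        residue_sets = {
            su: tuple(sorted(g["residue"].unique())) for su, g in df.groupby("subunit")
        }
        ref = residue_sets[0]
        for su, rs in residue_sets.items():
            if rs != ref:
                counts = {k: len(v) for k, v in residue_sets.items()}
                raise StructureError(
                    f"ragged subunits: residue sets differ (counts per subunit: {counts})"
                )
        bb = df[df["role"] == "BB"]
        n_bb = bb.groupby(["subunit", "residue"]).size()
        if len(n_bb) != N_SUBUNITS * len(ref):
            raise StructureError("every residue of every subunit needs a backbone bead")
        return self

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CGStructure):
            return NotImplemented
        return self._df.equals(other._df) and self.box == other.box

    @property
    def beads(self) -> pd.DataFrame:
        """The underlying bead table (view; treat as read-only)."""
        return self._df

    @property
    def coords(self) -> np.ndarray:
        return self._df[["x", "y", "z"]].to_numpy()

    @property
    def subunits(self) -> list[int]:
        return sorted(self._df["subunit"].unique())

    def residues(self, subunit: int | None = None) -> list[int]:
        df = self._df if subunit is None else self._df[self._df["subunit"] == subunit]
        return sorted(df["residue"].unique())

    def copy(self) -> "CGStructure":
        return CGStructure(self._df.copy(), box=self.box, label=self.label)

    def with_coords(self, coords: np.ndarray) -> "CGStructure":
        """Return a copy with the same beads but new coordinates (nm)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self._df), 3):
            raise StructureError(f"coords shape {coords.shape} != ({len(self._df)}, 3)")
        df = self._df.copy()
        df[["x", "y", "z"]] = coords
        return CGStructure(df, box=self.box, label=self.label)

    def backbone(self) -> "CGStructure":
        return CGStructure(self._df[self._df["role"] == "BB"], box=self.box, label=self.label)

    def positions(self, residue: int, role: str = "BB") -> np.ndarray:
        """Positions of one residue's beads of the given role, ordered by subunit.

        Returns a ``(n_subunits, 3)`` array; raises if any subunit lacks it.
        """
        sel = self._df[(self._df["residue"] == residue) & (self._df["role"] == role)]
        sel = sel.sort_values("subunit")
        if len(sel) != len(self.subunits):
            raise StructureError(
                f"residue {residue} role {role!r} missing in some subunits "
                f"(found {len(sel)} of {len(self.subunits)})"
            )
        return sel[["x", "y", "z"]].to_numpy()

    # -- selection ----------------------------------------------------------

    def select(
        self,
        domain: str | tuple[int, int] | None = None,
        subunit: int | Sequence[int] | None = None,
        role: str | None = None,
        domain_map: DomainMap | None = None,
    ) -> "CGStructure":
        """Subset by domain (name or explicit inclusive interval), subunit, role.

        Ordering and annotations are preserved; filters commute and the
        operation is idempotent.
        """
        df = self._df
        if domain is not None:
            if isinstance(domain, str):
                dm = domain_map or DomainMap.default()
                first, last = dm.interval(domain)
            else:
                first, last = int(domain[0]), int(domain[1])
            df = df[(df["residue"] >= first) & (df["residue"] <= last)]
        if subunit is not None:
            wanted = [subunit] if np.isscalar(subunit) else list(subunit)
            df = df[df["subunit"].isin(wanted)]
        if role is not None:
            df = df[df["role"] == role]
        return CGStructure(df, box=self.box, label=self.label)


def select(
    s: CGStructure,
    domain: str | tuple[int, int] | None = None,
    subunit: int | Sequence[int] | None = None,
    role: str | None = None,
    domain_map: DomainMap | None = None,
) -> CGStructure:
    """Functional form of :meth:`CGStructure.select`."""
    return s.select(domain=domain, subunit=subunit, role=role, domain_map=domain_map)


# ---------------------------------------------------------------------------
# File I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def _sniff_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix == "gro":
        return "gro"
    raise FormatError(f"cannot infer format from suffix of {path.name!r}; pass format=")


def _load_universe(path: Path, fmt: str):
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return mda.Universe(str(path), format=fmt)
    except Exception as exc:  # pragma: no cover - message path
        raise FormatError(f"could not parse {path} as {fmt.upper()}: {exc}") from exc


def _subunits_from_chains(chain_ids: np.ndarray) -> np.ndarray | None:
    """Map chain ids to subunit indices 0..4, or None if chains are absent."""
    distinct = [c for c in dict.fromkeys(chain_ids) if str(c).strip()]
    if len(distinct) <= 1:
        return None
    if len(distinct) != N_SUBUNITS:
        raise AmbiguityError(
            f"expected {N_SUBUNITS} chains, found {len(distinct)}: {distinct}"
        )
    order = {c: i for i, c in enumerate(distinct)}
    return np.array([order[c] for c in chain_ids], dtype=int)


def _subunits_from_blocks(resids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Infer subunits by splitting the residue sequence into 5 equivalent blocks.

    Returns (subunit index per atom, canonical residue number per atom).
    Handles both dialects: per-subunit numbering that resets, and numbering
    that continues across subunits (renumbered to the first block).
    """
    # block boundaries where the residue number decreases
    boundaries = [0]
    for i in range(1, len(resids)):
        if resids[i] < resids[i - 1]:
            boundaries.append(i)
    boundaries.append(len(resids))
    blocks = [resids[a:b] for a, b in zip(boundaries[:-1], boundaries[1:])]

    if len(blocks) == 1:
        # continued numbering: split unique residues into 5 equal runs
        uniq = list(dict.fromkeys(resids.tolist()))
        if len(uniq) % N_SUBUNITS:
            raise AmbiguityError(
                f"no chain ids and {len(uniq)} residues not divisible into "
                f"{N_SUBUNITS} equivalent subunits"
            )
        per = len(uniq) // N_SUBUNITS
        block_of_resid = {r: i // per for i, r in enumerate(uniq)}
        subunit = np.array([block_of_resid[r] for r in resids], dtype=int)
        first_block = uniq[:per]
        offset_sets = []
        for b in range(N_SUBUNITS):
            seq = uniq[b * per : (b + 1) * per]
            offset_sets.append([r - seq[0] + first_block[0] for r in seq])
        if any(seq != first_block for seq in offset_sets):
            counts = [per] * N_SUBUNITS
            raise AmbiguityError(
                f"5 residue blocks are not equivalent (residue counts {counts})"
            )
        canonical = {}
        for b in range(N_SUBUNITS):
            for r, c in zip(uniq[b * per : (b + 1) * per], first_block):
                canonical[(b, r)] = c
        canon = np.array([canonical[(s, r)] for s, r in zip(subunit, resids)], dtype=int)
        return subunit, canon

    if len(blocks) != N_SUBUNITS:
        counts = [len(dict.fromkeys(b.tolist())) for b in blocks]
        raise AmbiguityError(
            f"no chain ids and residue numbering forms {len(blocks)} blocks, "
            f"not {N_SUBUNITS} (residue counts {counts})"
        )
    first = list(dict.fromkeys(blocks[0].tolist()))
    for b in blocks[1:]:
        if list(dict.fromkeys(b.tolist())) != first:
            counts = [len(dict.fromkeys(b.tolist())) for b in blocks]
            raise AmbiguityError(
                f"residue blocks are not equivalent (residue counts {counts})"
            )
    subunit = np.empty(len(resids), dtype=int)
    for i, (a, b) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        subunit[a:b] = i
    return subunit, resids.astype(int)


def _normalise_roles(names: np.ndarray, subunit: np.ndarray, resids: np.ndarray) -> list[str]:
    """Map atom names to roles, sniffing the backbone bead per residue.

    The backbone is the bead named like one of :data:`BACKBONE_ALIASES`; if a
    residue carries none of those names its first bead is taken as backbone and
    the remaining beads become SC1, SC2, ... in file order.
    """
    roles = [str(n).strip() for n in names]
    out = list(roles)
    df = pd.DataFrame({"subunit": subunit, "residue": resids, "i": np.arange(len(roles))})
    for _, g in df.groupby(["subunit", "residue"], sort=False):
        idx = g["i"].to_numpy()
        local = [roles[i] for i in idx]
        bb_pos = [j for j, n in enumerate(local) if n.upper() in BACKBONE_ALIASES]
        if bb_pos:
            sc = 0
            for j, i in enumerate(idx):
                if j == bb_pos[0]:
                    out[i] = "BB"
                elif local[j].upper().startswith("SC"):
                    out[i] = local[j].upper()
                else:
                    sc += 1
                    out[i] = f"SC{sc}"
        else:
            out[idx[0]] = "BB"
            for k, i in enumerate(idx[1:], start=1):
                out[i] = local[k].upper() if local[k].upper().startswith("SC") else f"SC{k}"
    return out


def _structure_from_universe(u, fmt: str, label: str) -> CGStructure:
    atoms = u.atoms
    resids = atoms.resids.astype(int)
    names = atoms.names if hasattr(atoms, "names") else np.array(["BB"] * len(atoms))
    chain_sub = None
    if hasattr(atoms, "chainIDs"):
        chain_sub = _subunits_from_chains(atoms.chainIDs)
    elif hasattr(atoms, "segids"):
        segs = np.array([str(s) for s in atoms.segids])
        if len({s for s in segs if s and s != "SYSTEM"}) > 1:
            chain_sub = _subunits_from_chains(segs)
    if chain_sub is not None:
        subunit, canon = chain_sub, resids
    else:
        subunit, canon = _subunits_from_blocks(resids)
    roles = _normalise_roles(names, subunit, canon)
    xyz = atoms.positions * NM_PER_ANGSTROM  # MDAnalysis is Angstrom internally
    df = pd.DataFrame(
        {
            "subunit": subunit,
            "residue": canon,
            "role": roles,
            "x": xyz[:, 0],
            "y": xyz[:, 1],
            "z": xyz[:, 2],
        }
    )
    box = None
    if u.dimensions is not None:
        lx, ly, lz = (float(v) * NM_PER_ANGSTROM for v in u.dimensions[:3])
        # a unitary/zero cell is a placeholder, not a real box
        if min(lx, ly, lz) > 0.2:
            box = (lx, ly, lz)
    return CGStructure(df, box=box, label=label).validate_pentamer()


def read_structure(path: str | Path, format: str = "auto") -> CGStructure:
    """Read a CG pentamer from a PDB or GRO file.

    Subunits come from chain ids when present, otherwise from an equal-length
    split of the residue sequence into 5 blocks.  Coordinates are converted to
    nm regardless of the on-disk unit convention.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _sniff_format(path, format)
    u = _load_universe(path, fmt)
    return _structure_from_universe(u, fmt, label=path.stem)


def read_structures(path: str | Path, format: str = "auto") -> list[CGStructure]:
    """Read a structure list (multi-model PDB; single-frame files give one)."""
    path = Path(path)
    fmt = _sniff_format(path, format)
    u = _load_universe(path, fmt)
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, _ in enumerate(u.trajectory):
            s = _structure_from_universe(u, fmt, label=f"{path.stem}[{i}]")
            out.append(s)
    return out


def write_structure(s: CGStructure, path: str | Path, format: str = "auto") -> None:
    """Write a CGStructure as PDB (Angstrom, chain per subunit) or GRO (nm).

    ``read_structure(write_structure(s))`` is the identity up to the format's
    coordinate precision (1e-4 nm for PDB, 1e-3 nm for GRO).
    """
    import MDAnalysis as mda

    if len(s) == 0:
        raise StructureError("refusing to write a structure with no beads")
    s.validate_pentamer()
    path = Path(path)
    fmt = _sniff_format(path, format)

    df = s.beads
    res_key = list(dict.fromkeys(zip(df["subunit"], df["residue"])))
    res_index = {k: i for i, k in enumerate(res_key)}
    atom_resindex = np.array([res_index[(su, r)] for su, r in zip(df["subunit"], df["residue"])])
    residue_segindex = np.array([k[0] for k in res_key])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=len(df),
            n_residues=len(res_key),
            n_segments=N_SUBUNITS,
            atom_resindex=atom_resindex,
            residue_segindex=residue_segindex,
            trajectory=True,
        )
        u.add_TopologyAttr("names", df["role"].tolist())
        u.add_TopologyAttr("resids", [k[1] for k in res_key])
        u.add_TopologyAttr("resnames", ["CGR"] * len(res_key))
        u.add_TopologyAttr("segids", [_CHAIN_IDS[i] for i in range(N_SUBUNITS)])
        u.add_TopologyAttr("chainIDs", [_CHAIN_IDS[su] for su in df["subunit"]])
        u.atoms.positions = s.coords / NM_PER_ANGSTROM
        if s.box is not None:
            u.dimensions = [*(v / NM_PER_ANGSTROM for v in s.box), 90.0, 90.0, 90.0]
        elif fmt == "gro":
            # GRO needs a box record; use a generous bounding box
            span = s.coords.max(0) - s.coords.min(0) + 2.0
            u.dimensions = [*(v / NM_PER_ANGSTROM for v in span), 90.0, 90.0, 90.0]
        u.atoms.write(str(path))
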