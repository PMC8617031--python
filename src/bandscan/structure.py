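"""Structure data model, PDB input/output, atom selection, and lysine point mutants.

The in-memory model is a column-oriented ``Structure`` (parallel numpy arrays,
one row per atom) mirroring the fields of a PDB ATOM/HETATM record. Author
residue numbering from the file is kept verbatim, insertion codes included;
nothing is ever renumbered silently. All geometry is heavy-atom; crystal
structures of the complexes this package models carry no hydrogens.

Parsing and serialisation go through biotite's PDB reader/writer; this module
adds the single-conformer altloc policy, a small selection language, and
ideal-geometry side-chain construction for lysine point mutants.
"""
from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as _bst
from biotite.structure.io.pdb import PDBFile

from .geometry import place_atom

__all__ = [
    "AtomRecord",
    "Structure",
    "AtomSet",
    "PDBParseError",
    "read_structure",
    "write_structure",
    "select",
    "mutate_to_lysine",
    "IDEAL_BACKBONE",
    "IDEAL_SIDECHAIN",
]


class PDBParseError(ValueError):
    """Raised when PDB text cannot be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure, in PDB terms."""

    serial: int
    name: str
    element: str
    chain_id: str
    res_name: str
    res_seq: int
    icode: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False


class Structure:
    """Column-oriented atom table with stable file order.

    All per-atom annotations are parallel numpy arrays of length ``n_atoms``;
    ``coord`` is ``(n_atoms, 3)`` float64 in Angstrom.
    """

    _FIELDS = ("serial", "name", "element", "chain_id", "res_name",
               "res_seq", "icode", "occupancy", "altloc", "is_hetero")

    def __init__(self, serial, name, element, chain_id, res_name, res_seq,
                 icode, coord, occupancy=None, altloc=None, is_hetero=None,
                 title: str = ""):
        n = len(name)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.name = np.asarray(name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.res_name = np.asarray(res_name, dtype="U5")
        self.res_seq = np.asarray(res_seq, dtype=np.int64)
        self.icode = np.asarray(icode, dtype="U1")
        self.coord = np.array(coord, dtype=np.float64).reshape(n, 3)
        self.occupancy = (np.ones(n) if occupancy is None
                          else np.asarray(occupancy, dtype=np.float64))
        self.altloc = (np.full(n, "", dtype="U1") if altloc is None
                       else np.asarray(altloc, dtype="U1"))
        self.is_hetero = (np.zeros(n, dtype=bool) if is_hetero is None
                          else np.asarray(is_hetero, dtype=bool))
        self.title = title
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates in Structure")
        if np.any(self.element == ""):
            raise ValueError("empty element symbol in Structure")

    # -- basic container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.name)

    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in first-appearance (file) order."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(
            serial=int(self.serial[i]), name=str(self.name[i]),
            element=str(self.element[i]), chain_id=str(self.chain_id[i]),
            res_name=str(self.res_name[i]), res_seq=int(self.res_seq[i]),
            icode=str(self.icode[i]), coord=self.coord[i].copy(),
            occupancy=float(self.occupancy[i]), altloc=str(self.altloc[i]),
            is_hetero=bool(self.is_hetero[i]),
        )

    def __iter__(self):
        for i in range(len(self)):
            yield self.atom(i)

    # -- derived views ------------------------------------------------------------

    def copy(self) -> "Structure":
        return self.with_coord(self.coord.copy())

    def with_coord(self, coord: np.ndarray) -> "Structure":
        """Same topology and annotations, new coordinates."""
        out = Structure.__new__(Structure)
        for f in self._FIELDS:
            setattr(out, f, getattr(self, f).copy())
        out.coord = np.array(coord, dtype=np.float64).reshape(len(self), 3)
        out.title = self.title
        return out

    def subset(self, indices: np.ndarray) -> "Structure":
        idx = np.asarray(indices, dtype=np.int64)
        return Structure(coord=self.coord[idx].copy(), title=self.title,
                         **{f: getattr(self, f)[idx] for f in self._FIELDS})

    def find_atom(self, chain_id: str, res_seq: int, name: str, icode: str = "") -> int:
        """Index of a uniquely addressed atom; raises KeyError if absent or ambiguous."""
        mask = ((self.chain_id == chain_id) & (self.res_seq == res_seq)
                & (self.name == name) & (self.icode == icode))
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"atom {chain_id}/{res_seq}{icode}/{name} not found")
        if len(idx) > 1:
            raise KeyError(f"atom {chain_id}/{res_seq}{icode}/{name} is ambiguous")
        return int(idx[0])

    def residue_indices(self, chain_id: str, res_seq: int, icode: str = "") -> np.ndarray:
        mask = ((self.chain_id == chain_id) & (self.res_seq == res_seq)
                & (self.icode == icode))
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise KeyError(f"residue {chain_id}/{res_seq}{icode} not found")
        return idx

    def iter_residues(self):
        """Yield ``(chain_id, res_seq, icode, indices)`` in file order."""
        if len(self) == 0:
            return
        key = np.stack([self.chain_id.astype("U4"),
                        self.res_seq.astype("U12"),
                        self.icode.astype("U1")], axis=1)
        start = 0
        for i in range(1, len(self) + 1):
            if i == len(self) or not np.array_equal(key[i], key[start]):
                yield (str(self.chain_id[start]), int(self.res_seq[start]),
                       str(self.icode[start]), np.arange(start, i))
                start = i

    # -- biotite interop ----------------------------------------------------------

    def to_atom_array(self) -> _bst.AtomArray:
        arr = _bst.AtomArray(len(self))
        arr.coord = self.coord.astype(np.float32)
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_seq.copy()
        arr.ins_code = self.icode.astype("U1")
        arr.res_name = self.res_name.astype("U5")
        arr.hetero = self.is_hetero.copy()
        arr.atom_name = self.name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.set_annotation("occupancy", self.occupancy.copy())
        arr.set_annotation("b_factor", np.zeros(len(self)))
        return arr

    @classmethod
    def from_atom_array(cls, arr: _bst.AtomArray, title: str = "") -> "Structure":
        n = arr.array_length()
        occ = (arr.occupancy if "occupancy" in arr.get_annotation_categories()
               else np.ones(n))
        alt = (arr.altloc_id if "altloc_id" in arr.get_annotation_categories()
               else np.full(n, "", dtype="U1"))
        alt = np.char.strip(alt.astype("U1"))
        serial = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
                  else np.arange(1, n + 1))
        element = np.char.strip(arr.element.astype("U2"))
        if np.any(element == ""):
            element = element.copy()
            for i in np.flatnonzero(element == ""):
                element[i] = _infer_element(str(arr.atom_name[i]))
        return cls(serial=serial, name=np.char.strip(arr.atom_name.astype("U6")),
                   element=element, chain_id=arr.chain_id, res_name=arr.res_name,
                   res_seq=arr.res_id, icode=np.char.strip(arr.ins_code.astype("U1")),
                   coord=arr.coord.astype(np.float64), occupancy=occ, altloc=alt,
                   is_hetero=arr.hetero, title=title)


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("FE", "ZN", "MG", "MN", "CL", "BR", "NA", "SE"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


@dataclass
class AtomSet:
    """An ordered, duplicate-free view onto a subset of a Structure's atoms."""

    structure: Structure
    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if len(self.indices) != len(np.unique(self.indices)):
            raise ValueError("AtomSet indices must be unique")
        if len(self.indices) and (self.indices.min() < 0
                                  or self.indices.max() >= len(self.structure)):
            raise ValueError("AtomSet index out of range")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def coord(self) -> np.ndarray:
        return self.structure.coord[self.indices]

    def to_structure(self) -> Structure:
        return self.structure.subset(self.indices)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

_COORD_RE = re.compile(r"^(ATOM|HETATM)")


def read_structure(source) -> Structure:
    """Read a PDB file (path, text, or file-like) into a :class:`Structure`.

    Altloc policy (single-conformer model): keep records with blank or 'A'
    altloc; for residues offering neither, keep the highest-occupancy record
    of each atom. Coordinates are preserved to the 3 decimals of the format.
    """
    text, origin = _as_text(source)
    if not text.strip():
        raise PDBParseError(f"empty PDB input ({origin})")
    try:
        pdb = PDBFile.read(io.StringIO(text))
        arr = pdb.get_structure(model=1, altloc="all",
                                extra_fields=["atom_id", "occupancy"])
    except Exception as exc:  # locate the offending line for the error message
        lineno = _first_malformed_line(text)
        raise PDBParseError(f"cannot parse PDB input ({origin}): {exc}",
                            line_number=lineno) from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"no ATOM/HETATM records in input ({origin})")
    s = Structure.from_atom_array(arr, title=origin)
    return _resolve_altloc(s)


def _as_text(source) -> tuple[str, str]:
    if hasattr(source, "read"):
        return source.read(), "<stream>"
    s = str(source)
    if "\n" in s or s.startswith(("ATOM", "HETATM", "HEADER", "TITLE", "MODEL", "CRYST")):
        return s, "<text>"
    if os.path.exists(s):
        with open(s) as fh:
            return fh.read(), os.path.basename(s)
    raise FileNotFoundError(f"no such PDB file: {s}")


def _first_malformed_line(text: str) -> int | None:
    for i, line in enumerate(text.splitlines(), start=1):
        if _COORD_RE.match(line):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                return i
    return None


def _resolve_altloc(s: Structure) -> Structure:
    if np.all(s.altloc == ""):
        return s
    keep = (s.altloc == "") | (s.altloc == "A")
    # atoms whose every altloc is non-blank, non-A: keep the top-occupancy one
    groups: dict[tuple, list[int]] = {}
    for i in np.flatnonzero(~keep):
        key = (str(s.chain_id[i]), int(s.res_seq[i]), str(s.icode[i]), str(s.name[i]))
        groups.setdefault(key, []).append(i)
    for key, members in groups.items():
        chain, seq, icode, name = key
        has_primary = np.any(
            keep & (s.chain_id == chain) & (s.res_seq == seq)
            & (s.icode == icode) & (s.name == name))
        if not has_primary:
            best = max(members, key=lambda i: s.occupancy[i])
            keep[best] = True
    return s.subset(np.flatnonzero(keep))


def write_structure(s: Structure, dest=None) -> str:
    """Serialise a Structure to PDB text; optionally write it to ``dest``.

    The emitted text re-parses to an equal structure (coordinates to 1e-3 A).
    """
    if len(s) == 0:
        raise ValueError("cannot write an empty Structure")
    too_long = np.char.str_len(s.name) > 4
    if np.any(too_long):
        bad = str(s.name[np.flatnonzero(too_long)[0]])
        raise ValueError(f"atom name {bad!r} exceeds the 4-character PDB field")
    pdb = PDBFile()
    pdb.set_structure(s.to_atom_array())
    buf = io.StringIO()
    pdb.write(buf)
    text = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

_SELECT_FIELDS = {"chain", "resseq", "resname", "name", "element", "hetero", "protein", "all"}


def select(s: Structure, query: str | None = None, **fields) -> AtomSet:
    """Select atoms by a query string or keyword filters; returns an AtomSet.

    Keyword form: ``select(s, chain="A", res_seq=85, name="SG")``; values may
    be scalars, lists, or ``(lo, hi)`` inclusive ranges for ``res_seq``.

    String form (documented in the README): terms ``chain A``, ``resseq 36-40``,
    ``resname LYS``, ``name CA``, ``element N``, ``hetero``, ``protein``, ``all``,
    combined with ``and``, ``or``, ``not`` and parentheses. Comma-separated
    values within a term are alternatives.
    """
    if query is not None and fields:
        raise ValueError("give either a query string or keyword filters, not both")
    if query is not None:
        mask = _SelectionParser(query).parse()(s)
    else:
        mask = np.ones(len(s), dtype=bool)
        for key, value in fields.items():
            mask &= _keyword_mask(s, key, value)
    return AtomSet(s, np.flatnonzero(mask))


def _keyword_mask(s: Structure, key: str, value) -> np.ndarray:
    arrays = {"chain": s.chain_id, "chain_id": s.chain_id, "res_name": s.res_name,
              "name": s.name, "element": s.element}
    if key in arrays:
        values = value if isinstance(value, (list, tuple, set)) else [value]
        return np.isin(arrays[key], list(values))
    if key == "res_seq":
        if isinstance(value, tuple) and len(value) == 2:
            return (s.res_seq >= value[0]) & (s.res_seq <= value[1])
        values = value if isinstance(value, (list, set)) else [value]
        return np.isin(s.res_seq, list(values))
    if key == "hetero":
        return s.is_hetero == bool(value)
    raise ValueError(f"unknown selection field: {key!r}")


class _SelectionParser:
    """Recursive-descent parser for the tiny selection language."""

    def __init__(self, text: str):
        self.tokens = text.replace("(", " ( ").replace(")", " ) ").split()
        self.pos = 0

    def parse(self):
        node = self._or()
        if self.pos != len(self.tokens):
            raise ValueError(f"trailing tokens in selection: {self.tokens[self.pos:]}")
        return node

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        self.pos += 1
        return tok

    def _or(self):
        left = self._and()
        while self._peek() == "or":
            self._next()
            right = self._and()
            left = (lambda a, b: lambda s: a(s) | b(s))(left, right)
        return left

    def _and(self):
        left = self._unary()
        while self._peek() == "and":
            self._next()
            right = self._unary()
            left = (lambda a, b: lambda s: a(s) & b(s))(left, right)
        return left

    def _unary(self):
        tok = self._peek()
        if tok == "not":
            self._next()
            inner = self._unary()
            return lambda s: ~inner(s)
        if tok == "(":
            self._next()
            inner = self._or()
            if self._next() != ")":
                raise ValueError("unbalanced parentheses in selection")
            return inner
        return self._term()

    def _term(self):
        tok = self._next()
        if tok is None:
            raise ValueError("unexpected end of selection")
        field = tok.lower()
        if field not in _SELECT_FIELDS:
            raise ValueError(f"unknown field in selection query: {tok!r}")
        if field == "hetero":
            return lambda s: s.is_hetero.copy()
        if field == "protein":
            return lambda s: ~s.is_hetero
        if field == "all":
            return lambda s: np.ones(len(s), dtype=bool)
        value = self._next()
        if value is None:
            raise ValueError(f"missing value after {field!r}")
        alternatives = value.split(",")
        if field == "resseq":
            def resseq_mask(s, alts=alternatives):
                mask = np.zeros(len(s), dtype=bool)
                for alt in alts:
                    if re.fullmatch(r"-?\d+", alt):
                        mask |= s.res_seq == int(alt)
                    else:
                        lo, hi = _parse_range(alt)
                        mask |= (s.res_seq >= lo) & (s.res_seq <= hi)
                return mask
            return resseq_mask
        array_name = {"chain": "chain_id", "resname": "res_name",
                      "name": "name", "element": "element"}[field]
        return lambda s: np.isin(getattr(s, array_name), alternatives)


def _parse_range(token: str) -> tuple[int, int]:
    m = re.fullmatch(r"(-?\d+)-(-?\d+)", token)
    if not m:
        raise ValueError(f"bad residue range: {token!r}")
    return int(m.group(1)), int(m.group(2))


# ---------------------------------------------------------------------------
# Lysine point mutants
# ---------------------------------------------------------------------------

# Ideal heavy-atom geometry (bond lengths in A, angles in degrees), standard
# small-molecule values for aliphatic chains and the peptide unit.
IDEAL_BACKBONE = {
    "N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231,
    "N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8,
}
IDEAL_SIDECHAIN = {
    "CA-CB": 1.530, "C-C": 1.520, "C-N": 1.489, "C-O": 1.249,
    "N-CA-CB": 110.5, "C-C-C": 111.3, "C-C-N": 111.9, "C-C-O": 118.4,
    "C-N-CA-CB": 122.6,  # improper fixing the L-configuration at CA
}

# Side chains are built in the extended rotamer: every chi torsion at 180 deg.
_LYS_SIDE_CHAIN = [
    # (name, element, ref atoms, bond key, angle key, torsion)
    ("CB", "C", ("C", "N", "CA"), "CA-CB", "N-CA-CB", IDEAL_SIDECHAIN["C-N-CA-CB"]),
    ("CG", "C", ("N", "CA", "CB"), "C-C", "C-C-C", 180.0),
    ("CD", "C", ("CA", "CB", "CG"), "C-C", "C-C-C", 180.0),
    ("CE", "C", ("CB", "CG", "CD"), "C-C", "C-C-C", 180.0),
    ("NZ", "N", ("CG", "CD", "CE"), "C-N", "C-C-N", 180.0),
]


def build_lysine_side_chain(n, ca, c) -> list[tuple[str, str, np.ndarray]]:
    """Ideal extended-rotamer lysine side chain from backbone N, CA, C positions.

    Returns ``[(atom_name, element, coord), ...]`` for CB, CG, CD, CE, NZ.
    """
    pos = {"N": np.asarray(n, float), "CA": np.asarray(ca, float),
           "C": np.asarray(c, float)}
    out = []
    for name, element, (a, b, cref), bond_key, angle_key, torsion in _LYS_SIDE_CHAIN:
        coord = place_atom(pos[a], pos[b], pos[cref],
                           IDEAL_SIDECHAIN[bond_key], IDEAL_SIDECHAIN[angle_key],
                           torsion)
        pos[name] = coord
        out.append((name, element, coord))
    return out


def mutate_to_lysine(s: Structure, chain_id: str, res_seq: int,
                     icode: str = "") -> Structure:
    """Replace a residue's side chain with an ideal extended-rotamer lysine.

    Backbone atoms (N, CA, C, O) are untouched; all existing side-chain atoms
    are removed and CB-CG-CD-CE-NZ are rebuilt with ideal bond lengths and
    angles, every side-chain torsion at 180 degrees. The residue is renamed
    LYS. No atom outside the target residue is modified.
    """
    res_idx = s.residue_indices(chain_id, res_seq, icode)
    names = s.name[res_idx]
    for required in ("N", "CA", "C"):
        if required not in names:
            raise ValueError(
                f"residue {chain_id}/{res_seq}{icode} lacks backbone atom {required}; "
                "cannot build a lysine side chain")
    backbone_names = {"N", "CA", "C", "O", "OXT"}
    keep_mask = np.ones(len(s), dtype=bool)
    for i in res_idx:
        if s.name[i] not in backbone_names:
            keep_mask[i] = False
    kept = s.subset(np.flatnonzero(keep_mask))

    n = s.coord[res_idx[names == "N"][0]]
    ca = s.coord[res_idx[names == "CA"][0]]
    c = s.coord[res_idx[names == "C"][0]]
    side = build_lysine_side_chain(n, ca, c)

    # splice the new atoms immediately after the residue's kept atoms
    kept_res = ((kept.chain_id == chain_id) & (kept.res_seq == res_seq)
                & (kept.icode == icode))
    insert_at = int(np.flatnonzero(kept_res)[-1]) + 1
    new_rows = {f: [] for f in Structure._FIELDS}
    new_coords = []
    for name, element, coord in side:
        new_rows["serial"].append(0)
        new_rows["name"].append(name)
        new_rows["element"].append(element)
        new_rows["chain_id"].append(chain_id)
        new_rows["res_name"].append("LYS")
        new_rows["res_seq"].append(res_seq)
        new_rows["icode"].append(icode)
        new_rows["occupancy"].append(1.0)
        new_rows["altloc"].append("")
        new_rows["is_hetero"].append(False)
        new_coords.append(coord)

    def splice(arr, new):
        return np.concatenate([arr[:insert_at], np.asarray(new, dtype=arr.dtype),
                               arr[insert_at:]])

    fields = {f: splice(getattr(kept, f), new_rows[f]) for f in Structure._FIELDS}
    coord = np.concatenate([kept.coord[:insert_at], np.asarray(new_coords),
                            kept.coord[insert_at:]])
    out = Structure(coord=coord, title=s.title, **fields)
    out.res_name[(out.chain_id == chain_id) & (out.res_seq == res_seq)
                 & (out.icode == icode)] = "LYS"
    out.serial = np.arange(1, len(out) + 1)
    return out
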