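"""Coordinate file I/O, atom selections, and ligand extraction.

The data model is deliberately small: a :class:`StructureModel` is an
ordered list of :class:`AtomRecord`, one per retained heavy atom of the
first model of a PDB or mmCIF file.  Everything downstream — domain
superposition, the flag-rotation sweep, clash counting, cavity detection —
consumes these records or plain NumPy coordinate arrays derived from them.

Parsing is backed by gemmi; writing uses the fixed-column PDB format so
synthetic fixtures round-trip losslessly at format precision (1e-3 Å).

Conventions applied at parse time:

* only the first model of multi-model files is kept;
* hydrogens (and deuterium) are dropped — the crystal structures analysed
  contain none and the clash thresholds are calibrated on heavy atoms;
* waters are excluded;
* alternate locations are resolved to the highest-occupancy conformer,
  ties broken by alphabetical altloc identifier;
* residue numbering is author numbering throughout.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    FormatError,
    InputError,
    MissingLigandError,
    ParameterError,
)

logger = logging.getLogger(__name__)

#: Atom names expanded by the ``main_chain`` atom class.
MAIN_CHAIN_NAMES = ("N", "CA", "C", "O")

#: Water component codes excluded at parse time.
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

_ATOM_CLASSES = frozenset({"main_chain", "c_beta", "all_heavy"})


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom with its crystallographic identity."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    xyz: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    def __post_init__(self):
        xyz = np.asarray(self.xyz, dtype=float)
        if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
            raise FormatError(
                f"atom {self.name} {self.chain}/{self.res_seq}: "
                f"coordinates must be three finite numbers, got {self.xyz!r}"
            )
        object.__setattr__(self, "xyz", xyz)
        if not self.element:
            raise FormatError(
                f"atom {self.name} {self.chain}/{self.res_seq}: empty element symbol"
            )

    @property
    def key(self) -> tuple:
        """Identity tuple (chain, res_seq, name) after altloc resolution."""
        return (self.chain, self.res_seq, self.name)

    def moved_to(self, xyz) -> "AtomRecord":
        """Copy of this record at new coordinates."""
        return replace(self, xyz=np.asarray(xyz, dtype=float))


@dataclass
class StructureModel:
    """An ordered collection of heavy atoms from one protomer/model."""

    structure_id: str
    atoms: list = field(default_factory=list)
    protomer_id: str = ""

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) array of atom coordinates in input order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.array([a.xyz for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Same atoms, new coordinates (used after rigid transforms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ParameterError(
                f"coordinate array shape {coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        atoms = [a.moved_to(x) for a, x in zip(self.atoms, coords)]
        return StructureModel(self.structure_id, atoms, self.protomer_id)

    def copy(self) -> "StructureModel":
        return StructureModel(self.structure_id, list(self.atoms), self.protomer_id)

    def chains(self) -> list:
        seen = dict.fromkeys(a.chain for a in self.atoms)
        return list(seen)

    def residues(self, chain: str | None = None) -> list:
        """Ordered distinct (chain, res_seq, res_name) triples."""
        out = dict.fromkeys(
            (a.chain, a.res_seq, a.res_name)
            for a in self.atoms
            if chain is None or a.chain == chain
        )
        return list(out)

    def to_pdb_string(self) -> str:
        lines = []
        for a in self.atoms:
            record = "HETATM" if a.hetero else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{a.serial % 100000:5d} {name}{a.altloc or ' ':1s}"
                f"{a.res_name:>3s} {a.chain[:1]:1s}{a.res_seq:4d}    "
                f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2s}"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"

    def write_pdb(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_pdb_string())


@dataclass
class SelectionSpec:
    """Declarative atom selection: chain ∧ residue ranges ∧ atom classes.

    ``atom_classes`` is a subset of {main_chain, c_beta, all_heavy};
    ``main_chain`` expands to exactly N, CA, C, O and ``c_beta`` to CB
    (glycine therefore contributes no c_beta atom).  ``ligand_names``
    additionally admits hetero components by residue code.
    """

    chain: str
    residue_ranges: list = field(default_factory=list)
    atom_classes: tuple = ("all_heavy",)
    ligand_names: tuple = ()

    def validate(self) -> None:
        if not self.residue_ranges and not self.ligand_names:
            raise ParameterError("selection has no residue_ranges and no ligand_names")
        for rng in self.residue_ranges:
            if len(rng) != 2 or rng[0] > rng[1]:
                raise ParameterError(f"invalid residue range {rng!r}: need start <= end")
        bad = set(self.atom_classes) - _ATOM_CLASSES
        if bad:
            raise ParameterError(f"unknown atom classes {sorted(bad)}")
        if not self.atom_classes:
            raise ParameterError("selection needs at least one atom class")

    def _name_matches(self, atom: AtomRecord) -> bool:
        if "all_heavy" in self.atom_classes:
            return True
        if "main_chain" in self.atom_classes and atom.name in MAIN_CHAIN_NAMES:
            return True
        if "c_beta" in self.atom_classes and atom.name == "CB":
            return True
        return False

    def matches(self, atom: AtomRecord) -> bool:
        if atom.chain != self.chain:
            return False
        if atom.hetero:
            return atom.res_name in self.ligand_names
        in_range = any(lo <= atom.res_seq <= hi for lo, hi in self.residue_ranges)
        return in_range and self._name_matches(atom)


@dataclass
class DomainDefinition:
    """A named domain (n_domain, c_domain, subdomain_a, subdomain_b, fsh)."""

    name: str
    selection: SelectionSpec

    _NAMES = frozenset({"n_domain", "c_domain", "subdomain_a", "subdomain_b", "fsh"})

    def __post_init__(self):
        if self.name not in self._NAMES:
            raise ParameterError(
                f"domain name {self.name!r} not in {sorted(self._NAMES)}"
            )
        self.selection.validate()

    def residue_set(self) -> set:
        return {
            r
            for lo, hi in self.selection.residue_ranges
            for r in range(lo, hi + 1)
        }


def check_domains_disjoint(n_def: DomainDefinition, c_def: DomainDefinition) -> None:
    """N- and C-terminal domains of one structure must not share residues."""
    overlap = n_def.residue_set() & c_def.residue_set()
    if overlap:
        raise ParameterError(
            f"n_domain and c_domain overlap at residues {sorted(overlap)[:5]}..."
            if len(overlap) > 5
            else f"n_domain and c_domain overlap at residues {sorted(overlap)}"
        )


# ---------------------------------------------------------------------------
# parsing


def _looks_like_mmcif(text: str) -> bool:
    head = text.lstrip()[:4000]
    return head.startswith("data_") or "_atom_site." in head


def _gemmi_structure(source, dialect: str) -> gemmi.Structure:
    """Load a gemmi Structure from a path or raw text in either dialect."""
    is_path = isinstance(source, os.PathLike) or (
        isinstance(source, str) and "\n" not in source and os.path.exists(source)
    )
    if is_path:
        path = os.fspath(source)
        try:
            with open(path) as fh:
                text = fh.read()
        except OSError as exc:
            raise InputError(f"cannot read {path}: {exc}") from exc
        if dialect == "auto":
            if path.endswith((".cif", ".mmcif")) or _looks_like_mmcif(text):
                dialect = "mmcif"
            else:
                dialect = "pdb"
    else:
        if not isinstance(source, str):
            raise InputError(f"unsupported source type {type(source)!r}")
        if isinstance(source, str) and "\n" not in source and not os.path.exists(source):
            raise InputError(f"no such file: {source}")
        text = source
        if dialect == "auto":
            dialect = "mmcif" if _looks_like_mmcif(text) else "pdb"

    try:
        if dialect == "pdb":
            return gemmi.read_pdb_string(text)
        if dialect == "mmcif":
            doc = gemmi.cif.read_string(text)
            return gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse {dialect} input: {exc}") from exc
    raise ParameterError(f"unknown dialect {dialect!r}; use pdb, mmcif or auto")


def _resolve_altlocs(atoms: list) -> list:
    """Keep one atom per (chain, res_seq, name): highest occupancy wins,
    ties broken by alphabetical altloc id."""
    best: dict = {}
    order: list = []
    for a in atoms:
        k = a.key
        if k not in best:
            best[k] = a
            order.append(k)
        else:
            b = best[k]
            if (a.occupancy, _altloc_rank(a)) > (b.occupancy, _altloc_rank(b)):
                best[k] = a
    return [best[k] for k in order]


def _altloc_rank(a: AtomRecord):
    # higher rank wins; alphabetically earlier altloc preferred on occupancy tie
    return -ord(a.altloc) if a.altloc else 1


def parse_structure(source, dialect: str = "auto") -> StructureModel:
    """Parse a PDB or mmCIF file (path or raw text) into a StructureModel.

    Returns all heavy atoms of the first model; hydrogens and waters are
    dropped and alternate locations resolved (highest occupancy, ties to
    the alphabetically first altloc).

    Parameters
    ----------
    source : path or str
        File path, or the raw text of a coordinate file.
    dialect : {"auto", "pdb", "mmcif"}
        Input format; ``auto`` sniffs the content.
    """
    st = _gemmi_structure(source, dialect)
    if len(st) == 0:
        raise EmptyStructureError(f"{st.name or 'input'}: no models found")
    model = st[0]

    atoms = []
    serial = 0
    for chain in model:
        for residue in chain:
            if residue.is_water() or residue.name in WATER_NAMES:
                continue
            hetero = residue.het_flag == "H"
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                serial += 1
                altloc = atom.altloc if atom.altloc and atom.altloc != "\0" else ""
                element = atom.element.name.strip()
                if not element or element == "X":
                    # fall back on the leading letter(s) of the atom name
                    element = "".join(c for c in atom.name if c.isalpha())[:1] or "C"
                atoms.append(
                    AtomRecord(
                        serial=atom.serial or serial,
                        name=atom.name,
                        element=element,
                        res_name=residue.name,
                        res_seq=residue.seqid.num,
                        chain=chain.name,
                        xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        occupancy=atom.occ,
                        altloc=altloc,
                        hetero=hetero,
                    )
                )
    if not atoms:
        raise EmptyStructureError("input contains zero ATOM/HETATM records")
    atoms = _resolve_altlocs(atoms)
    name = st.name or ""
    return StructureModel(structure_id=name.strip() or "unnamed", atoms=atoms)


def select_atoms(structure: StructureModel, spec: SelectionSpec) -> list:
    """Atoms of ``structure`` matching ``spec``, in input order.

    An empty result is legal here (callers that require atoms raise
    :class:`EmptySelectionError` themselves) but is logged as a warning.
    """
    spec.validate()
    picked = [a for a in structure.atoms if spec.matches(a)]
    if not picked:
        logger.warning(
            "selection on %s (chain %s, ranges %s, classes %s) matched no atoms",
            structure.structure_id,
            spec.chain,
            spec.residue_ranges,
            spec.atom_classes,
        )
    return picked


def require_atoms(atoms: list, what: str) -> list:
    if not atoms:
        raise EmptySelectionError(f"{what}: selection resolved to zero atoms")
    return atoms


def extract_ligand(structure: StructureModel, component_code: str) -> StructureModel:
    """Extract the first instance of a hetero-component as its own model.

    Atom names are preserved exactly as in the source.  If several copies
    of the component exist (e.g. one per protomer) the first in file order
    is taken and a log line records the choice.
    """
    instances: dict = {}
    for a in structure.atoms:
        if a.hetero and a.res_name == component_code:
            instances.setdefault((a.chain, a.res_seq), []).append(a)
    if not instances:
        present = sorted({a.res_name for a in structure.atoms if a.hetero})
        raise MissingLigandError(
            f"{structure.structure_id}: component {component_code!r} not found; "
            f"hetero components present: {present or 'none'}"
        )
    key = next(iter(instances))
    if len(instances) > 1:
        logger.info(
            "%s: %d instances of %s; using chain %s residue %d",
            structure.structure_id,
            len(instances),
            component_code,
            key[0],
            key[1],
        )
    return StructureModel(
        structure_id=f"{structure.structure_id}:{component_code}",
        atoms=list(instances[key]),
        protomer_id=key[0],
    )
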