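"""CoA ligand geometry: the flag-on-a-mast decomposition and the
exhaustive rigid rotation of the flag about the mast axis.

Coenzyme A is 4'-phosphopantetheine (the "mast": rigid, extended,
thiol-terminated — the moiety shared with holo-ACP) joined through a
pyrophosphate bridge to adenosine 3',5'-bisphosphate (the "flag": the
head group that distinguishes CoA from a bare 4'-PPant arm).  The split
point is the single bridging oxygen of the pyrophosphate: the
pantetheine-side phosphate belongs to the mast, the ribose-5'-side
phosphate to the flag, and the bridging oxygen itself is the rotation
anchor, assigned to neither set for clash counting.

The partition is found by distance-based bond perception and a graph cut
at the bridging oxygen rather than by a hard-coded atom-name list, so it
works for the wwPDB chemical component COA and for renamed variants alike.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .errors import (
    DegenerateGeometryError,
    IncompleteLigandError,
    MappingError,
    ParameterError,
)
from .structure_io import AtomRecord, StructureModel

#: Covalent radii (Å) for bond perception on CoA-like ligands.
COVALENT_RADII = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "P": 1.07,
    "S": 1.05,
    "SE": 1.20,
    "F": 0.57,
    "CL": 1.02,
    "BR": 1.20,
}

#: Slack added to the sum of covalent radii when perceiving bonds.
BOND_TOLERANCE = 0.45


@dataclass(frozen=True)
class MastAxis:
    """The rotation axis: a point plus a unit direction."""

    anchor: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        anchor = np.asarray(self.anchor, dtype=float)
        direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(direction)
        if not np.isfinite(norm) or norm < 1e-12:
            raise DegenerateGeometryError("axis direction has zero length")
        object.__setattr__(self, "anchor", anchor)
        object.__setattr__(self, "direction", direction / norm)


@dataclass
class CoASplit:
    """CoA partitioned into flag, mast and the bridging pivot atom."""

    flag: list
    mast: list
    bridge: AtomRecord
    axis: MastAxis

    @property
    def flag_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.flag], dtype=float)

    @property
    def mast_coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.mast], dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.flag) + len(self.mast) + 1

    def all_atoms(self) -> list:
        return list(self.mast) + [self.bridge] + list(self.flag)


@dataclass
class ConformerSet:
    """The flag swept rigidly about the mast axis at fixed angular steps."""

    angles: np.ndarray
    flag_coords: np.ndarray  # (n_angles, n_flag_atoms, 3)
    split: CoASplit

    def __len__(self) -> int:
        return len(self.angles)

    def frame(self, i: int) -> np.ndarray:
        return self.flag_coords[i]

    def to_multimodel_pdb(self, path) -> None:
        """One MODEL per angle, for visual inspection."""
        with open(path, "w") as fh:
            for i, angle in enumerate(self.angles):
                fh.write(f"MODEL     {i + 1:4d}\n")
                fh.write(f"REMARK 250 ROTATION ANGLE {angle:.1f} DEG\n")
                model = StructureModel(
                    "conf", [a.moved_to(x) for a, x in zip(self.split.flag, self.flag_coords[i])]
                )
                fh.write(model.to_pdb_string().replace("END\n", ""))
                fh.write("ENDMDL\n")
            fh.write("END\n")


def apply_name_map(ligand: StructureModel, name_map: dict) -> StructureModel:
    """Rename ligand atoms via a {source_name: COA_name} map (2-column TSV
    supplied by the user for non-standard CoA naming)."""
    atoms = []
    unmatched = []
    for a in ligand.atoms:
        if a.name in name_map:
            atoms.append(
                AtomRecord(
                    a.serial, name_map[a.name], a.element, a.res_name,
                    a.res_seq, a.chain, a.xyz, a.occupancy, a.altloc, a.hetero,
                )
            )
        else:
            unmatched.append(a.name)
            atoms.append(a)
    if unmatched:
        raise MappingError(f"atom names not covered by the name map: {unmatched}")
    return StructureModel(ligand.structure_id, atoms, ligand.protomer_id)


def perceive_bonds(atoms: list) -> list:
    """Bonded atom-index pairs by the covalent-radius criterion
    d <= r_i + r_j + tolerance."""
    coords = np.array([a.xyz for a in atoms])
    radii = np.array(
        [COVALENT_RADII.get(a.element.upper(), 0.77) for a in atoms]
    )
    d = cdist(coords, coords)
    cut = radii[:, None] + radii[None, :] + BOND_TOLERANCE
    ii, jj = np.where((d <= cut) & (d > 1e-6))
    return [(int(i), int(j)) for i, j in zip(ii, jj) if i < j]


def _connected_component(start: int, adjacency: dict, blocked: int) -> set:
    seen = {start}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adjacency.get(u, ()):
            if v != blocked and v not in seen:
                seen.add(v)
                queue.append(v)
    return seen


def split_coa(ligand: StructureModel, name_map: dict | None = None) -> CoASplit:
    """Partition a CoA-like ligand at the pyrophosphate bridge.

    The bridging oxygen is the unique oxygen bonded to two phosphorus
    atoms.  Cutting it separates the ligand into the mast (the component
    holding the terminal thiol sulfur, i.e. 4'-phosphopantetheine with its
    4'-phosphate) and the flag (the component holding the adenine ring,
    i.e. adenosine 3',5'-bisphosphate with the 5'-alpha-phosphate).  The
    rotation axis is the principal axis of the mast anchored at the bridge.

    Raises
    ------
    IncompleteLigandError
        Missing phosphates, thiol sulfur or adenine nitrogens.
    """
    if name_map:
        ligand = apply_name_map(ligand, name_map)
    atoms = list(ligand.atoms)
    if len(atoms) < 5:
        raise IncompleteLigandError(
            f"{ligand.structure_id}: only {len(atoms)} atoms; not a CoA-like ligand"
        )
    elements = [a.element.upper() for a in atoms]
    p_idx = [i for i, e in enumerate(elements) if e == "P"]
    if len(p_idx) < 2:
        raise IncompleteLigandError(
            f"{ligand.structure_id}: found {len(p_idx)} phosphorus atom(s); "
            "a pyrophosphate bridge requires at least two"
        )

    bonds = perceive_bonds(atoms)
    adjacency: dict = {}
    for i, j in bonds:
        adjacency.setdefault(i, set()).add(j)
        adjacency.setdefault(j, set()).add(i)

    bridge_candidates = [
        i
        for i, e in enumerate(elements)
        if e == "O" and len(adjacency.get(i, set()) & set(p_idx)) >= 2
    ]
    if not bridge_candidates:
        raise IncompleteLigandError(
            f"{ligand.structure_id}: no oxygen bridging two phosphorus atoms "
            "(pyrophosphate bridge not found)"
        )
    # deterministic choice if the geometry is odd enough to offer several
    bridge_idx = min(bridge_candidates, key=lambda i: (atoms[i].name, i))
    bridge = atoms[bridge_idx]

    s_idx = [i for i, e in enumerate(elements) if e == "S"]
    if not s_idx:
        raise IncompleteLigandError(
            f"{ligand.structure_id}: no sulfur atom; the mast must end in a thiol"
        )
    mast_set = _connected_component(s_idx[0], adjacency, blocked=bridge_idx)
    flag_set = set(range(len(atoms))) - mast_set - {bridge_idx}
    if not flag_set:
        raise IncompleteLigandError(
            f"{ligand.structure_id}: nothing on the flag side of the bridge"
        )
    # the flag side must be one connected piece containing the adenine
    flag_seed = next(iter(flag_set))
    flag_component = _connected_component(flag_seed, adjacency, blocked=bridge_idx)
    if flag_component != flag_set:
        raise IncompleteLigandError(
            f"{ligand.structure_id}: ligand is not two connected halves about "
            "the pyrophosphate bridge"
        )
    if not any(elements[i] == "N" for i in flag_set):
        raise IncompleteLigandError(
            f"{ligand.structure_id}: flag side has no nitrogen atoms; "
            "adenine ring appears to be missing"
        )

    mast = [atoms[i] for i in sorted(mast_set)]
    flag = [atoms[i] for i in sorted(flag_set)]
    axis = fit_mast_axis(mast, bridge)
    return CoASplit(flag=flag, mast=mast, bridge=bridge, axis=axis)


def fit_mast_axis(mast: list, anchor_atom: AtomRecord) -> MastAxis:
    """Principal axis of the mast atoms, anchored at the bridge.

    The direction is the first principal component of the mast heavy-atom
    coordinates, sign-oriented from the anchor toward the terminal thiol
    sulfur (or, absent a sulfur, toward the atom farthest from the anchor).
    """
    coords = np.array([a.xyz for a in mast], dtype=float)
    if coords.shape[0] < 2:
        raise DegenerateGeometryError("mast needs at least two atoms to define an axis")
    centered = coords - coords.mean(axis=0)
    if float(np.max(np.abs(centered))) < 1e-9:
        raise DegenerateGeometryError("all mast atoms coincident; axis undefined")
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]

    anchor = np.asarray(anchor_atom.xyz, dtype=float)
    s_atoms = [a for a in mast if a.element.upper() == "S"]
    target = s_atoms[0].xyz if s_atoms else coords[np.argmax(
        np.linalg.norm(coords - anchor, axis=1)
    )]
    if np.dot(direction, np.asarray(target) - anchor) < 0:
        direction = -direction
    return MastAxis(anchor=anchor, direction=direction)


def rotate_flag(split: CoASplit, theta: float) -> np.ndarray:
    """Flag coordinates after rigid rotation by ``theta`` degrees about the
    mast axis (mast and bridge stay put)."""
    if not np.isfinite(theta):
        raise ParameterError(f"rotation angle must be finite, got {theta!r}")
    rot = Rotation.from_rotvec(np.deg2rad(theta) * split.axis.direction)
    rel = split.flag_coords - split.axis.anchor
    return rot.apply(rel) + split.axis.anchor


def generate_conformers(split: CoASplit, step: float = 1.0) -> ConformerSet:
    """Exhaustive sweep of the flag about the mast: frames at
    0, step, 2·step, …, 360−step degrees (frame 0 = crystallographic pose).

    ``step`` must divide 360 exactly so the sweep tiles the circle.
    """
    if not (0 < step <= 360):
        raise ParameterError(f"step must be in (0, 360], got {step}")
    n = 360.0 / step
    if abs(n - round(n)) > 1e-9:
        raise ParameterError(f"step {step} does not divide 360 evenly")
    n = int(round(n))
    angles = np.arange(n) * step
    rot = Rotation.from_rotvec(
        np.deg2rad(angles)[:, None] * split.axis.direction[None, :]
    )
    rel = split.flag_coords - split.axis.anchor
    frames = np.einsum("nij,aj->nai", rot.as_matrix(), rel) + split.axis.anchor
    return ConformerSet(angles=angles, flag_coords=frames, split=split)


def measure_arm_length(mast: list | np.ndarray) -> float:
    """End-to-end extent of the mast: maximum pairwise heavy-atom distance
    (Å).  Crystal structures of CoA-bound adenylate-forming enzymes put
    this around 15–16 Å for an extended 4'-PPant arm."""
    coords = (
        np.asarray(mast, dtype=float)
        if isinstance(mast, np.ndarray)
        else np.array([a.xyz for a in mast], dtype=float)
    )
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ParameterError("mast must contain at least one atom")
    if coords.shape[0] == 1:
        return 0.0
    return float(pdist(coords).max())
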