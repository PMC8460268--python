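"""Van der Waals clash counting, ranked clash scoring, and the
short-contact census of the canonical CoA pocket.

Definitions
-----------
overlap
    ``r_i + r_j − d`` for two atoms with van der Waals radii r and
    centre distance d; positive means interpenetration.
clash
    overlap strictly greater than the threshold (default 0.25 Å),
    evaluated between the protein selection (main-chain N, CA, C, O plus
    CB) and the atoms of the rotated flag only — the mast and the bridge
    pivot are excluded.
clash count
    the number of *distinct protein atoms* in clash with at least one
    flag atom at a given rotation angle (pair-level detail is kept in the
    contact list).
ranked score
    a step function of the clash count: ≥30 → 3, ≥10 → 2, ≥2 → 1, else 0.
short contact
    a protein/ligand atom pair at distance strictly below the census
    cutoff (default 2.5 Å), evaluated against the whole ligand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmptySelectionError, ParameterError, UnknownElementError
from .structure_io import AtomRecord

#: Overlap above which a contact is a clash (Å).
DEFAULT_CLASH_THRESHOLD = 0.25
#: Distance below which a contact enters the short-contact census (Å).
DEFAULT_CENSUS_CUTOFF = 2.5
#: Ranked-score breakpoints on the clash count.
SCORE_BREAKPOINTS = (2, 10, 30)

_CLASH_ATOM_NAMES = frozenset({"N", "CA", "C", "O", "CB"})


class VdwRadiiTable:
    """Element → van der Waals radius (Å) mapping.

    The default is the Bondi-type set (C 1.70, N 1.55, O 1.52, P 1.80,
    S 1.80) shipped as an editable TSV; every report echoes the table used
    so runs with alternative radii are self-describing.
    """

    def __init__(self, radii: dict, source: str = "custom"):
        self.source = source
        self._radii = {}
        for el, r in radii.items():
            r = float(r)
            if not (0.5 < r < 3.0):
                raise ParameterError(
                    f"radius for {el} is {r} Å; plausible radii lie in (0.5, 3.0)"
                )
            self._radii[el.upper()] = r

    def radius(self, element: str) -> float:
        try:
            return self._radii[element.upper()]
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} absent from radii table ({self.source}); "
                f"known: {sorted(self._radii)}"
            ) from None

    def radii_for(self, atoms: list) -> np.ndarray:
        return np.array([self.radius(a.element) for a in atoms])

    def as_dict(self) -> dict:
        return dict(self._radii)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("element\tradius\n")
            for el in sorted(self._radii):
                fh.write(f"{el}\t{self._radii[el]:.2f}\n")

    @classmethod
    def from_tsv(cls, path, source: str | None = None) -> "VdwRadiiTable":
        df = pd.read_csv(path, sep="\t")
        if not {"element", "radius"} <= set(df.columns):
            raise ParameterError(f"{path}: radii TSV needs 'element' and 'radius' columns")
        return cls(
            dict(zip(df["element"].astype(str), df["radius"])),
            source=source or str(path),
        )

    @classmethod
    def default(cls) -> "VdwRadiiTable":
        ref = resources.files("coaclash").joinpath("data/vdw_radii.tsv")
        with resources.as_file(ref) as path:
            table = cls.from_tsv(path, source="bondi-default")
        return table


@dataclass(frozen=True)
class ContactRecord:
    """One protein-atom/ligand-atom pair under a distance cutoff."""

    protein_atom: AtomRecord
    ligand_atom: AtomRecord
    distance: float
    overlap: float


@dataclass
class ClashResult:
    """Clash census of one flag conformer against the protein selection."""

    angle: float
    clash_count: int
    score: int
    contacts: list = field(default_factory=list)


@dataclass
class ClashProfile:
    """Per-angle clash counts and scores for one (state × donor) pair —
    the machine-readable form of the rotation-angle score plot."""

    state: str
    faal_id: str
    donor_id: str
    results: list
    summary: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "angle": [r.angle for r in self.results],
                "clash_count": [r.clash_count for r in self.results],
                "score": [r.score for r in self.results],
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["angle"] = df["angle"].map(lambda x: f"{x:.1f}")
        df.to_csv(path, index=False)

    @property
    def mean_clash_count(self) -> float:
        return float(np.mean([r.clash_count for r in self.results]))

    @property
    def max_clash_count(self) -> int:
        return int(max(r.clash_count for r in self.results))


def vdw_overlap(a: AtomRecord, b: AtomRecord, radii: VdwRadiiTable) -> float:
    """r_a + r_b − d(a, b); positive = interpenetrating spheres."""
    d = float(np.linalg.norm(np.asarray(a.xyz) - np.asarray(b.xyz)))
    return radii.radius(a.element) + radii.radius(b.element) - d


def _check_clash_selection(protein_atoms: list) -> None:
    bad = {a.name for a in protein_atoms} - _CLASH_ATOM_NAMES
    if bad:
        raise ParameterError(
            f"clash counting is defined on main-chain + C-beta atoms "
            f"(N, CA, C, O, CB); selection also contains {sorted(bad)}"
        )


def count_clashes(
    protein_atoms: list,
    flag_atoms: list,
    flag_coords: np.ndarray | None = None,
    radii: VdwRadiiTable | None = None,
    threshold: float = DEFAULT_CLASH_THRESHOLD,
    angle: float = 0.0,
) -> ClashResult:
    """Count distinct protein atoms clashing with one flag conformer.

    ``flag_coords`` overrides the coordinates of ``flag_atoms`` (the sweep
    moves the flag without rewriting atom records).  A clash is overlap
    strictly greater than ``threshold``.
    """
    if not protein_atoms:
        raise EmptySelectionError("clash counting requires a non-empty protein selection")
    if not flag_atoms:
        return ClashResult(angle=angle, clash_count=0, score=0, contacts=[])
    _check_clash_selection(protein_atoms)
    radii = radii or VdwRadiiTable.default()

    p_xyz = np.array([a.xyz for a in protein_atoms], dtype=float)
    f_xyz = (
        np.asarray(flag_coords, dtype=float)
        if flag_coords is not None
        else np.array([a.xyz for a in flag_atoms], dtype=float)
    )
    if f_xyz.shape != (len(flag_atoms), 3):
        raise ParameterError(
            f"flag coordinate shape {f_xyz.shape} does not match {len(flag_atoms)} atoms"
        )
    rp = radii.radii_for(protein_atoms)
    rf = radii.radii_for(flag_atoms)
    d = cdist(p_xyz, f_xyz)
    overlap = rp[:, None] + rf[None, :] - d
    ii, jj = np.where(overlap > threshold)
    contacts = [
        ContactRecord(
            protein_atom=protein_atoms[i],
            ligand_atom=flag_atoms[j].moved_to(f_xyz[j]),
            distance=float(d[i, j]),
            overlap=float(overlap[i, j]),
        )
        for i, j in zip(ii, jj)
    ]
    clash_count = int(len(set(ii.tolist())))
    return ClashResult(
        angle=angle, clash_count=clash_count, score=score_clashes(clash_count),
        contacts=contacts,
    )


def score_clashes(clash_count: int) -> int:
    """Ranked score of a clash count: ≥30 → 3, ≥10 → 2, ≥2 → 1, <2 → 0."""
    if clash_count < 0:
        raise ParameterError(f"clash count must be non-negative, got {clash_count}")
    if clash_count >= SCORE_BREAKPOINTS[2]:
        return 3
    if clash_count >= SCORE_BREAKPOINTS[1]:
        return 2
    if clash_count >= SCORE_BREAKPOINTS[0]:
        return 1
    return 0


def clash_profile(
    state,
    conformers,
    protein_atoms: list,
    radii: VdwRadiiTable | None = None,
    threshold: float = DEFAULT_CLASH_THRESHOLD,
    donor_id: str = "",
    keep_contacts: bool = False,
) -> ClashProfile:
    """Sweep the clash count over every conformer angle.

    ``state`` is a StateModel (or anything with ``.state`` and
    ``.structure.structure_id``); the protein selection must already be
    restricted to main-chain + C-beta atoms.  Contact lists are dropped by
    default to keep 360-frame profiles light.
    """
    radii = radii or VdwRadiiTable.default()
    flag_atoms = conformers.split.flag
    results = []
    for angle, frame in zip(conformers.angles, conformers.flag_coords):
        res = count_clashes(
            protein_atoms, flag_atoms, flag_coords=frame, radii=radii,
            threshold=threshold, angle=float(angle),
        )
        if not keep_contacts:
            res.contacts = []
        results.append(res)
    counts = [r.clash_count for r in results]
    return ClashProfile(
        state=getattr(state, "state", "A"),
        faal_id=getattr(getattr(state, "structure", state), "structure_id", ""),
        donor_id=donor_id,
        results=results,
        summary={
            "mean_clash_count": float(np.mean(counts)),
            "max_clash_count": int(np.max(counts)),
            "n_angles": len(counts),
            "threshold": threshold,
            "radii_source": radii.source,
        },
    )


def short_contact_census(
    protein_atoms: list,
    ligand_atoms: list,
    cutoff: float = DEFAULT_CENSUS_CUTOFF,
    radii: VdwRadiiTable | None = None,
    conformation: str = "",
) -> list:
    """All protein/ligand atom pairs at distance strictly below ``cutoff``.

    Overlap is recorded when a radii table is given (informational); the
    census itself is purely distance-based.
    """
    if not protein_atoms or not ligand_atoms:
        raise EmptySelectionError("census requires non-empty protein and ligand sets")
    if cutoff < 0:
        raise ParameterError(f"cutoff must be non-negative, got {cutoff}")
    p_xyz = np.array([a.xyz for a in protein_atoms], dtype=float)
    l_xyz = np.array([a.xyz for a in ligand_atoms], dtype=float)
    d = cdist(p_xyz, l_xyz)
    ii, jj = np.where(d < cutoff)
    out = []
    for i, j in zip(ii, jj):
        if radii is not None:
            ov = radii.radius(protein_atoms[i].element) + radii.radius(
                ligand_atoms[j].element
            ) - float(d[i, j])
        else:
            ov = float("nan")
        out.append(
            ContactRecord(
                protein_atom=protein_atoms[i],
                ligand_atom=ligand_atoms[j],
                distance=float(d[i, j]),
                overlap=ov,
            )
        )
    return out


def distinct_protein_atoms(census: list) -> int:
    """Number of distinct protein atoms appearing in a census."""
    return len({c.protein_atom.key for c in census})


def distinct_protein_residues(census: list) -> int:
    """Number of distinct protein residues appearing in a census."""
    return len({(c.protein_atom.chain, c.protein_atom.res_seq) for c in census})


def census_union(censuses: list) -> list:
    """Merge censuses over several ligand conformations, keeping for each
    (protein atom, ligand atom) pair the closest observation."""
    best: dict = {}
    for census in censuses:
        for c in census:
            k = (c.protein_atom.key, c.ligand_atom.name)
            if k not in best or c.distance < best[k].distance:
                best[k] = c
    return sorted(best.values(), key=lambda c: c.distance)


def census_residue_table(census: list) -> pd.DataFrame:
    """Per-residue aggregation of a census: contact-atom counts and the
    closest approach, sorted by min_distance."""
    if not census:
        return pd.DataFrame(
            columns=["chain", "res_seq", "res_name", "n_contact_atoms", "min_distance"]
        )
    rows = pd.DataFrame(
        {
            "chain": [c.protein_atom.chain for c in census],
            "res_seq": [c.protein_atom.res_seq for c in census],
            "res_name": [c.protein_atom.res_name for c in census],
            "atom": [c.protein_atom.name for c in census],
            "distance": [c.distance for c in census],
        }
    )
    grouped = (
        rows.groupby(["chain", "res_seq", "res_name"], sort=False)
        .agg(
            n_contact_atoms=("atom", "nunique"),
            min_distance=("distance", "min"),
        )
        .reset_index()
        .sort_values("min_distance", kind="stable")
        .reset_index(drop=True)
    )
    return grouped


def census_to_tsv(census: list, path, conformation: str = "") -> None:
    """Write a census as TSV (protein atom id, ligand atom id, conformation
    label, distance) — the machine-readable short-contact table."""
    with open(path, "w") as fh:
        fh.write("chain\tres_seq\tres_name\tatom\tligand_atom\tconformation\tdistance\n")
        for c in sorted(census, key=lambda c: c.distance):
            p = c.protein_atom
            fh.write(
                f"{p.chain}\t{p.res_seq}\t{p.res_name}\t{p.name}\t"
                f"{c.ligand_atom.name}\t{conformation}\t{c.distance:.3f}\n"
            )
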