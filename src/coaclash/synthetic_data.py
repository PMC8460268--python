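"""Deterministic synthetic fixtures with analytically known answers.

Every stage of the pipeline is testable without downloading a structure:

* :func:`make_tunnel_fixture` — a cylindrical shell of pseudo-atoms with a
  clash wall planted at a known azimuth window, plus a toy CoA on the
  cylinder axis; the azimuth window where the rotating flag must clash is
  computed in closed form from circle geometry, independently of the
  production clash code.
* :func:`make_hinge_fixture` — a two-rigid-domain point cloud and a copy
  whose C-domain has been moved by a known hinge transform.
* :func:`make_toy_coa` — a miniature CoA with exact hand-set coordinates
  (collinear 15 Å mast, planar flag, a real pyrophosphate bridge) whose
  serialised form round-trips through the connectivity-based splitter.
* :func:`make_cavity_fixture` — hollow shells (sphere or capped cylinder)
  with analytic cavity volume, axis and extent.

Fixtures are pseudo-chemical: all-carbon linings with fake residue
numbering in valid ranges.  They exercise geometry, not chemistry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .coa_geometry import CoASplit, split_coa
from .errors import ParameterError
from .structure_io import AtomRecord, DomainDefinition, SelectionSpec, StructureModel
from .superposition import RigidTransform

#: vdW radii assumed by the closed-form clash-window arithmetic; kept in
#: sync with the default table but owned here so the oracle never calls
#: production code.
_FIXTURE_VDW = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}


def _protein_atom(serial, xyz, name="CA", res_name="ALA", res_seq=None, chain="A"):
    return AtomRecord(
        serial=serial, name=name, element="C", res_name=res_name,
        res_seq=res_seq if res_seq is not None else serial, chain=chain,
        xyz=np.asarray(xyz, dtype=float),
    )


# ---------------------------------------------------------------------------
# toy CoA

_TOY_MAST = [
    # (name, element) bottom-up along +z, 1.5 Å spacing, thiol on top
    ("P2A", "P"), ("O6A", "O"), ("CCP", "C"), ("CBP", "C"), ("CAP", "C"),
    ("C9P", "C"), ("N8P", "N"), ("C7P", "C"), ("C6P", "C"), ("C2P", "C"),
    ("S1P", "S"),
]
_TOY_FLAG = [
    ("P1A", "P"), ("O1A", "O"), ("O2A", "O"), ("C5B", "C"),
    ("C4B", "C"), ("C1B", "C"), ("N9A", "N"), ("C8A", "C"),
]


def toy_coa_model(
    flag_tip_radius: float = 4.0,
    origin=(0.0, 0.0, 0.0),
    chain: str = "A",
    res_seq: int = 900,
) -> StructureModel:
    """The toy CoA as a hetero-component StructureModel (code COA).

    Mast: 11 collinear atoms along +z at 1.5 Å spacing (extent 15.0 Å),
    thiol sulfur at the top.  Bridge: O3A 1.5 Å below the mast phosphate.
    Flag: 8 atoms in the z-plane 3.0 Å below the mast start, laid radially
    along +x from 1.0 Å out to ``flag_tip_radius``.
    """
    if flag_tip_radius <= 1.0:
        raise ParameterError("flag_tip_radius must exceed 1.0 Å")
    origin = np.asarray(origin, dtype=float)
    atoms = []
    serial = 1
    for i, (name, el) in enumerate(_TOY_MAST):
        atoms.append(
            AtomRecord(serial, name, el, "COA", res_seq, chain,
                       origin + (0.0, 0.0, 1.5 * i), hetero=True)
        )
        serial += 1
    atoms.append(
        AtomRecord(serial, "O3A", "O", "COA", res_seq, chain,
                   origin + (0.0, 0.0, -1.5), hetero=True)
    )
    serial += 1
    xs = np.linspace(1.0, flag_tip_radius, len(_TOY_FLAG))
    for x, (name, el) in zip(xs, _TOY_FLAG):
        atoms.append(
            AtomRecord(serial, name, el, "COA", res_seq, chain,
                       origin + (x, 0.0, -3.0), hetero=True)
        )
        serial += 1
    return StructureModel("toy_coa", atoms)


def make_toy_coa(flag_tip_radius: float = 4.0) -> CoASplit:
    """Toy CoA already partitioned into mast/flag/bridge (via the same
    connectivity-based splitter that real ligands go through, so the
    construction round-trips by definition)."""
    return split_coa(toy_coa_model(flag_tip_radius=flag_tip_radius))


# ---------------------------------------------------------------------------
# tunnel fixture


@dataclass
class TunnelFixture:
    """Cylindrical pseudo-protein with a planted clash wall + axial toy CoA."""

    structure: StructureModel          # lining + wall
    ligand_model: StructureModel       # toy CoA as HETATM records
    split: CoASplit
    expected_clash_window: list        # [(lo, hi)] degrees, may wrap at 360
    threshold: float
    params: dict = field(default_factory=dict)

    def combined_model(self) -> StructureModel:
        return StructureModel(
            self.structure.structure_id,
            list(self.structure.atoms) + list(self.ligand_model.atoms),
        )

    def n_domain(self) -> DomainDefinition:
        n = len(self.structure.atoms)
        return DomainDefinition(
            "n_domain",
            SelectionSpec(chain="A", residue_ranges=[[1, n]],
                          atom_classes=("main_chain", "c_beta")),
        )

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        self.combined_model().write_pdb(os.path.join(directory, "tunnel.pdb"))
        manifest = {
            "fixture": "tunnel",
            "expected_clash_window_deg": [
                [round(lo, 3), round(hi, 3)] for lo, hi in self.expected_clash_window
            ],
            "threshold": self.threshold,
            "params": self.params,
        }
        with open(os.path.join(directory, "tunnel_manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _merge_intervals(intervals: list) -> list:
    """Merge overlapping angular intervals given on the real line, then
    normalise into [0, 360) (a window crossing 0 is split in two)."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out = []
    for lo, hi in merged:
        if hi - lo >= 360.0:
            return [(0.0, 360.0)]
        lo_m, hi_m = lo % 360.0, hi % 360.0
        if lo_m <= hi_m:
            out.append((lo_m, hi_m))
        else:
            out.append((lo_m, 360.0))
            out.append((0.0, hi_m))
    return sorted(out)


def angle_in_windows(theta: float, windows: list) -> bool:
    t = theta % 360.0
    return any(lo <= t <= hi for lo, hi in windows)


def make_tunnel_fixture(
    R: float = 10.0,
    L: float = 24.0,
    wall_azimuth=(80.0, 100.0),
    r_wall: float = 6.0,
    r_flag: float = 6.0,
    atom_spacing: float = 1.5,
    seed: int = 0,
    threshold: float = 0.25,
    wall_step_deg: float = 1.0,
    with_wall: bool = True,
) -> TunnelFixture:
    """Build the tunnel fixture.

    The protein is a cylinder lining of pseudo-carbons at radius ``R``
    about the z axis plus a wall arc at radius ``r_wall`` spanning
    azimuth ``wall_azimuth`` in the flag plane.  The ligand is the toy CoA
    on the axis with its flag tip at radius ``r_flag`` and azimuth 0 at
    rotation angle 0.  ``expected_clash_window`` is the closed-form union,
    over flag atoms, of rotation angles where some wall atom overlaps the
    atom by more than ``threshold``:

        cos Δφ_i = (ρ_i² + r_wall² − d_i²) / (2 ρ_i r_wall),
        d_i = r_vdw(i) + r_vdw(C) − threshold,

    each atom contributing [w0 − Δφ_i, w1 + Δφ_i].
    """
    if not (r_wall + 1.7 < R):
        raise ParameterError("wall must sit inside the lining: need r_wall + 1.7 < R")
    if min(R, L, r_wall, r_flag, atom_spacing) <= 0:
        raise ParameterError("all tunnel dimensions must be positive")
    w0, w1 = float(wall_azimuth[0]), float(wall_azimuth[1])
    if w1 < w0:
        raise ParameterError("wall azimuth window must have w0 <= w1")

    z_tip = 6.0                       # flag plane
    z_lo = z_tip - 4.0                # cylinder foot
    # the toy flag sits 3.0 Å below its construction origin, so placing the
    # origin at z_tip + 3 puts the flag plane exactly at z_tip
    ligand = toy_coa_model(
        flag_tip_radius=r_flag, origin=(0.0, 0.0, z_tip + 3.0), res_seq=900
    )
    split = split_coa(ligand)

    # worst-case reach of any flag atom toward the lining must stay clear
    flag_radii = [np.hypot(a.xyz[0], a.xyz[1]) for a in split.flag]
    d_lining = [
        _FIXTURE_VDW[a.element.upper()] + _FIXTURE_VDW["C"] - threshold
        for a in split.flag
    ]
    if any(R - rho <= d for rho, d in zip(flag_radii, d_lining)):
        raise ParameterError("flag would clash with the lining; increase R")

    atoms = []
    serial = 1
    n_az = max(int(np.ceil(2 * np.pi * R / atom_spacing)), 3)
    for z in np.arange(z_lo, z_lo + L + 1e-9, atom_spacing):
        for k in range(n_az):
            phi = 2 * np.pi * k / n_az
            atoms.append(
                _protein_atom(serial, (R * np.cos(phi), R * np.sin(phi), z))
            )
            serial += 1
    if with_wall:
        wall_angles = np.arange(w0, w1 + 1e-9, wall_step_deg)
        for ang in wall_angles:
            phi = np.deg2rad(ang)
            atoms.append(
                _protein_atom(serial, (r_wall * np.cos(phi), r_wall * np.sin(phi), z_tip))
            )
            serial += 1
    structure = StructureModel("tunnel", atoms)

    windows = []
    for a in split.flag if with_wall else []:
        rho = float(np.hypot(a.xyz[0], a.xyz[1]))
        dz = float(a.xyz[2] - z_tip)
        alpha = float(np.degrees(np.arctan2(a.xyz[1], a.xyz[0])))
        d_max = _FIXTURE_VDW[a.element.upper()] + _FIXTURE_VDW["C"] - threshold
        reach_sq = d_max**2 - dz**2
        if reach_sq <= 0 or rho < 1e-9:
            continue
        c = (rho**2 + r_wall**2 - reach_sq) / (2 * rho * r_wall)
        if c >= 1.0:
            continue
        dphi = 180.0 if c <= -1.0 else float(np.degrees(np.arccos(c)))
        windows.append((w0 - alpha - dphi, w1 - alpha + dphi))
    expected = _merge_intervals(windows)

    rng = np.random.default_rng(seed)  # reserved for optional perturbations
    del rng
    return TunnelFixture(
        structure=structure,
        ligand_model=ligand,
        split=split,
        expected_clash_window=expected,
        threshold=threshold,
        params={
            "R": R, "L": L, "wall_azimuth": [w0, w1], "r_wall": r_wall,
            "r_flag": r_flag, "atom_spacing": atom_spacing, "seed": seed,
            "wall_step_deg": wall_step_deg, "z_tip": z_tip, "with_wall": with_wall,
        },
    )


# ---------------------------------------------------------------------------
# hinge fixture


@dataclass
class HingeFixture:
    """Two-domain cloud plus a copy with the C-domain moved by a known
    rigid hinge transform."""

    base: StructureModel
    moved: StructureModel
    truth: RigidTransform
    hinge_point: np.ndarray
    hinge_axis: np.ndarray
    n_def: DomainDefinition
    c_def: DomainDefinition


def make_hinge_fixture(
    n_atoms: int = 60, hinge_angle: float = 30.0, seed: int = 0
) -> HingeFixture:
    """Random two-domain Cα cloud; the moved copy has its C-domain rotated
    by ``hinge_angle`` degrees about a seeded random axis through the
    hinge point (12, 0, 0).  The truth transform maps base C-domain
    coordinates to moved C-domain coordinates exactly."""
    if n_atoms < 8:
        raise ParameterError("hinge fixture needs at least 8 atoms")
    rng = np.random.default_rng(seed)
    n1 = n_atoms // 2
    n2 = n_atoms - n1
    n_xyz = rng.uniform(-8, 8, size=(n1, 3))
    c_xyz = rng.uniform(-8, 8, size=(n2, 3)) + np.array([20.0, 0.0, 0.0])

    hinge_point = np.array([12.0, 0.0, 0.0])
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(np.deg2rad(hinge_angle) * axis).as_matrix()
    t = hinge_point - R @ hinge_point
    truth = RigidTransform(R, t)

    def build(c_coords):
        atoms = []
        for i, x in enumerate(n_xyz):
            atoms.append(_protein_atom(i + 1, x, res_seq=i + 1))
        for i, x in enumerate(c_coords):
            atoms.append(_protein_atom(n1 + i + 1, x, res_seq=201 + i))
        return atoms

    base = StructureModel("hinge_base", build(c_xyz))
    moved = StructureModel("hinge_moved", build(truth.apply(c_xyz)))
    n_def = DomainDefinition(
        "n_domain", SelectionSpec("A", [[1, n1]], ("main_chain", "c_beta"))
    )
    c_def = DomainDefinition(
        "c_domain", SelectionSpec("A", [[201, 200 + n2]], ("main_chain", "c_beta"))
    )
    return HingeFixture(base, moved, truth, hinge_point, axis, n_def, c_def)


# ---------------------------------------------------------------------------
# cavity fixtures


@dataclass
class CavityFixture:
    """Hollow atom shell with analytically known cavity truth."""

    structure: StructureModel
    shape: str
    truth: dict
    params: dict = field(default_factory=dict)


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return radius * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def make_cavity_fixture(
    shape: str,
    inner_radius: float = 6.0,
    length: float = 18.0,
    lining_spacing: float = 1.2,
    seed: int = 0,
) -> CavityFixture:
    """Hollow shell fixtures for cavity detection.

    ``sphere``: atom centres on a Fibonacci lattice at
    inner_radius + r_C(1.7 Å) so the vdW inner surface sits at
    ``inner_radius``; truth volume (4/3)π·r³.

    ``cylinder``: a capped channel of inner radius ``inner_radius`` and
    length ``length`` along +z (cavity z ∈ [0, length]); truth extent =
    length, truth axis = (0, 0, 1).
    """
    if min(inner_radius, lining_spacing) <= 0:
        raise ParameterError("sizes must be positive")
    r_c = 1.7
    atoms = []
    serial = 1
    if shape == "sphere":
        R_shell = inner_radius + r_c
        n = int(np.ceil(4 * np.pi * R_shell**2 / (0.75 * lining_spacing**2)))
        for xyz in _fibonacci_sphere(n, R_shell):
            atoms.append(_protein_atom(serial, xyz))
            serial += 1
        truth = {
            "volume": 4.0 / 3.0 * np.pi * inner_radius**3,
            "axis": None,
            "extent": 2 * inner_radius,
        }
        params = {"inner_radius": inner_radius, "lining_spacing": lining_spacing}
    elif shape == "cylinder":
        if length <= 0:
            raise ParameterError("cylinder length must be positive")
        R_shell = inner_radius + r_c
        n_az = max(int(np.ceil(2 * np.pi * R_shell / lining_spacing)), 3)
        for z in np.arange(0.0, length + 1e-9, lining_spacing):
            for k in range(n_az):
                phi = 2 * np.pi * k / n_az
                atoms.append(
                    _protein_atom(
                        serial, (R_shell * np.cos(phi), R_shell * np.sin(phi), z)
                    )
                )
                serial += 1
        for z_cap in (-r_c, length + r_c):
            for rr in np.arange(0.0, R_shell + 1e-9, lining_spacing):
                n_ring = max(int(np.ceil(2 * np.pi * max(rr, 0.5) / lining_spacing)), 1)
                for k in range(n_ring):
                    phi = 2 * np.pi * k / n_ring
                    atoms.append(
                        _protein_atom(
                            serial, (rr * np.cos(phi), rr * np.sin(phi), z_cap)
                        )
                    )
                    serial += 1
        truth = {
            "volume": np.pi * inner_radius**2 * length,
            "axis": (0.0, 0.0, 1.0),
            "extent": length,
        }
        params = {
            "inner_radius": inner_radius, "length": length,
            "lining_spacing": lining_spacing,
        }
    else:
        raise ParameterError(f"unknown cavity shape {shape!r}; use sphere or cylinder")
    params["seed"] = seed
    return CavityFixture(
        structure=StructureModel(f"cavity_{shape}", atoms),
        shape=shape,
        truth=truth,
        params=params,
    )


def make_solid_block(side: float = 12.0, spacing: float = 1.5) -> StructureModel:
    """A close-packed solid block of pseudo-atoms: contains no cavity."""
    atoms = []
    serial = 1
    rng = np.arange(0.0, side + 1e-9, spacing)
    for x in rng:
        for y in rng:
            for z in rng:
                atoms.append(_protein_atom(serial, (x, y, z)))
                serial += 1
    return StructureModel("solid_block", atoms)


def write_fixture_set(directory, seed: int = 0) -> dict:
    """Emit the standard fixture set plus a manifest of truth values."""
    import os

    os.makedirs(directory, exist_ok=True)
    tunnel = make_tunnel_fixture(seed=seed)
    tunnel.write(directory)
    toy = toy_coa_model()
    toy.write_pdb(os.path.join(directory, "toy_coa.pdb"))
    hinge = make_hinge_fixture(seed=seed)
    hinge.base.write_pdb(os.path.join(directory, "hinge_base.pdb"))
    hinge.moved.write_pdb(os.path.join(directory, "hinge_moved.pdb"))
    manifest = {
        "seed": seed,
        "tunnel": {
            "expected_clash_window_deg": [
                [round(a, 3), round(b, 3)] for a, b in tunnel.expected_clash_window
            ],
            "threshold": tunnel.threshold,
        },
        "hinge": {
            "hinge_point": hinge.hinge_point.tolist(),
            "hinge_axis": [round(x, 6) for x in hinge.hinge_axis],
        },
        "cavities": {},
    }
    for shape in ("sphere", "cylinder"):
        fx = make_cavity_fixture(shape, seed=seed)
        fx.structure.write_pdb(os.path.join(directory, f"cavity_{shape}.pdb"))
        manifest["cavities"][shape] = {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in fx.truth.items()
        }
    path = os.path.join(directory, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
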