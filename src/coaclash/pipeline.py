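"""Run-level orchestration: one declarative config drives the full
rejection scan (transplant × state × sweep × clash score), the
short-contact census, and the pocket survey.

Configuration is YAML.  A minimal scan config::

    structures:
      tunnel:
        path: fixtures/tunnel.pdb
        chain: A
        n_domain: [[1, 735]]
        ligand: COA
    targets: [tunnel]
    donors: [tunnel]
    states: [A]
    step: 1.0
    out_dir: out

All outputs are plain text (CSV/TSV/JSON) with fixed numeric formatting
(3 decimals for Å, 1 for degrees) so re-running a config is bit-identical.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import contact_analysis as ca
from . import pocket_mapping as pm
from .coa_geometry import generate_conformers, measure_arm_length, split_coa
from .errors import CoaClashError, ConfigError
from .structure_io import (
    DomainDefinition,
    SelectionSpec,
    StructureModel,
    check_domains_disjoint,
    extract_ligand,
    parse_structure,
    select_atoms,
)
from .superposition import CorrespondenceMap, build_state_model, transplant_ligand

logger = logging.getLogger(__name__)


@dataclass
class StructureEntry:
    """One structure in the run: path, protomer, domains, ligand code."""

    id: str
    path: str
    chain: str = "A"
    dialect: str = "auto"
    n_domain: list | None = None
    c_domain: list | None = None
    ligand: str | None = None
    pairs: dict = field(default_factory=dict)  # domain name -> TSV path

    def domain(self, name: str) -> DomainDefinition:
        ranges = {"n_domain": self.n_domain, "c_domain": self.c_domain}.get(name)
        if not ranges:
            raise ConfigError(f"structure {self.id}: {name} residue ranges not configured")
        return DomainDefinition(
            name,
            SelectionSpec(chain=self.chain, residue_ranges=[list(r) for r in ranges],
                          atom_classes=("all_heavy",)),
        )

    def clash_selection(self) -> SelectionSpec:
        """Main-chain + Cβ over every configured domain range."""
        ranges = [list(r) for r in (self.n_domain or [])] + [
            list(r) for r in (self.c_domain or [])
        ]
        if not ranges:
            raise ConfigError(f"structure {self.id}: no domain ranges configured")
        return SelectionSpec(chain=self.chain, residue_ranges=ranges,
                             atom_classes=("main_chain", "c_beta"))


@dataclass
class RunConfig:
    structures: dict
    targets: list
    donors: list
    states: list = field(default_factory=lambda: ["A", "T"])
    t_state_template: str | None = None
    correspondence: str = "sequence_alignment"
    overlap_threshold: float = ca.DEFAULT_CLASH_THRESHOLD
    census_cutoff: float = ca.DEFAULT_CENSUS_CUTOFF
    step: float = 1.0
    radii_table: str | None = None
    pocket: dict = field(default_factory=dict)
    canonical_donor: str | None = None
    out_dir: str = "out"
    seed: int = 0

    def validate(self) -> None:
        for ids, label in ((self.targets, "targets"), (self.donors, "donors")):
            for sid in ids:
                if sid not in self.structures:
                    raise ConfigError(f"{label} entry {sid!r} has no structures entry")
        if self.overlap_threshold <= 0 or self.census_cutoff <= 0:
            raise ConfigError("thresholds must be positive")
        n = 360.0 / self.step
        if self.step <= 0 or abs(n - round(n)) > 1e-9:
            raise ConfigError(f"angular step {self.step} must divide 360")
        for st in self.states:
            if st not in ("A", "T"):
                raise ConfigError(f"unknown state {st!r}")
        if "T" in self.states and not self.t_state_template:
            raise ConfigError("states include T but t_state_template is not set")

    def radii(self) -> ca.VdwRadiiTable:
        if self.radii_table:
            return ca.VdwRadiiTable.from_tsv(self.radii_table)
        return ca.VdwRadiiTable.default()

    def echo(self) -> dict:
        return {
            "targets": list(self.targets),
            "donors": list(self.donors),
            "states": list(self.states),
            "t_state_template": self.t_state_template,
            "correspondence": self.correspondence,
            "overlap_threshold": self.overlap_threshold,
            "census_cutoff": self.census_cutoff,
            "step": self.step,
            "radii": self.radii().as_dict(),
            "radii_source": self.radii().source,
            "pocket": dict(self.pocket),
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict) or "structures" not in raw:
        raise ConfigError(f"{path}: config must be a mapping with a 'structures' block")
    base = os.path.dirname(os.path.abspath(path))
    structures = {}
    for sid, entry in raw["structures"].items():
        p = entry.get("path")
        if not p:
            raise ConfigError(f"structure {sid}: missing path")
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        structures[sid] = StructureEntry(
            id=sid,
            path=p,
            chain=str(entry.get("chain", "A")),
            dialect=entry.get("dialect", "auto"),
            n_domain=entry.get("n_domain"),
            c_domain=entry.get("c_domain"),
            ligand=entry.get("ligand"),
            pairs=entry.get("pairs", {}) or {},
        )
    cfg = RunConfig(
        structures=structures,
        targets=list(raw.get("targets", [])),
        donors=list(raw.get("donors", [])),
        states=list(raw.get("states", ["A", "T"])),
        t_state_template=raw.get("t_state_template"),
        correspondence=raw.get("correspondence", "sequence_alignment"),
        overlap_threshold=float(raw.get("overlap_threshold", ca.DEFAULT_CLASH_THRESHOLD)),
        census_cutoff=float(raw.get("census_cutoff", ca.DEFAULT_CENSUS_CUTOFF)),
        step=float(raw.get("step", 1.0)),
        radii_table=raw.get("radii_table"),
        pocket=raw.get("pocket", {}) or {},
        canonical_donor=raw.get("canonical_donor"),
        out_dir=raw.get("out_dir", "out"),
        seed=int(raw.get("seed", 0)),
    )
    cfg.validate()
    return cfg


@dataclass
class RunReport:
    """What a subcommand produced: file paths plus the in-memory summary."""

    summary: dict
    files: list = field(default_factory=list)
    failures: list = field(default_factory=list)

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary, fh, indent=2, sort_keys=True)
        self.files.append(str(path))


class _Loader:
    """Parse-once cache of the run's structures."""

    def __init__(self, config: RunConfig):
        self.config = config
        self._cache: dict = {}

    def __call__(self, sid: str) -> StructureModel:
        if sid not in self._cache:
            entry = self.config.structures[sid]
            st = parse_structure(entry.path, entry.dialect)
            st.structure_id = sid
            self._cache[sid] = st
        return self._cache[sid]


def _config_pairs(entry: StructureEntry, domain: str):
    path = entry.pairs.get(domain)
    if path:
        return CorrespondenceMap.from_tsv(path).pairs
    return None


def _transplanted_split(config, load, donor_id, target_id, target_structure=None):
    """Transplant the donor's CoA into the target frame and split it."""
    donor_entry = config.structures[donor_id]
    target_entry = config.structures[target_id]
    donor = load(donor_id)
    target = target_structure if target_structure is not None else load(target_id)
    code = donor_entry.ligand or "COA"
    if donor_id == target_id and target_structure is None:
        ligand = extract_ligand(donor, code)
    else:
        pairs = _config_pairs(donor_entry, "n_domain")
        mode = "config" if pairs else config.correspondence
        ligand = transplant_ligand(
            donor, target, target_entry.domain("n_domain"), code,
            mode=mode, pairs=pairs, donor_domain=donor_entry.domain("n_domain"),
        )
    return ligand, split_coa(ligand)


def _build_states(config: RunConfig, load, target_id: str) -> list:
    entry = config.structures[target_id]
    faal = load(target_id)
    out = []
    for state in config.states:
        if state == "A":
            out.append(build_state_model(faal, faal, "A", None, None))
        else:
            template = load(config.t_state_template)
            template_entry = config.structures[config.t_state_template]
            n_def, c_def = entry.domain("n_domain"), entry.domain("c_domain")
            check_domains_disjoint(n_def, c_def)
            out.append(
                build_state_model(
                    faal, template, "T", n_def, c_def,
                    template_n_def=template_entry.domain("n_domain"),
                    template_c_def=template_entry.domain("c_domain"),
                    mode="config" if _config_pairs(entry, "c_domain") else config.correspondence,
                    n_pairs=_config_pairs(template_entry, "n_domain"),
                    c_pairs=_config_pairs(entry, "c_domain"),
                )
            )
    return out


def run_rejection_scan(config: RunConfig) -> RunReport:
    """Transplant every donor CoA into every target state, sweep the flag,
    and score clashes: one profile CSV per (target × state × donor) plus a
    summary with per-configuration and grand mean clash counts."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    radii = config.radii()
    load = _Loader(config)
    profiles = []
    failures = []
    files = []
    per_config = {}
    for target_id in config.targets:
        entry = config.structures[target_id]
        try:
            states = _build_states(config, load, target_id)
        except CoaClashError as exc:
            logger.warning("target %s: state construction failed: %s", target_id, exc)
            failures.append({"target": target_id, "error": str(exc)})
            continue
        for state in states:
            selection = select_atoms(state.structure, entry.clash_selection())
            for donor_id in config.donors:
                triple = (target_id, state.state, donor_id)
                try:
                    _, split = _transplanted_split(
                        config, load, donor_id, target_id, target_structure=state.structure
                    )
                    conformers = generate_conformers(split, config.step)
                    profile = ca.clash_profile(
                        state, conformers, selection, radii=radii,
                        threshold=config.overlap_threshold, donor_id=donor_id,
                    )
                except CoaClashError as exc:
                    logger.warning("scan %s failed: %s", triple, exc)
                    failures.append({"triple": list(triple), "error": str(exc)})
                    continue
                profiles.append(profile)
                path = os.path.join(
                    config.out_dir, f"scan_{target_id}_{state.state}_{donor_id}.csv"
                )
                profile.to_csv(path)
                files.append(path)
                per_config[f"{target_id}/{state.state}/{donor_id}"] = {
                    "mean_clash_count": round(profile.mean_clash_count, 3),
                    "max_clash_count": profile.max_clash_count,
                }
    if not profiles:
        raise CoaClashError(f"rejection scan produced no profiles; failures: {failures}")
    all_counts = np.concatenate(
        [[r.clash_count for r in p.results] for p in profiles]
    )
    summary = {
        "config": config.echo(),
        "per_configuration": per_config,
        "grand_mean_clash_count": round(float(all_counts.mean()), 3),
        "grand_max_clash_count": int(all_counts.max()),
        "n_profiles": len(profiles),
        "n_angles_per_profile": int(360.0 / config.step),
        "failures": failures,
    }
    report = RunReport(summary=summary, files=files, failures=failures)
    report.write_summary(os.path.join(config.out_dir, "scan_summary.json"))
    report.profiles = profiles  # type: ignore[attr-defined]
    return report


def run_census(config: RunConfig) -> RunReport:
    """Short-contact census (< cutoff) of each target's N-domain against
    every transplanted CoA conformation, per donor and in union mode."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    radii = config.radii()
    load = _Loader(config)
    failures = []
    files = []
    results = {}
    for target_id in config.targets:
        entry = config.structures[target_id]
        target = load(target_id)
        protein = select_atoms(target, entry.domain("n_domain").selection)
        protein = [a for a in protein if not a.hetero]
        per_donor = {}
        censuses = []
        for donor_id in config.donors:
            try:
                ligand, _ = _transplanted_split(config, load, donor_id, target_id)
                census = ca.short_contact_census(
                    protein, list(ligand.atoms), cutoff=config.census_cutoff,
                    radii=radii, conformation=donor_id,
                )
            except CoaClashError as exc:
                logger.warning("census (%s, %s) failed: %s", target_id, donor_id, exc)
                failures.append({"pair": [target_id, donor_id], "error": str(exc)})
                continue
            censuses.append(census)
            path = os.path.join(config.out_dir, f"census_{target_id}_{donor_id}.tsv")
            ca.census_to_tsv(census, path, conformation=donor_id)
            files.append(path)
            per_donor[donor_id] = {
                "n_contacts": len(census),
                "distinct_protein_atoms": ca.distinct_protein_atoms(census),
                "distinct_protein_residues": ca.distinct_protein_residues(census),
            }
        if not censuses:
            continue
        union = ca.census_union(censuses)
        upath = os.path.join(config.out_dir, f"census_{target_id}_union.tsv")
        ca.census_to_tsv(union, upath, conformation="union")
        files.append(upath)
        results[target_id] = {
            "per_donor": per_donor,
            "union": {
                "n_contacts": len(union),
                "distinct_protein_atoms": ca.distinct_protein_atoms(union),
                "distinct_protein_residues": ca.distinct_protein_residues(union),
            },
        }
    if not results:
        raise CoaClashError(f"census produced no results; failures: {failures}")
    summary = {"config": config.echo(), "census": results, "failures": failures}
    report = RunReport(summary=summary, files=files, failures=failures)
    report.write_summary(os.path.join(config.out_dir, "census_summary.json"))
    return report


def run_pockets(config: RunConfig) -> RunReport:
    """Detect N-domain cavities per target, measure extent and axis, and
    report each pocket's angle to the canonical CoA axis."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    radii = config.radii()
    load = _Loader(config)
    pocket_params = {
        "spacing": float(config.pocket.get("spacing", pm.DEFAULT_SPACING)),
        "probe": float(config.pocket.get("probe", pm.DEFAULT_PROBE)),
        "burial_fraction": float(
            config.pocket.get("burial_fraction", pm.DEFAULT_BURIAL_FRACTION)
        ),
        "min_volume": float(config.pocket.get("min_volume", pm.DEFAULT_MIN_VOLUME)),
    }
    failures = []
    files = []
    results = {}
    for target_id in config.targets:
        entry = config.structures[target_id]
        target = load(target_id)
        protein = [
            a
            for a in select_atoms(target, entry.domain("n_domain").selection)
            if not a.hetero
        ]
        try:
            pockets = pm.detect_cavities(protein, radii=radii, **pocket_params)
        except CoaClashError as exc:
            logger.warning("pockets on %s failed: %s", target_id, exc)
            failures.append({"target": target_id, "error": str(exc)})
            continue
        canonical = None
        donor_id = config.canonical_donor or (config.donors[0] if config.donors else None)
        if donor_id:
            try:
                _, split = _transplanted_split(config, load, donor_id, target_id)
                canonical = pm.canonical_pocket_axis(None, split)
            except CoaClashError as exc:
                logger.warning(
                    "canonical axis for %s via %s failed: %s", target_id, donor_id, exc
                )
        entries = []
        for i, p in enumerate(pockets):
            d = p.summary()
            if canonical is not None:
                d["angle_to_canonical_deg"] = round(
                    pm.interpocket_angle(p.principal_axis, canonical.direction), 1
                )
            entries.append(d)
            if i == 0:
                ppath = os.path.join(config.out_dir, f"pocket_{target_id}_top.pdb")
                p.to_pseudoatom_pdb(ppath)
                files.append(ppath)
        results[target_id] = {
            "n_pockets": len(pockets),
            "pockets": entries,
            "canonical_donor": donor_id,
        }
    if not results:
        raise CoaClashError(f"pocket run produced no results; failures: {failures}")
    summary = {
        "config": config.echo(),
        "pocket_params": pocket_params,
        "pockets": results,
        "failures": failures,
    }
    report = RunReport(summary=summary, files=files, failures=failures)
    report.write_summary(os.path.join(config.out_dir, "pocket_summary.json"))
    return report


def merge_reports(paths: list, out_path) -> dict:
    """Merge several summary JSONs into one report document."""
    merged = {}
    for p in paths:
        with open(p) as fh:
            merged[os.path.basename(str(p))] = json.load(fh)
    with open(out_path, "w") as fh:
        json.dump(merged, fh, indent=2, sort_keys=True)
    return merged
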