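"""Orchestration of the full domain-motion analysis from a config file.

One config describes a set of coordinate files, each tagged with a
nucleotide-state label, the two rigid-body domain definitions, and which
state is the reference.  ``run_analysis`` then produces the standard report
bundle:

* pairwise domain RMSD matrices (direct fits, and anchored fits that
  expose relative domain motion),
* a rotation descriptor (kappa, axis, screw translation) for every state
  against the reference,
* an inter-subunit distance-change table when dimers are available,
* named active-site distances from measurement recipes,
* optionally, crystal-contact interface areas and the fractional position
  of the dimer dyad.

All floating output is written at fixed precision so re-running on the
same inputs reproduces byte-identical files.
"""

from __future__ import annotations

import json
import time
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .dimer_geometry import (
    DEFAULT_RESIDUE_PANEL,
    Dimer,
    build_dimer,
    intersubunit_distance_table,
    molecular_dyad,
)
from .errors import ConfigError, GyrmotionError
from .packing_analysis import (
    buried_interface_area,
    locate_local_dyad_fractional,
    symmetry_mates,
)
from .rotation_analysis import relative_domain_rotation
from .site_geometry import AtomSpec, atom_distance
from .structure_io import (
    ATPASE_DOMAIN,
    TRANSDUCER_DOMAIN,
    DomainDefinition,
    Structure,
    read_structure,
    select,
)
from .superpose import pairwise_domain_rmsd

__all__ = ["StructureEntry", "AnalysisConfig", "load_config", "run_analysis"]

KNOWN_STATES = ("AMPPNP", "ADP.BeF3", "ADP.Pi", "ADP", "other")


@dataclass
class StructureEntry:
    id: str
    path: str
    state: str
    structure: Structure | None = None

    def load(self) -> Structure:
        if self.structure is None:
            self.structure = read_structure(self.path)
            self.structure.id = self.id
        return self.structure


@dataclass
class AnalysisConfig:
    structures: list[StructureEntry]
    domains: list[DomainDefinition] = field(
        default_factory=lambda: [ATPASE_DOMAIN, TRANSDUCER_DOMAIN]
    )
    anchor: str = "atpase"
    mobile: str = "transducer"
    reference_state: str = "AMPPNP"
    residue_panel: tuple[str, ...] = DEFAULT_RESIDUE_PANEL
    dimer_chains: tuple[str, str] | None = None  # build dimers from two chains
    dimer_operator: int | None = None  # or from a crystallographic 2-fold
    measurements: list[dict] = field(default_factory=list)
    packing: bool = False
    contact_cutoff: float = 5.0
    output_dir: str = "gyrmotion_out"

    def __post_init__(self) -> None:
        states = [e.state for e in self.structures]
        if len(set(states)) != len(states):
            raise ConfigError("state labels must be unique")
        if self.reference_state not in states:
            raise ConfigError(f"reference state {self.reference_state!r} not among {states}")
        names = {d.name for d in self.domains}
        for role, name in (("anchor", self.anchor), ("mobile", self.mobile)):
            if name not in names:
                raise ConfigError(f"{role} domain {name!r} not defined")

    def domain(self, name: str) -> DomainDefinition:
        return next(d for d in self.domains if d.name == name)


def load_config(path: str | Path) -> AnalysisConfig:
    """Parse a YAML analysis configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "structures" not in raw:
        raise ConfigError("config must be a mapping with a 'structures' list")
    base = Path(path).parent
    entries = []
    for item in raw["structures"]:
        p = Path(item["path"])
        if not p.is_absolute():
            p = base / p
        entries.append(StructureEntry(id=item["id"], path=str(p), state=item["state"]))
    domains = []
    for d in raw.get("domains", []):
        domains.append(
            DomainDefinition(
                name=d["name"],
                residue_ranges=tuple(tuple(r) for r in d["ranges"]),
                chain_id=d.get("chain"),
                atom_names=frozenset(d.get("atom_names", ["CA"])),
            )
        )
    kwargs = dict(structures=entries)
    if domains:
        kwargs["domains"] = domains
    for key in ("anchor", "mobile", "reference_state", "packing", "contact_cutoff",
                "output_dir", "measurements"):
        if key in raw:
            kwargs[key] = raw[key]
    if "residue_panel" in raw:
        kwargs["residue_panel"] = tuple(str(r) for r in raw["residue_panel"])
    dimer = raw.get("dimer") or {}
    if dimer.get("chains"):
        kwargs["dimer_chains"] = tuple(dimer["chains"])
    if "operator" in dimer:
        kwargs["dimer_operator"] = int(dimer["operator"])
    return AnalysisConfig(**kwargs)


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _build_dimer_for(entry: StructureEntry, config: AnalysisConfig) -> Dimer | None:
    s = entry.load()
    if config.dimer_chains is not None:
        return build_dimer(s, chains=config.dimer_chains)
    if config.dimer_operator is not None:
        return build_dimer(s, operator_index=config.dimer_operator)
    return None


def run_analysis(config: AnalysisConfig) -> dict:
    """Run every configured stage and write the report bundle.

    Returns the machine-readable summary (also written as summary.json).
    Raises the first stage error, tagged with the stage name.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"states": {}, "stages": []}

    def stage(name):
        def wrapper(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except GyrmotionError as exc:
                raise type(exc)(f"stage {name!r}: {exc}") from exc
            _log(f"[gyrmotion] stage {name}: {time.perf_counter() - t0:.2f}s")
            summary["stages"].append(name)
        return wrapper

    structures = [e.load() for e in config.structures]
    by_state = {e.state: e for e in config.structures}
    ref_entry = by_state[config.reference_state]
    anchor = config.domain(config.anchor)
    mobile = config.domain(config.mobile)

    @stage("superpose")
    def _():
        result = pairwise_domain_rmsd(structures, config.domains, anchored_on=anchor)
        result.to_csv(str(out_dir / "rmsd"))
        summary["rmsd_direct"] = {
            dom: df.round(3).to_dict() for dom, df in result.direct.items()
        }
        summary["rmsd_anchored"] = {
            dom: df.round(3).to_dict() for dom, df in result.anchored.items()
        }

    @stage("rotation")
    def _():
        rotations = {}
        for entry in config.structures:
            if entry.state == config.reference_state:
                continue
            desc = relative_domain_rotation(ref_entry.load(), entry.load(), anchor, mobile)
            rotations[entry.state] = desc.to_dict()
            summary["states"].setdefault(entry.state, {})["kappa_deg"] = round(
                desc.kappa_deg, 4
            )
            summary["states"][entry.state]["screw_translation_A"] = round(
                desc.screw_translation, 4
            )
        summary["rotations"] = rotations
        (out_dir / "rotations.json").write_text(json.dumps(rotations, indent=2) + "\n")

    dimers: dict[str, Dimer] = {}

    @stage("dimer-table")
    def _():
        if config.dimer_chains is None and config.dimer_operator is None:
            return
        for entry in config.structures:
            dimers[entry.state] = _build_dimer_for(entry, config)
        ref_dimer = dimers[config.reference_state]
        tables = {}
        for state, dim in dimers.items():
            if state == config.reference_state:
                continue
            df = intersubunit_distance_table(ref_dimer, dim, config.residue_panel)
            df.round(3).to_csv(out_dir / f"distance_table_{state.replace('.', '')}.csv",
                               index=False)
            tables[state] = {
                row["residue"]: round(row["delta"], 3)
                for _, row in df.iterrows()
                if row["present"]
            }
        summary["intersubunit_delta_A"] = tables

    @stage("site")
    def _():
        if not config.measurements:
            return
        site: dict[str, dict[str, float]] = {}
        for entry in config.structures:
            s = entry.load()
            vals = {}
            for recipe in config.measurements:
                a = AtomSpec(**recipe["a"])
                b = AtomSpec(**recipe["b"])
                try:
                    vals[recipe["name"]] = round(atom_distance(s, a, b), 3)
                except GyrmotionError:
                    vals[recipe["name"]] = None
            site[entry.state] = vals
        summary["site_distances_A"] = site
        (out_dir / "site.json").write_text(json.dumps(site, indent=2) + "\n")

    @stage("packing")
    def _():
        if not config.packing:
            return
        packing: dict[str, dict] = {}
        for entry in config.structures:
            s = entry.load()
            if s.symmetry_ops is None or s.cell is None:
                continue
            mates = symmetry_mates(s, contact_cutoff=config.contact_cutoff)
            rec: dict = {"n_contact_mates": len(mates)}
            if mates:
                protein = select(s, hetero=False)
                mate_protein = select(mates[0].structure, hetero=False)
                rec["closest_mate"] = {
                    "operator": mates[0].operator_index,
                    "translation": list(mates[0].lattice_translation),
                    "buried_area_A2": round(
                        buried_interface_area(protein, mate_protein), 1
                    ),
                }
            packing[entry.state] = rec
        if dimers:
            for state, dim in dimers.items():
                s = by_state[state].load()
                if s.cell is None:
                    continue
                try:
                    fd = locate_local_dyad_fractional(dim, s.cell)
                except GyrmotionError:
                    continue
                packing.setdefault(state, {})["dyad_fractional_x"] = round(fd.x, 4)
        summary["packing"] = packing
        (out_dir / "packing.json").write_text(
            json.dumps(_round_floats(packing), indent=2) + "\n"
        )

    (out_dir / "summary.json").write_text(
        json.dumps(_round_floats(summary), indent=2, sort_keys=True) + "\n"
    )
    return summary
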