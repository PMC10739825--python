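"""Built-in compound fixtures, the observation simulator, and format I/O.

Two fixture sets make the whole pipeline testable without an instrument:

* ``c12h10o2_isomers`` — the 18 commercially available constitutional isomers
  of C12H10O2 (nominal mass 186) spanning diols, acids, esters, an
  ortho-hydroxy aryl ketone pair, aryl ethers and methoxy carbaldehydes.
* ``validation_mix`` — ten structurally diverse compounds carrying up to
  three different O-functionalities each.

Each record freezes the structure SMILES (derived once from the published
IUPAC names) together with a hand-annotated functional-group truth row.

The simulator forward-predicts what a GC-MS run would observe for a
structure under a reagent panel: a molecular-ion mass shift, no change, or a
new smaller-mass peak from ester hydrolysis. It models molecular ions only —
no EI fragmentation — and supports full or per-site-Bernoulli partial
conversion plus Gaussian mass noise, all driven by a seeded generator.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .candidate_filter import CandidateRecord, FilterReport
from .chem_core import (
    ALKYL_KETONE,
    ARYL_ESTER,
    ORTHO_OH_ARYL_KETONE,
    FGProfile,
    Structure,
    parse_structure,
)
from .errors import FormatError, UnknownFixtureError
from .reaction_rules import (
    OutcomeKind,
    ReagentId,
    RetentionDirection,
    REAGENTS,
    RuleSet,
    reactive_sites,
    realize_product,
)
from .workflow import (
    DEFAULT_TOLERANCE,
    Observation,
    ObservationKind,
    ObservationSet,
)


@dataclass(frozen=True)
class FixtureRecord:
    index: int
    name: str
    smiles: str
    structure: Structure
    truth: FGProfile


@dataclass(frozen=True)
class FixtureSet:
    name: str
    records: tuple[FixtureRecord, ...]

    def __len__(self) -> int:
        return len(self.records)

    def get(self, index: int) -> FixtureRecord:
        for r in self.records:
            if r.index == index:
                return r
        raise KeyError(index)

    def as_candidates(self) -> list[CandidateRecord]:
        return [
            CandidateRecord(id=str(r.index), name=r.name, structure=r.structure)
            for r in self.records
        ]


def _p(**kw) -> dict:
    return kw


# (index, published name, SMILES, truth-profile kwargs)
_C12H10O2 = [
    (1, "biphenyl-2,2'-diol", "Oc1ccccc1-c1ccccc1O", _p(n_oh_phenolic=2)),
    (2, "naphthalen-1-yl acetic acid", "OC(=O)Cc1cccc2ccccc12", _p(n_cooh=1)),
    (3, "biphenyl-2,5-diol", "Oc1ccc(O)c(-c2ccccc2)c1", _p(n_oh_phenolic=2)),
    (4, "biphenyl-4,4'-diol", "Oc1ccc(-c2ccc(O)cc2)cc1", _p(n_oh_phenolic=2)),
    (5, "methyl naphthalene-1-carboxylate", "COC(=O)c1cccc2ccccc12", _p(n_ester=1)),
    (6, "1-(1-hydroxynaphthalen-2-yl) ethanone", "CC(=O)c1ccc2ccccc2c1O",
     _p(n_oh_phenolic=1, n_ketone=1,
        flags=frozenset({ORTHO_OH_ARYL_KETONE, ALKYL_KETONE}))),
    (7, "naphthalen-2-yl acetate", "CC(=O)Oc1ccc2ccccc2c1",
     _p(n_ester=1, flags=frozenset({ARYL_ESTER}))),
    (8, "naphthalen-1-yl acetate", "CC(=O)Oc1cccc2ccccc12",
     _p(n_ester=1, flags=frozenset({ARYL_ESTER}))),
    (9, "4-methoxynaphthalene-1-carbaldehyde", "COc1ccc(C=O)c2ccccc12",
     _p(n_cho=1, n_ether=1)),
    (10, "naphthalen-2-yl acetic acid", "OC(=O)Cc1ccc2ccccc2c1", _p(n_cooh=1)),
    (11, "4-phenoxyphenol", "Oc1ccc(Oc2ccccc2)cc1", _p(n_oh_phenolic=1, n_ether=1)),
    (12, "1-(2-hydroxynaphthalen-1-yl) ethanone", "CC(=O)c1c(O)ccc2ccccc12",
     _p(n_oh_phenolic=1, n_ketone=1,
        flags=frozenset({ORTHO_OH_ARYL_KETONE, ALKYL_KETONE}))),
    (13, "2-methoxynaphthalene-1-carbaldehyde", "COc1ccc2ccccc2c1C=O",
     _p(n_cho=1, n_ether=1)),
    (14, "3-phenoxyphenol", "Oc1cccc(Oc2ccccc2)c1", _p(n_oh_phenolic=1, n_ether=1)),
    (15, "2-phenoxyphenol", "Oc1ccccc1Oc1ccccc1", _p(n_oh_phenolic=1, n_ether=1)),
    (16, "biphenyl-2,3-diol", "Oc1cccc(-c2ccccc2)c1O", _p(n_oh_phenolic=2)),
    (17, "biphenyl-3,3'-diol", "Oc1cccc(-c2cccc(O)c2)c1", _p(n_oh_phenolic=2)),
    (18, "methyl naphthalene-2-carboxylate", "COC(=O)c1ccc2ccccc2c1", _p(n_ester=1)),
]

_VALIDATION_MIX = [
    (19, "vanillin", "COc1cc(C=O)ccc1O", _p(n_oh_phenolic=1, n_cho=1, n_ether=1)),
    (20, "benzaldehyde", "O=Cc1ccccc1", _p(n_cho=1)),
    (21, "4-bromophenol", "Oc1ccc(Br)cc1", _p(n_oh_phenolic=1)),
    (22, "ethyl decanoate", "CCCCCCCCCC(=O)OCC", _p(n_ester=1)),
    (23, "di-n-propyl phthalate", "CCCOC(=O)c1ccccc1C(=O)OCCC", _p(n_ester=2)),
    (24, "benzophenone", "O=C(c1ccccc1)c1ccccc1", _p(n_ketone=1)),
    (25, "valerophenone", "CCCCC(=O)c1ccccc1",
     _p(n_ketone=1, flags=frozenset({ALKYL_KETONE}))),
    (26, "mecoprop", "CC(Oc1ccc(Cl)cc1C)C(=O)O", _p(n_cooh=1, n_ether=1)),
    (27, "naphthaleneacetic acid", "OC(=O)Cc1cccc2ccccc12", _p(n_cooh=1)),
    (28, "phenyl benzoate", "O=C(Oc1ccccc1)c1ccccc1",
     _p(n_ester=1, flags=frozenset({ARYL_ESTER}))),
]

_FIXTURES = {"c12h10o2_isomers": _C12H10O2, "validation_mix": _VALIDATION_MIX}


def load_fixture(name: str) -> FixtureSet:
    """Load a packaged fixture set (``c12h10o2_isomers`` or ``validation_mix``)."""
    try:
        raw = _FIXTURES[name]
    except KeyError:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        ) from None
    records = []
    for index, cname, smiles, truth_kw in raw:
        structure = parse_structure(smiles)
        records.append(
            FixtureRecord(
                index=index,
                name=cname,
                smiles=structure.smiles,
                structure=structure,
                truth=FGProfile(**truth_kw),
            )
        )
    return FixtureSet(name=name, records=tuple(records))


# ---------------------------------------------------------------------------
# Observation simulator
# ---------------------------------------------------------------------------

ALL_REAGENTS: tuple[ReagentId, ...] = tuple(ReagentId)


@dataclass(frozen=True)
class SimConfig:
    """Conversion model and noise for the synthetic GC-MS observer.

    ``FULL`` converts every reactive site (mirroring exhaustive
    derivatization); ``PARTIAL`` converts each site independently with
    probability ``p`` — except under TFAA, which always reacts exhaustively.
    ``mass_noise_sd`` adds Gaussian noise (Da) to every emitted mass; 0 gives
    exact nominal values. A fixed ``seed`` makes the output fully
    reproducible.
    """

    conversion_model: str = "FULL"  # "FULL" | "PARTIAL"
    p: float = 1.0
    mass_noise_sd: float = 0.0
    seed: int = 0
    panel: tuple[ReagentId, ...] = ALL_REAGENTS
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")
        if self.conversion_model not in ("FULL", "PARTIAL"):
            raise ValueError("conversion_model must be FULL or PARTIAL")


def _site_primary_shift(rs) -> int:
    if rs.rule.transform is not None:
        return rs.rule.transform.delta_m_nominal
    return rs.rule.alternate_shifts[0]


def simulate_observations(
    structure: Structure, rules: RuleSet, cfg: SimConfig = SimConfig()
) -> ObservationSet:
    """Forward-predict the per-reagent observations for one structure.

    Only reliable rules produce signal; chemistry the method itself marks
    unreliable (TMSCHN2 on aldehydes, the borate imine route) simulates as
    NO_CHANGE. Retention directions are copied from the reagent.
    """
    rng = np.random.default_rng(cfg.seed)
    noise = (
        (lambda: float(rng.normal(0.0, cfg.mass_noise_sd)))
        if cfg.mass_noise_sd > 0
        else (lambda: 0.0)
    )
    observations: list[Observation] = []
    for reagent_id in cfg.panel:
        sites = [
            s for s in reactive_sites(structure, reagent_id, rules) if s.rule.reliable
        ]
        if cfg.conversion_model == "PARTIAL" and reagent_id is not ReagentId.TFAA:
            chosen = [s for s in sites if rng.random() < cfg.p]
        else:
            chosen = sites
        if not chosen:
            observations.append(
                Observation(reagent_id, ObservationKind.NO_CHANGE, tolerance=cfg.tolerance)
            )
            continue
        if any(s.rule.outcome is OutcomeKind.CLEAVAGE for s in chosen):
            product = realize_product(structure, chosen, n_total_sites=len(sites))
            visible = [f for f in product.fragments if f.gc_visible]
            peak = max(f.structure.nominal_mass for f in visible)
            observations.append(
                Observation(
                    reagent_id,
                    ObservationKind.NEW_SMALLER_PEAK,
                    new_peak_mz=peak + noise(),
                    retention_direction=RetentionDirection.UNKNOWN,
                    tolerance=cfg.tolerance,
                )
            )
            continue
        delta = sum(_site_primary_shift(s) for s in chosen)
        direction = REAGENTS[reagent_id].retention_shift_direction
        if direction not in (RetentionDirection.LATER, RetentionDirection.EARLIER):
            direction = RetentionDirection.UNKNOWN
        observations.append(
            Observation(
                reagent_id,
                ObservationKind.SHIFT,
                observed_delta_m=delta + noise(),
                retention_direction=direction,
                tolerance=cfg.tolerance,
            )
        )
    return ObservationSet(
        parent_mz=float(structure.nominal_mass) + noise(),
        observations=tuple(observations),
    )


# ---------------------------------------------------------------------------
# Candidate readers / writers
# ---------------------------------------------------------------------------


def read_candidates(path: str | Path, fmt: str = "smiles") -> list[CandidateRecord]:
    """Read candidates from a SMILES list, an SDF (V2000), or a CSV.

    SMILES list lines are ``smiles[<TAB>id[<TAB>name]]``; CSV needs columns
    ``id,name,smiles``. Empty files yield an empty list; malformed content
    raises :class:`FormatError` naming the line.
    """
    path = Path(path)
    if fmt == "smiles":
        records = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                structure = parse_structure(parts[0])
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            cid = parts[1] if len(parts) > 1 else str(lineno)
            name = parts[2] if len(parts) > 2 else cid
            records.append(CandidateRecord(id=cid, name=name, structure=structure))
        return records
    if fmt == "sdf":
        records = []
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                raise FormatError(f"{path}: unreadable SDF record #{i}")
            structure = parse_structure(Chem.MolToSmiles(mol))
            cid = mol.GetProp("id") if mol.HasProp("id") else str(i)
            name = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name")
                else cid
            )
            records.append(CandidateRecord(id=cid, name=name, structure=structure))
        return records
    if fmt == "csv":
        records = []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                return []
            missing = {"id", "name", "smiles"} - set(reader.fieldnames)
            if missing:
                raise FormatError(f"{path}:1: missing columns {sorted(missing)}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    structure = parse_structure(row["smiles"])
                except Exception as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
                records.append(
                    CandidateRecord(id=row["id"], name=row["name"], structure=structure)
                )
        return records
    raise FormatError(f"unknown candidate format {fmt!r}")


def write_candidates(
    records: Sequence[CandidateRecord], path: str | Path, fmt: str = "smiles"
) -> None:
    path = Path(path)
    if fmt == "smiles":
        lines = [f"{r.structure.smiles}\t{r.id}\t{r.name}" for r in records]
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for r in records:
                mol = Chem.Mol(r.structure.mol)
                mol.SetProp("_Name", r.name)
                mol.SetProp("id", r.id)
                writer.write(mol)
        finally:
            writer.close()
        return
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "name", "smiles"])
            for r in records:
                w.writerow([r.id, r.name, r.structure.smiles])
        return
    raise FormatError(f"unknown candidate format {fmt!r}")


# ---------------------------------------------------------------------------
# Observation CSV round trip
# ---------------------------------------------------------------------------

_OBS_COLUMNS = [
    "parent_mz",
    "reagent",
    "kind",
    "delta_m",
    "new_peak_mz",
    "retention_direction",
    "tolerance",
]


def write_observations(obs: ObservationSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_OBS_COLUMNS)
        for o in obs.observations:
            w.writerow(
                [
                    repr(obs.parent_mz),
                    o.reagent_id.value,
                    o.kind.value,
                    "" if o.observed_delta_m is None else repr(o.observed_delta_m),
                    "" if o.new_peak_mz is None else repr(o.new_peak_mz),
                    o.retention_direction.value,
                    repr(o.tolerance),
                ]
            )


def read_observations(path: str | Path) -> ObservationSet:
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}:1: empty observations file")
        missing = set(_OBS_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}:1: missing columns {sorted(missing)}")
        parent_mz: float | None = None
        observations = []
        for lineno, row in enumerate(reader, start=2):
            try:
                parent_mz = float(row["parent_mz"])
                observations.append(
                    Observation(
                        reagent_id=ReagentId(row["reagent"]),
                        kind=ObservationKind(row["kind"]),
                        observed_delta_m=(
                            float(row["delta_m"]) if row["delta_m"] else None
                        ),
                        new_peak_mz=(
                            float(row["new_peak_mz"]) if row["new_peak_mz"] else None
                        ),
                        retention_direction=RetentionDirection(
                            row["retention_direction"]
                        ),
                        tolerance=float(row["tolerance"]),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
        if parent_mz is None:
            raise FormatError(f"{path}: no observation rows")
    return ObservationSet(parent_mz=parent_mz, observations=tuple(observations))


def write_report(
    report: FilterReport,
    csv_path: str | Path | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write the filter report as a CSV table and/or a JSON summary."""
    if csv_path is not None:
        report.to_dataframe().to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(report.summary_json() + "\n")
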