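"""Structure parsing, formula/mass computation, and functional-group detection.

Everything downstream (reaction rules, the decision-tree classifier, the
candidate filter) operates on the two objects defined here: :class:`Structure`,
a canonicalized small molecule with nominal / monoisotopic / average masses,
and :class:`FGProfile`, the per-molecule census of oxygen-bearing functional
groups (hydroxyl, carboxylic acid, aldehyde, ketone, carboxylic ester, ether).

Group detection is deliberately precedence-resolved: a carboxylic acid is one
COOH, never an OH plus a ketone; an ester is one COOR, never an ether plus a
ketone. Atoms consumed by a higher-precedence match are excluded from all
later patterns, so every oxygen is assigned to at most one group. Oxygens in
environments outside the six target classes (e.g. acetal oxygens) are counted
in ``unassigned_oxygens`` rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

from rdkit import Chem, RDLogger

from .errors import ParseError, UnknownElementError

RDLogger.DisableLog("rdApp.*")

# Per element: (nominal integer mass, monoisotopic mass / Da, standard atomic
# weight / g mol^-1). Monoisotopic values are the most-abundant-isotope exact
# masses (CODATA/IUPAC); average weights are the conventional IUPAC values.
ELEMENT_MASSES: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.00782503, 1.008),
    "C": (12, 12.00000000, 12.011),
    "N": (14, 14.00307401, 14.007),
    "O": (16, 15.99491462, 15.999),
    "F": (19, 18.99840316, 18.998),
    "S": (32, 31.97207117, 32.06),
    "Cl": (35, 34.96885268, 35.45),
    "Br": (79, 78.91833760, 79.904),
}


def _check_element(symbol: str) -> tuple[int, float, float]:
    try:
        return ELEMENT_MASSES[symbol]
    except KeyError:
        raise UnknownElementError(
            f"element {symbol!r} is not in the mass table"
        ) from None


@dataclass(frozen=True)
class Formula:
    """An element → count map with Hill-order rendering (C, H, alphabetical)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned = {el: int(n) for el, n in self.counts.items() if n != 0}
        if any(n < 0 for n in cleaned.values()):
            raise ValueError(f"negative element count in {cleaned}")
        object.__setattr__(self, "counts", cleaned)

    @classmethod
    def from_mol(cls, mol: Chem.Mol) -> "Formula":
        counts: dict[str, int] = {}
        for atom in mol.GetAtoms():
            counts[atom.GetSymbol()] = counts.get(atom.GetSymbol(), 0) + 1
            h = atom.GetTotalNumHs()
            if h:
                counts["H"] = counts.get("H", 0) + h
        return cls(counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __str__(self) -> str:
        parts = []
        order = [el for el in ("C", "H") if el in self.counts]
        order += sorted(el for el in self.counts if el not in ("C", "H"))
        for el in order:
            n = self.counts[el]
            parts.append(el if n == 1 else f"{el}{n}")
        return "".join(parts)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Formula) and dict(self.counts) == dict(other.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))


def nominal_mass(f: Formula) -> int:
    """Integer mass from most-abundant-isotope integer masses, in Da."""
    if not f.counts:
        raise ValueError("empty formula")
    return sum(_check_element(el)[0] * n for el, n in f.counts.items())


def monoisotopic_mass(f: Formula) -> float:
    """Exact mass from most-abundant-isotope exact masses, in Da."""
    if not f.counts:
        raise ValueError("empty formula")
    return sum(_check_element(el)[1] * n for el, n in f.counts.items())


def average_mass(f: Formula) -> float:
    """Molecular weight from standard atomic weights, in g/mol."""
    if not f.counts:
        raise ValueError("empty formula")
    return sum(_check_element(el)[2] * n for el, n in f.counts.items())


@dataclass(frozen=True)
class Structure:
    """A parsed small molecule.

    ``smiles`` is the toolkit-canonical form; re-parsing it reproduces itself.
    All three masses are computed from :data:`ELEMENT_MASSES` over the
    molecular formula (graph-derived and formula-derived masses coincide by
    construction).
    """

    smiles: str
    mol: Chem.Mol = field(repr=False, compare=False)
    formula: Formula
    nominal_mass: int
    monoisotopic_mass: float
    average_mass: float

    @property
    def formula_string(self) -> str:
        return str(self.formula)


def structure_from_mol(mol: Chem.Mol) -> Structure:
    f = Formula.from_mol(mol)
    return Structure(
        smiles=Chem.MolToSmiles(mol),
        mol=mol,
        formula=f,
        nominal_mass=nominal_mass(f),
        monoisotopic_mass=monoisotopic_mass(f),
        average_mass=average_mass(f),
    )


def parse_structure(smiles: str) -> Structure:
    """Parse a SMILES string into a canonicalized :class:`Structure`.

    Raises :class:`ParseError` on empty or invalid input; the message carries
    the offending string.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES: {smiles!r}")
    return structure_from_mol(mol)


class FunctionalGroup(str, Enum):
    """The six oxygen-bearing group classes the workflow discriminates."""

    OH = "OH"
    COOH = "COOH"
    CHO = "CHO"
    KETONE = "KETONE"
    ESTER = "ESTER"
    ETHER = "ETHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Profile / site flags.
ORTHO_OH_ARYL_KETONE = "ORTHO_OH_ARYL_KETONE"
ARYL_ESTER = "ARYL_ESTER"
ALKYL_KETONE = "ALKYL_KETONE"
PHENOLIC = "PHENOLIC"
ALIPHATIC = "ALIPHATIC"


@dataclass(frozen=True)
class GroupSite:
    """One matched functional-group site: atom indices plus site flags.

    Atom index conventions (all indices into the parent molecule):
      OH     -> (C, O)
      COOH   -> (C_carbonyl, O_carbonyl, O_hydroxyl)
      CHO    -> (C_carbonyl, O_carbonyl)
      KETONE -> (C_carbonyl, O_carbonyl, C_flank1, C_flank2)
      ESTER  -> (C_carbonyl, O_carbonyl, O_ester, C_on_O)
      ETHER  -> (C, O, C)
    """

    group: FunctionalGroup
    atoms: tuple[int, ...]
    flags: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FGProfile:
    """Counts of O-functional groups with qualifier flags.

    ``unassigned_oxygens`` counts oxygen atoms not claimed by any of the six
    classes (e.g. acetal oxygens); it is reported, never silently dropped.
    """

    n_oh_phenolic: int = 0
    n_oh_aliphatic: int = 0
    n_cooh: int = 0
    n_cho: int = 0
    n_ketone: int = 0
    n_ester: int = 0
    n_ether: int = 0
    flags: frozenset[str] = frozenset()
    unassigned_oxygens: int = 0

    @property
    def n_oh(self) -> int:
        return self.n_oh_phenolic + self.n_oh_aliphatic

    def count(self, group: FunctionalGroup) -> int:
        return {
            FunctionalGroup.OH: self.n_oh,
            FunctionalGroup.COOH: self.n_cooh,
            FunctionalGroup.CHO: self.n_cho,
            FunctionalGroup.KETONE: self.n_ketone,
            FunctionalGroup.ESTER: self.n_ester,
            FunctionalGroup.ETHER: self.n_ether,
        }[group]

    def as_multiset(self) -> tuple[FunctionalGroup, ...]:
        """The group multiset, sorted, with OH variants merged."""
        out: list[FunctionalGroup] = []
        for g in FunctionalGroup:
            out.extend([g] * self.count(g))
        return tuple(sorted(out, key=lambda g: g.value))


_SMARTS = {
    FunctionalGroup.COOH: Chem.MolFromSmarts("[CX3](=[OX1])[OX2H1]"),
    FunctionalGroup.ESTER: Chem.MolFromSmarts("[CX3](=[OX1])[OX2H0][#6]"),
    FunctionalGroup.CHO: Chem.MolFromSmarts("[CX3H1](=[OX1])[#6]"),
    FunctionalGroup.KETONE: Chem.MolFromSmarts("[CX3](=[OX1])([#6])[#6]"),
    FunctionalGroup.OH: Chem.MolFromSmarts("[#6][OX2H1]"),
    FunctionalGroup.ETHER: Chem.MolFromSmarts("[#6][OX2H0][#6]"),
}

# Match order implements the precedence COOH > ester > CHO > ketone > OH >
# ether; atoms consumed by an earlier match are excluded from later patterns.
_PRECEDENCE = [
    FunctionalGroup.COOH,
    FunctionalGroup.ESTER,
    FunctionalGroup.CHO,
    FunctionalGroup.KETONE,
    FunctionalGroup.OH,
    FunctionalGroup.ETHER,
]


def _has_ortho_phenol(mol: Chem.Mol, aryl_idx: int) -> bool:
    """Does the aromatic ipso atom have an ortho neighbour bearing an OH?"""
    ipso = mol.GetAtomWithIdx(aryl_idx)
    for ortho in ipso.GetNeighbors():
        if not ortho.GetIsAromatic():
            continue
        for sub in ortho.GetNeighbors():
            if sub.GetSymbol() == "O" and sub.GetTotalNumHs() >= 1 and sub.GetDegree() == 1:
                return True
    return False


def _is_acetal_oxygen(mol: Chem.Mol, o_idx: int) -> bool:
    """True for an O whose sp3 carbon neighbour bears two or more oxygens."""
    for nb in mol.GetAtomWithIdx(o_idx).GetNeighbors():
        if nb.GetSymbol() != "C" or nb.GetIsAromatic():
            continue
        if nb.GetHybridization() == Chem.HybridizationType.SP3:
            n_o = sum(1 for x in nb.GetNeighbors() if x.GetSymbol() == "O")
            if n_o >= 2:
                return True
    return False


def find_group_sites(structure: Structure) -> list[GroupSite]:
    """Locate every functional-group site with precedence resolution.

    This single routine backs both :func:`detect_functional_groups` and the
    reaction engine, so the group census and the reactive-site census can
    never disagree.
    """
    mol = structure.mol
    consumed: set[int] = set()
    sites: list[GroupSite] = []
    for group in _PRECEDENCE:
        seen_keys: set[int] = set()
        for match in mol.GetSubstructMatches(_SMARTS[group]):
            if group in (FunctionalGroup.COOH, FunctionalGroup.ESTER):
                key_atoms = match[:3]  # carbonyl C and both oxygens
            elif group in (FunctionalGroup.CHO, FunctionalGroup.KETONE):
                key_atoms = match[:2]  # carbonyl C and O
            elif group is FunctionalGroup.OH:
                key_atoms = (match[1],)
            else:  # ETHER
                key_atoms = (match[1],)
            if any(a in consumed for a in key_atoms):
                continue
            key = key_atoms[0]
            if key in seen_keys:  # symmetric SMARTS (ketone, ether)
                continue
            seen_keys.add(key)

            flags: set[str] = set()
            if group is FunctionalGroup.OH:
                carbon = mol.GetAtomWithIdx(match[0])
                flags.add(PHENOLIC if carbon.GetIsAromatic() else ALIPHATIC)
            elif group is FunctionalGroup.KETONE:
                flank = [mol.GetAtomWithIdx(match[2]), mol.GetAtomWithIdx(match[3])]
                if any(
                    a.GetIsAromatic() and _has_ortho_phenol(mol, a.GetIdx())
                    for a in flank
                ):
                    flags.add(ORTHO_OH_ARYL_KETONE)
                if any(
                    not a.GetIsAromatic()
                    and a.GetHybridization() == Chem.HybridizationType.SP3
                    for a in flank
                ):
                    flags.add(ALKYL_KETONE)
            elif group is FunctionalGroup.ESTER:
                if mol.GetAtomWithIdx(match[3]).GetIsAromatic():
                    flags.add(ARYL_ESTER)
            elif group is FunctionalGroup.ETHER:
                if _is_acetal_oxygen(mol, match[1]):
                    continue  # acetal oxygens are not ethers

            consumed.update(key_atoms)
            sites.append(GroupSite(group, tuple(match), frozenset(flags)))
    return sites


def detect_functional_groups(structure: Structure) -> FGProfile:
    """Census of O-functional groups for one structure (deterministic)."""
    sites = find_group_sites(structure)
    counts = {g: 0 for g in FunctionalGroup}
    n_phen = n_aliph = 0
    flags: set[str] = set()
    assigned_o: set[int] = set()
    mol = structure.mol
    for s in sites:
        counts[s.group] += 1
        if s.group is FunctionalGroup.OH:
            if PHENOLIC in s.flags:
                n_phen += 1
            else:
                n_aliph += 1
            assigned_o.add(s.atoms[1])
        elif s.group in (FunctionalGroup.COOH, FunctionalGroup.ESTER):
            assigned_o.update(s.atoms[1:3])
        elif s.group in (FunctionalGroup.CHO, FunctionalGroup.KETONE):
            assigned_o.add(s.atoms[1])
        else:  # ETHER
            assigned_o.add(s.atoms[1])
        flags.update(s.flags - {PHENOLIC, ALIPHATIC})
    total_o = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == "O")
    return FGProfile(
        n_oh_phenolic=n_phen,
        n_oh_aliphatic=n_aliph,
        n_cooh=counts[FunctionalGroup.COOH],
        n_cho=counts[FunctionalGroup.CHO],
        n_ketone=counts[FunctionalGroup.KETONE],
        n_ester=counts[FunctionalGroup.ESTER],
        n_ether=counts[FunctionalGroup.ETHER],
        flags=frozenset(flags),
        unassigned_oxygens=total_o - len(assigned_o),
    )
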