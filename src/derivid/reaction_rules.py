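"""The reagent × functional-group reactivity matrix as executable transforms.

Six derivatization reagents are modeled: three methylating agents (TMSH,
TMSCHN2, DMF-DMA), the acylating agent TFAA, basic ester hydrolysis with
NH4OH, and imine formation with a borate ester plus a primary amine. Each
:class:`ReactionRule` couples a functional-group class to an outcome — a
molecular-ion mass shift (with the structural graph edit that produces it),
an ester cleavage into fragments, or no reaction. The per-site Δm of every
structural rule is *derived* from the atoms its transform adds and removes,
never typed in, so the tabulated shift and the product structure are two
routes to the same number and can be cross-checked.

Key shifts encoded (per reactive site, nominal Da):

* O-methylation of OH / COOH: +14 (observed alternate +18 accepted)
* aldehyde dimethyl-acetal formation: +46
* enol O-methylation of ortho-hydroxy aryl ketones: +14
* O-trifluoroacetylation of OH: +96 (a diol therefore shifts by +192)
* ester hydrolysis: cleavage; the alcohol fragment is the observable peak
* aldimine formation: amine mass − H2O (benzylamine: +89)
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

from rdkit import Chem

from .chem_core import (
    ARYL_ESTER,
    ORTHO_OH_ARYL_KETONE,
    FunctionalGroup,
    Formula,
    GroupSite,
    Structure,
    find_group_sites,
    monoisotopic_mass,
    nominal_mass,
    structure_from_mol,
)
from .errors import DerividError, SiteOverflowError

MAX_ENUMERATED_SITES = 8

UNRESOLVED_ADDUCT = "unresolved_adduct"


class ReagentId(str, Enum):
    TMSH = "TMSH"
    TMSCHN2 = "TMSCHN2"
    DMF_DMA = "DMF_DMA"
    TFAA = "TFAA"
    NH4OH = "NH4OH"
    BORATE_AMINE = "BORATE_AMINE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class RetentionDirection(str, Enum):
    LATER = "LATER"
    EARLIER = "EARLIER"
    NONE = "NONE"
    PRODUCT_SPECIFIC = "PRODUCT_SPECIFIC"
    UNKNOWN = "UNKNOWN"


class OutcomeKind(str, Enum):
    SHIFT = "SHIFT"
    CLEAVAGE = "CLEAVAGE"
    NONE = "NONE"


@dataclass(frozen=True)
class Reagent:
    id: ReagentId
    display_name: str
    retention_shift_direction: RetentionDirection


# Methylation moves the peak to later retention times; trifluoroacetylation
# to earlier ones. Hydrolysis yields an unrelated product peak.
REAGENTS: dict[ReagentId, Reagent] = {
    ReagentId.TMSH: Reagent(
        ReagentId.TMSH, "trimethylsulfonium hydroxide (TMSH)", RetentionDirection.LATER
    ),
    ReagentId.TMSCHN2: Reagent(
        ReagentId.TMSCHN2,
        "trimethylsilyldiazomethane (TMSCHN2)",
        RetentionDirection.LATER,
    ),
    ReagentId.DMF_DMA: Reagent(
        ReagentId.DMF_DMA,
        "N,N-dimethylformamide dimethyl acetal (DMF-DMA)",
        RetentionDirection.LATER,
    ),
    ReagentId.TFAA: Reagent(
        ReagentId.TFAA, "trifluoroacetic anhydride (TFAA)", RetentionDirection.EARLIER
    ),
    ReagentId.NH4OH: Reagent(
        ReagentId.NH4OH, "ammonium hydroxide (NH4OH)", RetentionDirection.PRODUCT_SPECIFIC
    ),
    ReagentId.BORATE_AMINE: Reagent(
        ReagentId.BORATE_AMINE,
        "tris(2,2,2-trifluoroethyl) borate + primary amine",
        RetentionDirection.NONE,
    ),
}

#: Amines available for the imine rule; Δm is always computed from the
#: transform, never hard-coded.
AMINE_SMILES: dict[str, str] = {
    "benzylamine": "NCc1ccccc1",
    "aniline": "Nc1ccccc1",
    "2,4-difluorobenzylamine": "NCc1ccc(F)cc1F",
}


# ---------------------------------------------------------------------------
# Structural transforms (graph edits on an RWMol, per matched site)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transform:
    """A named graph edit with its net formula change.

    ``added`` / ``removed`` describe the net atoms gained and lost by one
    application; the rule's Δm is derived from them and independently
    verified against the edited product graph in the test suite.
    """

    name: str
    added: Formula
    removed: Formula
    apply: Callable[[Chem.RWMol, GroupSite], None] = field(compare=False, repr=False)

    @property
    def delta_m_nominal(self) -> int:
        d = nominal_mass(self.added) if self.added.counts else 0
        if self.removed.counts:
            d -= nominal_mass(self.removed)
        return d

    @property
    def delta_m_monoisotopic(self) -> float:
        d = monoisotopic_mass(self.added) if self.added.counts else 0.0
        if self.removed.counts:
            d -= monoisotopic_mass(self.removed)
        return d


def _site_hydroxyl_oxygen(site: GroupSite) -> int:
    if site.group is FunctionalGroup.OH:
        return site.atoms[1]
    if site.group is FunctionalGroup.COOH:
        return site.atoms[2]
    raise DerividError(f"no hydroxyl oxygen on a {site.group} site")


def _apply_o_methylation(rw: Chem.RWMol, site: GroupSite) -> None:
    o = _site_hydroxyl_oxygen(site)
    c_new = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(o, c_new, Chem.BondType.SINGLE)


def _apply_dimethyl_acetal(rw: Chem.RWMol, site: GroupSite) -> None:
    c, o = site.atoms[0], site.atoms[1]
    rw.GetBondBetweenAtoms(c, o).SetBondType(Chem.BondType.SINGLE)
    m1 = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(o, m1, Chem.BondType.SINGLE)
    o2 = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(c, o2, Chem.BondType.SINGLE)
    m2 = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(o2, m2, Chem.BondType.SINGLE)


def _apply_enol_o_methylation(rw: Chem.RWMol, site: GroupSite) -> None:
    c, o = site.atoms[0], site.atoms[1]
    alpha = None
    for idx in site.atoms[2:]:
        atom = rw.GetAtomWithIdx(idx)
        if (
            not atom.GetIsAromatic()
            and atom.GetHybridization() == Chem.HybridizationType.SP3
            and atom.GetTotalNumHs() >= 1
        ):
            alpha = idx
            break
    if alpha is None:
        raise DerividError("enol methylation requires an sp3 alpha carbon with H")
    rw.GetBondBetweenAtoms(c, o).SetBondType(Chem.BondType.SINGLE)
    m = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(o, m, Chem.BondType.SINGLE)
    rw.GetBondBetweenAtoms(c, alpha).SetBondType(Chem.BondType.DOUBLE)


def _apply_trifluoroacetylation(rw: Chem.RWMol, site: GroupSite) -> None:
    o = _site_hydroxyl_oxygen(site)
    cc = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(o, cc, Chem.BondType.SINGLE)
    oo = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(cc, oo, Chem.BondType.DOUBLE)
    cf = rw.AddAtom(Chem.Atom(6))
    rw.AddBond(cc, cf, Chem.BondType.SINGLE)
    for _ in range(3):
        f = rw.AddAtom(Chem.Atom(9))
        rw.AddBond(cf, f, Chem.BondType.SINGLE)


def _apply_ester_hydrolysis(rw: Chem.RWMol, site: GroupSite) -> None:
    c_carbonyl, _, o_ester, _ = site.atoms
    rw.RemoveBond(c_carbonyl, o_ester)
    oh = rw.AddAtom(Chem.Atom(8))
    rw.AddBond(c_carbonyl, oh, Chem.BondType.SINGLE)


def _make_imine_apply(amine_smiles: str) -> Callable[[Chem.RWMol, GroupSite], None]:
    def _apply(rw: Chem.RWMol, site: GroupSite) -> None:
        c, o = site.atoms[0], site.atoms[1]
        amine = Chem.MolFromSmiles(amine_smiles)
        n_local = amine.GetSubstructMatch(Chem.MolFromSmarts("[NX3;H2]"))[0]
        offset = rw.GetNumAtoms()
        rw.InsertMol(amine)
        rw.RemoveBond(c, o)
        rw.RemoveAtom(o)
        c_idx = c - 1 if o < c else c
        n_idx = offset + n_local - 1  # o always precedes the inserted atoms
        rw.AddBond(c_idx, n_idx, Chem.BondType.DOUBLE)

    return _apply


def _amine_added_formula(amine_smiles: str) -> Formula:
    amine = Chem.MolFromSmiles(amine_smiles)
    f = dict(Formula.from_mol(amine).counts)
    f["H"] = f.get("H", 0) - 2  # both N-H hydrogens are lost on condensation
    return Formula(f)


def build_transform(name: str, amine: str = "benzylamine") -> Transform:
    """Construct a registered transform by name (``imine_formation`` takes an amine)."""
    if name == "o_methylation":
        return Transform(name, Formula({"C": 1, "H": 2}), Formula({}), _apply_o_methylation)
    if name == "dimethyl_acetal":
        return Transform(name, Formula({"C": 2, "H": 6, "O": 1}), Formula({}), _apply_dimethyl_acetal)
    if name == "enol_o_methylation":
        return Transform(name, Formula({"C": 1, "H": 2}), Formula({}), _apply_enol_o_methylation)
    if name == "o_trifluoroacetylation":
        return Transform(
            name, Formula({"C": 2, "F": 3, "O": 1}), Formula({"H": 1}), _apply_trifluoroacetylation
        )
    if name == "ester_hydrolysis":
        return Transform(name, Formula({"H": 2, "O": 1}), Formula({}), _apply_ester_hydrolysis)
    if name == "imine_formation":
        if amine not in AMINE_SMILES:
            raise DerividError(f"unknown amine {amine!r}; choose from {sorted(AMINE_SMILES)}")
        return Transform(
            f"imine_formation[{amine}]",
            _amine_added_formula(AMINE_SMILES[amine]),
            Formula({"O": 1}),
            _make_imine_apply(AMINE_SMILES[amine]),
        )
    raise DerividError(f"unknown transform {name!r}")


# ---------------------------------------------------------------------------
# Rules and rule sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionRule:
    reagent_id: ReagentId
    group: FunctionalGroup
    outcome: OutcomeKind
    flag_condition: str | None = None
    transform: Transform | None = None
    alternate_shifts: tuple[int, ...] = ()
    reliable: bool = True
    flags: frozenset[str] = frozenset()
    note: str = ""

    @property
    def delta_m_nominal(self) -> int | None:
        return self.transform.delta_m_nominal if self.transform else None

    @property
    def delta_m_monoisotopic(self) -> float | None:
        return self.transform.delta_m_monoisotopic if self.transform else None

    def shift_choices(self) -> tuple[int, ...]:
        """Acceptable per-site nominal Δm values (primary first)."""
        if self.outcome is not OutcomeKind.SHIFT:
            return ()
        if self.transform is not None:
            return (self.transform.delta_m_nominal, *self.alternate_shifts)
        return self.alternate_shifts


@dataclass(frozen=True)
class RuleSet:
    """A complete reagent × group matrix (no silent gaps) with options."""

    rules: tuple[ReactionRule, ...]
    version: str = "1"
    provenance: str = ""
    amine: str = "benzylamine"
    good_leaving_group_only: bool = False

    def validate(self) -> None:
        cells: dict[tuple[ReagentId, FunctionalGroup, str | None], int] = {}
        for r in self.rules:
            key = (r.reagent_id, r.group, r.flag_condition)
            cells[key] = cells.get(key, 0) + 1
            if cells[key] > 1:
                raise DerividError(f"duplicate rule for {key}")
        for reagent in ReagentId:
            for group in FunctionalGroup:
                if (reagent, group, None) not in cells:
                    raise DerividError(
                        f"rule matrix gap: no unconditional rule for ({reagent}, {group})"
                    )

    def rule_for(
        self,
        reagent_id: ReagentId,
        group: FunctionalGroup,
        site_flags: frozenset[str] = frozenset(),
    ) -> ReactionRule:
        """Most specific applicable rule: flag-conditioned beats unconditional."""
        unconditional = None
        for r in self.rules:
            if r.reagent_id is not reagent_id or r.group is not group:
                continue
            if r.flag_condition is not None and r.flag_condition in site_flags:
                return r
            if r.flag_condition is None:
                unconditional = r
        if unconditional is None:
            raise DerividError(f"no rule for ({reagent_id}, {group})")
        return unconditional

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "version": self.version,
            "provenance": self.provenance,
            "amine": self.amine,
            "good_leaving_group_only": self.good_leaving_group_only,
            "rules": [
                {
                    "reagent": r.reagent_id.value,
                    "group": r.group.value,
                    "outcome": r.outcome.value,
                    "flag_condition": r.flag_condition,
                    "transform": r.transform.name.split("[")[0] if r.transform else None,
                    "alternate_shifts": list(r.alternate_shifts),
                    "reliable": r.reliable,
                    "flags": sorted(r.flags),
                    "note": r.note,
                }
                for r in self.rules
            ],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        payload = json.loads(text)
        amine = payload.get("amine", "benzylamine")
        rules = tuple(
            ReactionRule(
                reagent_id=ReagentId(d["reagent"]),
                group=FunctionalGroup(d["group"]),
                outcome=OutcomeKind(d["outcome"]),
                flag_condition=d.get("flag_condition"),
                transform=(
                    build_transform(d["transform"], amine) if d.get("transform") else None
                ),
                alternate_shifts=tuple(d.get("alternate_shifts", ())),
                reliable=d.get("reliable", True),
                flags=frozenset(d.get("flags", ())),
                note=d.get("note", ""),
            )
            for d in payload["rules"]
        )
        rs = cls(
            rules=rules,
            version=payload.get("version", "1"),
            provenance=payload.get("provenance", ""),
            amine=amine,
            good_leaving_group_only=payload.get("good_leaving_group_only", False),
        )
        rs.validate()
        return rs


def default_rule_set(
    amine: str = "benzylamine", good_leaving_group_only: bool = False
) -> RuleSet:
    """The built-in six-reagent × six-group reactivity matrix.

    Notes on deliberately surfaced ambiguities:

    * TFAA: +96 per OH site from the acylation graph edit; the frequently
      quoted +192 shift corresponds to exhaustive acylation of a diol.
    * TMSH on ketones without an ortho-phenol: a shift is expected but the
      adduct structure is unresolved, so the rule carries accepted shifts
      (+14/+18) and no transform.
    * DMF-DMA methylates carboxylic acids only; its OH cell is NONE.
    * TMSCHN2 on aldehydes and the borate imine route are flagged unreliable
      and never drive a classification or a strict filtering verdict.
    """
    R, G, O = ReagentId, FunctionalGroup, OutcomeKind

    def rule(reagent, group, outcome, **kw) -> ReactionRule:
        return ReactionRule(reagent, group, outcome, **kw)

    meth = build_transform("o_methylation")
    acetal = build_transform("dimethyl_acetal")
    enol = build_transform("enol_o_methylation")
    tfa = build_transform("o_trifluoroacetylation")
    hydro = build_transform("ester_hydrolysis")
    imine = build_transform("imine_formation", amine)

    rules = [
        # TMSH — broad methylation
        rule(R.TMSH, G.OH, O.SHIFT, transform=meth, alternate_shifts=(18,)),
        rule(R.TMSH, G.COOH, O.SHIFT, transform=meth, alternate_shifts=(18,),
             note="methyl ester formation"),
        rule(R.TMSH, G.CHO, O.SHIFT, transform=acetal,
             note="aldehyde-specific +46 via the dimethyl acetal"),
        rule(R.TMSH, G.KETONE, O.SHIFT, flag_condition=ORTHO_OH_ARYL_KETONE,
             transform=enol, alternate_shifts=(18,),
             note="enol O-methylation enabled by keto-enol tautomerization"),
        rule(R.TMSH, G.KETONE, O.SHIFT, alternate_shifts=(14, 18),
             flags=frozenset({UNRESOLVED_ADDUCT}),
             note="shift observed but adduct structure unresolved"),
        rule(R.TMSH, G.ESTER, O.NONE),
        rule(R.TMSH, G.ETHER, O.NONE),
        # TMSCHN2 — supportive methylation
        rule(R.TMSCHN2, G.OH, O.SHIFT, transform=meth),
        rule(R.TMSCHN2, G.COOH, O.SHIFT, transform=meth),
        rule(R.TMSCHN2, G.CHO, O.SHIFT, alternate_shifts=(46,), reliable=False,
             note="no clear aldehyde methylation outcome; excluded from strict filtering"),
        rule(R.TMSCHN2, G.KETONE, O.NONE),
        rule(R.TMSCHN2, G.ESTER, O.NONE),
        rule(R.TMSCHN2, G.ETHER, O.NONE),
        # DMF-DMA — carboxylic-acid-selective methylation
        rule(R.DMF_DMA, G.COOH, O.SHIFT, transform=meth, alternate_shifts=(18,)),
        rule(R.DMF_DMA, G.CHO, O.SHIFT, transform=acetal),
        rule(R.DMF_DMA, G.OH, O.NONE,
             note="workflow reading: DMF-DMA methylates carboxylic acids only"),
        rule(R.DMF_DMA, G.KETONE, O.NONE),
        rule(R.DMF_DMA, G.ESTER, O.NONE),
        rule(R.DMF_DMA, G.ETHER, O.NONE),
        # TFAA — hydroxyl-selective acylation
        rule(R.TFAA, G.OH, O.SHIFT, transform=tfa,
             note="+96 per OH site; a diol shifts by +192 on exhaustive acylation"),
        rule(R.TFAA, G.COOH, O.NONE),
        rule(R.TFAA, G.CHO, O.NONE),
        rule(R.TFAA, G.KETONE, O.NONE),
        rule(R.TFAA, G.ESTER, O.NONE),
        rule(R.TFAA, G.ETHER, O.NONE),
        # NH4OH — basic ester hydrolysis
        rule(R.NH4OH, G.ESTER, O.CLEAVAGE, transform=hydro,
             note="observable peak is the alcohol fragment; the acid fragment is "
                  "usually not detectable by GC-MS"),
        rule(R.NH4OH, G.OH, O.NONE),
        rule(R.NH4OH, G.COOH, O.NONE),
        rule(R.NH4OH, G.CHO, O.NONE),
        rule(R.NH4OH, G.KETONE, O.NONE),
        rule(R.NH4OH, G.ETHER, O.NONE),
        # Borate + amine — aldimine formation (supportive only)
        rule(R.BORATE_AMINE, G.CHO, O.SHIFT, transform=imine, reliable=False,
             note="did not work for all aldehydes; supportive evidence only"),
        rule(R.BORATE_AMINE, G.OH, O.NONE),
        rule(R.BORATE_AMINE, G.COOH, O.NONE),
        rule(R.BORATE_AMINE, G.KETONE, O.NONE),
        rule(R.BORATE_AMINE, G.ESTER, O.NONE),
        rule(R.BORATE_AMINE, G.ETHER, O.NONE),
    ]
    rs = RuleSet(
        rules=tuple(rules),
        version="1",
        provenance="built-in reactivity matrix for O-functionalities",
        amine=amine,
        good_leaving_group_only=good_leaving_group_only,
    )
    rs.validate()
    return rs


# ---------------------------------------------------------------------------
# Product prediction
# ---------------------------------------------------------------------------


class ProductMode(str, Enum):
    FULL_ONLY = "FULL_ONLY"
    ALL_PARTIAL = "ALL_PARTIAL"


@dataclass(frozen=True)
class ReactiveSite:
    site: GroupSite
    rule: ReactionRule


@dataclass(frozen=True)
class FragmentRecord:
    structure: Structure
    role: str  # "alcohol" | "acid"
    gc_visible: bool


@dataclass(frozen=True)
class Product:
    structure: Structure | None
    sites_modified: tuple[tuple[ReactionRule, tuple[int, ...]], ...]
    total_delta_m_nominal: int
    total_delta_m_monoisotopic: float
    completeness: str  # "FULL" | "PARTIAL"
    fragments: tuple[FragmentRecord, ...] = ()


def reactive_sites(
    structure: Structure, reagent_id: ReagentId, rules: RuleSet
) -> list[ReactiveSite]:
    """All sites of ``structure`` with a non-NONE rule under the reagent."""
    out: list[ReactiveSite] = []
    for site in find_group_sites(structure):
        rule = rules.rule_for(reagent_id, site.group, site.flags)
        if rule.outcome is OutcomeKind.NONE:
            continue
        if (
            rule.outcome is OutcomeKind.CLEAVAGE
            and rules.good_leaving_group_only
            and ARYL_ESTER not in site.flags
        ):
            continue
        out.append(ReactiveSite(site=site, rule=rule))
    return out


def _apply_sites(structure: Structure, chosen: Sequence[ReactiveSite]) -> Chem.Mol:
    rw = Chem.RWMol(structure.mol)
    # Descending order keeps earlier-applied (higher) indices from disturbing
    # later sites; added atoms are always appended at the end.
    for rs in sorted(chosen, key=lambda r: -min(r.site.atoms)):
        rs.rule.transform.apply(rw, rs.site)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _cleavage_product(
    structure: Structure, chosen: Sequence[ReactiveSite], total_sites: int
) -> Product:
    mol = _apply_sites(structure, chosen)
    ester_oxygens = {rs.site.atoms[2] for rs in chosen}
    frags_idx = Chem.GetMolFrags(mol)
    frag_mols = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    fragments = []
    for idx_tuple, frag in zip(frags_idx, frag_mols):
        is_alcohol = any(i in ester_oxygens for i in idx_tuple)
        fragments.append(
            FragmentRecord(
                structure=structure_from_mol(frag),
                role="alcohol" if is_alcohol else "acid",
                gc_visible=is_alcohol,
            )
        )
    fragments.sort(key=lambda f: (-f.structure.nominal_mass, f.structure.smiles))
    n = len(chosen)
    return Product(
        structure=None,
        sites_modified=tuple((rs.rule, rs.site.atoms) for rs in chosen),
        total_delta_m_nominal=18 * n,
        total_delta_m_monoisotopic=sum(
            rs.rule.transform.delta_m_monoisotopic for rs in chosen
        ),
        completeness="FULL" if n == total_sites else "PARTIAL",
        fragments=tuple(fragments),
    )


def predict_products(
    structure: Structure,
    reagent: ReagentId | Reagent,
    rules: RuleSet,
    mode: ProductMode = ProductMode.FULL_ONLY,
) -> list[Product]:
    """Predict derivatization products of ``structure`` under one reagent.

    ``FULL_ONLY`` returns the single exhaustively derivatized product (or an
    empty list when no structural rule applies); ``ALL_PARTIAL`` additionally
    enumerates every non-empty subset of reactive sites. TFAA always reacts
    exhaustively, so it forces FULL_ONLY. Cleavage rules return products whose
    ``fragments`` carry the alcohol (GC-visible) and acid pieces.
    """
    reagent_id = reagent.id if isinstance(reagent, Reagent) else reagent
    sites = reactive_sites(structure, reagent_id, rules)
    structural = [s for s in sites if s.rule.transform is not None]
    if not structural:
        return []
    if len(structural) > MAX_ENUMERATED_SITES:
        raise SiteOverflowError(
            f"{len(structural)} reactive sites exceed the enumeration cap of "
            f"{MAX_ENUMERATED_SITES}"
        )
    if reagent_id is ReagentId.TFAA:
        mode = ProductMode.FULL_ONLY

    if mode is ProductMode.FULL_ONLY:
        subsets: Iterable[tuple[ReactiveSite, ...]] = [tuple(structural)]
    else:
        subsets = itertools.chain.from_iterable(
            itertools.combinations(structural, k)
            for k in range(1, len(structural) + 1)
        )

    products: list[Product] = []
    seen: set[tuple[str, int]] = set()
    for chosen in subsets:
        prod = realize_product(structure, chosen, n_total_sites=len(structural))
        if prod.fragments:
            key = (
                "|".join(f.structure.smiles for f in prod.fragments),
                prod.total_delta_m_nominal,
            )
        else:
            key = (prod.structure.smiles, prod.total_delta_m_nominal)
        if key in seen:
            continue
        seen.add(key)
        products.append(prod)
    products.sort(key=lambda p: (p.total_delta_m_nominal, p.completeness))
    return products


def realize_product(
    structure: Structure,
    chosen: Sequence[ReactiveSite],
    n_total_sites: int,
) -> Product:
    """Build the product for one specific subset of structural sites."""
    if any(s.rule.outcome is OutcomeKind.CLEAVAGE for s in chosen):
        return _cleavage_product(structure, chosen, n_total_sites)
    mol = _apply_sites(structure, chosen)
    product_structure = structure_from_mol(mol)
    return Product(
        structure=product_structure,
        sites_modified=tuple((rs.rule, rs.site.atoms) for rs in chosen),
        total_delta_m_nominal=sum(rs.rule.transform.delta_m_nominal for rs in chosen),
        total_delta_m_monoisotopic=sum(
            rs.rule.transform.delta_m_monoisotopic for rs in chosen
        ),
        completeness="FULL" if len(chosen) == n_total_sites else "PARTIAL",
    )


# ---------------------------------------------------------------------------
# Expected-outcome summary (the matcher's view of a candidate)
# ---------------------------------------------------------------------------


class ExpectedKind(str, Enum):
    NO_REACTION = "NO_REACTION"
    SHIFT_SET = "SHIFT_SET"
    CLEAVAGE_PEAKS = "CLEAVAGE_PEAKS"


@dataclass(frozen=True)
class ExpectedOutcome:
    reagent_id: ReagentId
    kind: ExpectedKind
    acceptable_shifts: tuple[int, ...] = ()
    full_shift_nominal: int | None = None
    cleavage_peak_masses: tuple[int, ...] = ()
    retention_direction: RetentionDirection = RetentionDirection.NONE
    n_reliable_sites: int = 0
    n_unreliable_sites: int = 0

    @property
    def reliable(self) -> bool:
        """False when every contributing rule is flagged unreliable."""
        if self.kind is ExpectedKind.NO_REACTION:
            return True
        return self.n_reliable_sites > 0


def _shift_sums(
    site_choices: Sequence[tuple[int, ...]], full_only: bool
) -> tuple[set[int], int]:
    """All achievable total shifts over site subsets, and the full primary sum."""
    full_sum = sum(choices[0] for choices in site_choices)
    sums: set[int] = set()
    n = len(site_choices)
    subset_sizes = [n] if full_only else range(1, n + 1)
    for k in subset_sizes:
        for combo in itertools.combinations(site_choices, k):
            for picks in itertools.product(*combo):
                sums.add(sum(picks))
    return sums, full_sum


def expected_outcome(
    structure: Structure, reagent: ReagentId | Reagent, rules: RuleSet
) -> ExpectedOutcome:
    """Compact matching summary: outcome kind, acceptable total Δm values
    (full product, partial products, and accepted alternates), cleavage peak
    masses, and the retention-direction hint."""
    reagent_id = reagent.id if isinstance(reagent, Reagent) else reagent
    retention = REAGENTS[reagent_id].retention_shift_direction
    sites = reactive_sites(structure, reagent_id, rules)
    if not sites:
        return ExpectedOutcome(reagent_id, ExpectedKind.NO_REACTION)
    if len(sites) > MAX_ENUMERATED_SITES:
        raise SiteOverflowError(
            f"{len(sites)} reactive sites exceed the enumeration cap of "
            f"{MAX_ENUMERATED_SITES}"
        )
    reliable = [s for s in sites if s.rule.reliable]
    unreliable = [s for s in sites if not s.rule.reliable]

    if any(s.rule.outcome is OutcomeKind.CLEAVAGE for s in reliable):
        full = predict_products(structure, reagent_id, rules, ProductMode.FULL_ONLY)
        masses = tuple(
            sorted(
                {
                    f.structure.nominal_mass
                    for p in full
                    for f in p.fragments
                    if f.gc_visible
                }
            )
        )
        return ExpectedOutcome(
            reagent_id,
            ExpectedKind.CLEAVAGE_PEAKS,
            cleavage_peak_masses=masses,
            retention_direction=retention,
            n_reliable_sites=len(reliable),
            n_unreliable_sites=len(unreliable),
        )

    pool = reliable if reliable else unreliable
    choices = [s.rule.shift_choices() for s in pool]
    sums, full_sum = _shift_sums(choices, full_only=reagent_id is ReagentId.TFAA)
    return ExpectedOutcome(
        reagent_id,
        ExpectedKind.SHIFT_SET,
        acceptable_shifts=tuple(sorted(sums)),
        full_shift_nominal=full_sum,
        retention_direction=retention,
        n_reliable_sites=len(reliable),
        n_unreliable_sites=len(unreliable),
    )
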