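# Methods

## Scope and model

`derivid` models derivatization-based functional-group identification at the
level of **molecular ions only**: a compound is a graph with a nominal mass,
a derivatization either shifts that mass by a reagent- and group-specific
amount, cleaves the molecule into fragments, or does nothing. Electron-
ionization fragment spectra, chromatographic peak shapes, yields, kinetics
and reaction conditions are outside the model; retention-time direction is
carried only as a soft, qualitative hint.

Six O-functionalities are discriminated: hydroxyl (OH), carboxylic acid
(COOH), aldehyde (CHO), ketone (COC), carboxylic ester (COOR), and ether
(ROR). Amine/thiol chemistry is an extension point, not implemented.

## Functional-group detection

Groups are matched with SMARTS patterns in the fixed precedence
COOH > ester > CHO > ketone > OH > ether; atoms consumed by an earlier match
are excluded from later patterns. This makes the census well-defined for
shared atoms: a carboxylic acid is never additionally an OH plus a carbonyl,
an ester never an ether plus a carbonyl. Oxygens that fit none of the six
classes (e.g. the two acetal oxygens of a dimethyl-acetal product) are
counted in `unassigned_oxygens` rather than dropped. Only explicit O–H on
carbon counts as hydroxyl — enols and hemiketals are not special-cased; no
fixture contains one. Phenolic vs aliphatic OH is distinguished by aromatic
attachment for reporting; both feed the same reaction rules. Site flags mark
chemistry-relevant context: `ORTHO_OH_ARYL_KETONE` (an aryl ketone with an
ortho phenol, which enables enol O-methylation via keto-enol
tautomerization), `ARYL_ESTER` (good leaving group for hydrolysis),
`ALKYL_KETONE` (informational).

Aromaticity perception and SMILES canonicalization are delegated to RDKit's
defaults; fixture SMILES are stored pre-canonicalized so the test surface is
pinned.

## The reaction rule matrix

Every (reagent, group) cell of the 6 × 6 matrix is explicit — SHIFT,
CLEAVAGE, or NONE — so there are no silent gaps. Rules that shift the mass
carry a structural transform (a graph edit), and the per-site Δm is
*derived* from the atoms the transform adds and removes; the test suite
verifies, for every rule × fixture pair, that the mass of the edited product
graph equals educt mass plus the tabulated shift. Design choices worth
recording:

* **Aldehyde +46 (TMSH / DMF-DMA)** is implemented as dimethyl-acetal
  formation (replace C=O by CH(OMe)₂): the unique simple graph edit
  consistent with the observed +46 per site.
* **TFAA** is hydroxyl-selective and always exhaustive. The per-site shift
  is +96 from the O-trifluoroacetylation edit (add C₂F₃O, lose H); the
  +192 figure often quoted for this chemistry is the two-site (diol) total,
  and both numbers are surfaced in the rule's note rather than reconciled
  silently.
* **+18 alternates.** Methylation chemistry sometimes shows +18 instead of
  +14; no adduct structure is claimed for it, so +18 is modeled as an
  accepted alternate Δm on the methylation rules (TMSH OH/COOH/ketone,
  DMF-DMA COOH), not as a transform.
* **Ketones.** With an ortho-phenol flag, TMSH performs enol O-methylation
  (+14, net CH₂, requires an sp3 α-carbon with H). All other ketones get a
  SHIFT rule with accepted shifts {+14, +18} and *no* transform
  (`unresolved_adduct`): a shift is expected but no product structure is
  claimed, and no product enumeration is possible.
* **DMF-DMA** methylates carboxylic acids (and shows the +46 aldehyde
  response) but not hydroxyls or ketones; the OH cell is NONE, which is what
  makes step 4 of the pathway discriminating.
* **Hydrolysis (NH₄OH)** cleaves the acyl–O bond and adds water across it.
  The alcohol fragment is the observable peak; the acid fragment is flagged
  not GC-visible. By default all esters cleave; the option
  `good_leaving_group_only` restricts cleavage to aryl esters for samples
  where sterically hindered esters are expected to resist.
* **Imine formation (borate + amine)** condenses the aldehyde with a
  configurable primary amine (benzylamine, aniline, 2,4-difluorobenzylamine);
  Δm is computed as amine mass − H₂O (benzylamine: +89). The rule — like
  TMSCHN₂ on aldehydes — is flagged `unreliable`: it never drives a
  classification branch or a strict filtering verdict, only confidence.

Partial conversion is first-class: `predict_products` in `ALL_PARTIAL` mode
enumerates every non-empty subset of reactive sites (capped at 8 sites,
2⁸ subsets; beyond that a `SiteOverflowError` is raised rather than
truncating silently — real analytes in this mass range carry ≤ 3 sites).
TFAA ignores the mode and always reacts exhaustively. Rule sets serialize
to JSON and round-trip bit-exactly.

## Classification

`classify` is a deterministic traversal of the decision pathway with a
complete trace; each branch cites the observation that justified it, and the
result is independent of the order observations are supplied. Mass matching
uses a ±0.5 Da tolerance by default (unit-mass single-quadrupole data); the
tolerance is per-observation, so high-resolution data can use tighter
values. Matching is against the acceptable-shift *set* (full, partial, and
alternate shifts), so a partially converted diol (+14) still routes to the
hydroxyl branch.

Where the linear pathway under-determines a combination (a compound carrying
both TFAA- and TMSH-reactive groups), the implementation subtracts the
hydroxyl methylation contribution implied by the TFAA count from the TMSH
shift and interprets the residual: +14k/+18k with DMF-DMA silent → ketones;
+46k or a DMF-DMA +46 response → aldehyde; an unexplainable residual stays
INCONCLUSIVE. Retention-direction mismatches and disagreeing supportive
reagents downgrade CONFIRMED to SUPPORTED but never flip a call; ether is
only ever established by elimination. Mutually impossible observations
(TMSH silent yet TFAA shifted) produce a structured contradiction result
naming the clashing pair.

`consistent_group_multisets` is the supported path for multifunctional
unknowns: it brute-forces all group multisets up to `max_groups` (default 3)
and keeps those whose predicted response under every observed reagent —
computed structure-free from per-group shift contributions, with partial
subsets allowed and unreliable chemistry treated as optional — matches the
data within tolerance.

## Candidate filtering

Each candidate is forward-predicted under every observed reagent and scored
MATCH / MISMATCH per reagent; unreliable rules score `UNRELIABLE_RULE` and
are excluded from the tested count. STRICT mode (default) retains a
candidate only if *every* tested reliable prediction matches — the workflow
is conjunctive — while LENIENT mode retains at a score threshold (default
0.75) for noisy or partial data. A candidate whose formula mass contradicts
the parent ion is scored and reported (with `parent_match = False`), not
silently dropped. An empty observation set is vacuous consistency: retained,
flagged `not_tested`. Candidates with identical predicted chemistry are
intentionally indistinguishable — the filter returns equivalence classes,
never a forced unique answer. Adding observations can only shrink the
strictly retained set (verified as a property test).

## The simulator

`simulate_observations` emulates the molecular-ion-level outcome of a GC-MS
measurement series: for each reagent in the panel it converts reactive sites
(all of them in `FULL` mode; independently with probability `p` in
`PARTIAL` mode — except TFAA, which is always exhaustive), sums the realized
per-site shifts, and emits SHIFT / NO_CHANGE / NEW_SMALLER_PEAK observations
with the reagent's retention direction. Gaussian noise of `mass_noise_sd`
(default 0 → exact nominal integers) is added to every emitted mass. All
randomness flows from one seeded `numpy` generator, so a fixed config is
byte-reproducible. Unreliable rules emit no signal: the simulator represents
only chemistry the method itself trusts. What the simulator does **not**
emulate — EI fragmentation, co-elution, matrix effects, detector response,
peak-assignment ambiguity in mixtures — bounds what passing round-trip tests
show: they validate the logic of the workflow, not its performance on real
chromatograms. In particular, pairing of product peaks to parent compounds
in a mixture is assumed given.

## Fixtures and problem sizes

The packaged fixtures are the 18 commercially available C₁₂H₁₀O₂ isomers
(five diols, two arylacetic acids, two methyl naphthoates, two naphthyl
acetates, two ortho-hydroxy aryl ketones, two methoxy carbaldehydes, three
phenoxyphenols) and a 10-compound validation mix carrying up to three
functionalities per structure. SMILES were derived once from the published
IUPAC names and frozen; "4-bromphenol" is read as 4-bromophenol. Truth
tables are hand-annotated group counts, checked exactly against the
detector. All tests and the acceptance script run on these 28 structures —
desk scale, deterministic, seconds of CPU; no instrument data or network
access is involved anywhere.

## Known limitations

* Nominal-mass arithmetic is the default throughout; monoisotopic masses are
  computed and carried but the decision logic matches at unit-mass
  tolerance unless configured otherwise.
* The element table covers C, H, N, O, F, S, Cl, Br — organics within the
  method's GC-amenable scope. Other elements raise `UnknownElementError`.
* Group detection is 2D and tautomer-naive; stereochemistry is carried
  through canonical SMILES but never used.
* The classifier counts groups only where a counting signal exists (TFAA's
  +96/site); co-occurring groups without such a signal may remain
  INCONCLUSIVE, which is the honest answer the data supports.
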