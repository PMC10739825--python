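# derivid

Reactivity-based identification of oxygen-bearing functional groups for
GC-MS non-target screening (NTS).

## The problem

In NTS an unknown peak first yields a molecular formula; that formula then
admits many constitutional isomers — hundreds for something as small as
C₁₂H₁₀O₂ — and the analyst needs classifiers to prune the candidate list.
Chemical derivatization provides one: different O-functionalities react
diagnostically with different reagents, and each successful reaction moves
the molecular ion M⁺ by a reagent- and group-specific mass shift Δm. By
measuring the sample underivatized and after a small panel of fast
derivatizations, one can confirm or exclude functional groups without ever
identifying the compound first.

`derivid` implements this strategy in silico, for people who want to apply
(or simulate, or automate) the workflow on candidate structures:

* **chem_core** — structure parsing (RDKit), nominal/monoisotopic/average
  masses from a built-in element table, and precedence-resolved detection of
  the six group classes OH, COOH, CHO, ketone (COC), ester (COOR), ether (ROR).
* **reaction_rules** — the six-reagent reactivity matrix (TMSH, TMSCHN₂,
  DMF-DMA, TFAA, NH₄OH, borate + amine) as executable graph transforms.
  Every per-site Δm is derived from the atoms the transform adds and removes:

  | reaction | per-site Δm (nominal) |
  |---|---|
  | O-methylation of OH / COOH | +14 (observed alternate +18) |
  | aldehyde → dimethyl acetal | +46 |
  | OH → trifluoroacetate (TFAA) | +96 (a diol shifts +192) |
  | ester hydrolysis (NH₄OH) | cleavage → alcohol peak |
  | aldimine (borate + benzylamine) | +89 |

* **workflow** — the four-step decision pathway (TMSH → NH₄OH → TFAA →
  DMF-DMA) that turns per-reagent observations into group hypotheses with a
  full decision trace, plus brute-force enumeration of all group multisets
  consistent with the data for multifunctional unknowns.
* **candidate_filter** — scores each candidate structure by forward
  prediction against the observations and retains only consistent ones.
* **io_fixtures** — packaged fixtures (the 18 C₁₂H₁₀O₂ isomers and a
  10-compound validation mix with hand-annotated truth tables), a seeded
  observation simulator (full or partial conversion, optional mass noise),
  and SMILES/SDF/CSV readers and writers.
* **cli** — `derivid groups | derivatize | classify | filter | simulate |
  fixtures`.

## Worked example

An unknown at m/z 186 shifts by +28 after TMSH (retention later) and by
+192 after TFAA (retention earlier), and is silent to DMF-DMA:

```sh
derivid simulate --smiles "Oc1ccc(-c2ccc(O)cc2)cc1" --out obs.csv
derivid classify obs.csv
```

```
Decision pathway:
  [1] TMSH: shift — Δm +28: hydroxyl / carboxylic acid / ketone chemistry
  [3] TFAA: shift +96k — Δm +192 ≈ 96×2: 2 hydroxyl group(s)
  [4] DMF_DMA: no change — no acid methylation
Group calls:
  OH ×2: CONFIRMED (TFAA acylation shift counts 2 OH site(s))
```

The +192 TFAA shift is two trifluoroacetylations at +96 each, so the unknown
carries exactly two hydroxyl groups; the +28 TMSH shift (2 × 14) is fully
explained by methylating them, so no acid or ketone is left to call.
Filtering the 18-isomer candidate list against the same observations:

```sh
derivid fixtures --name c12h10o2_isomers --out isomers.smi
derivid filter isomers.smi obs.csv
# → retained 5/18 (reduction 72%)
```

Only the five diols survive; acids, esters, carbaldehydes, ethers and
hydroxy-ketones all predict outcomes that contradict at least one
observation.

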