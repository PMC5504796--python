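# lipidrules

Rule-based lipid identification for untargeted LC-MS/MS lipidomics.

Untargeted lipidomics experiments produce a *feature table* (peaks defined
by m/z and retention time, from peak-picking software such as MZmine or
XCMS) and tandem-MS spectra from data-dependent acquisition (`.ms2` text
files, e.g. from MSConvert). Because synthetic standards exist for only a
tiny fraction of the lipidome, identification relies on *in silico
fragmentation libraries*: for each lipid species and adduct, the exact
theoretical m/z of the precursor ion and of its structurally indicative
fragments. `lipidrules` generates such libraries for acyl-containing
lipids — including oxidized species — and annotates feature tables against
them with explicit, user-editable fragmentation rules.

It is aimed at analytical chemists running orbitrap or Q-TOF LC-MS/MS
lipidomics who want annotations that never claim more structure than the
observed fragments support, and who need all co-eluting candidates for a
feature reported and ranked, not just a single best hit.

## Method

For each feature *f* = (m/z, RT) and each library entry (species ×
adduct) the pipeline:

1. **Precursor match** — pairs *f* with every entry whose theoretical
   precursor m/z lies within an absolute tolerance (Da) of the feature
   m/z, restricted to adducts of the run's polarity.
2. **Scan assignment** — collects MS/MS scans with |RT − RT_f| ≤ RT
   window and |isolation target − m/z_f| ≤ half the isolation width.
3. **Fragment profiling** — for every theoretical fragment, counts scans
   containing a peak within a ppm window and records the maximum
   intensity, mean observed m/z and RT at the maximum.
4. **Thresholding** — a fragment is *observed* if its maximum intensity
   and scan count meet the thresholds (defaults: intensity 1000, 1 scan).
5. **Rule evaluation** — per class/adduct, n-of-m groups over fragment
   labels. E.g. PC as [M+HCO2]⁻ requires both fatty-acyl carboxylate
   anions (R1COO⁻ and R2COO⁻); protonated PC requires the m/z 184.0733
   phosphocholine head-group ion plus one acyl-indicative neutral loss.
6. **Confidence coding** — 1 = class + fatty-acyl constituents
   (`PC(16:0_22:6)`, "_" marks unknown sn-position); 3 = class only
   (`PC(38:6)`, sum composition); 4 = precursor m/z only; 2 is reserved
   for data-independent acquisition and never emitted. Annotations are
   downgraded to sum composition whenever chain evidence is missing.
7. **Ranking** — co-eluting candidates for one feature are ordered by the
   summed maximum intensity of **all** matched in silico fragments,
   including fragments not required for confirmation.

All ion m/z values carry the electron-mass correction (0.00054858 Da per
charge); without it the 4th decimal of reference values such as 850.5604
([M+HCO2]⁻ of PC(16:0/22:6)) and 184.0733 is wrong.

Libraries contain exact m/z only (no predicted intensities) and are plain
CSV, so custom classes and rules are a text edit away. Shipped classes:
PC, PE, PS, PG, PI, PA, LPC, LPE, SM, Cer, MG, DG, TG, CE plus oxidized
PC and TG (hydroxyl/hydroperoxide/epoxide-or-keto additions and
short-chain aldehyde/carboxyl cleavage products of unsaturated chains).

## Worked example

Simulate a classic co-elution case — two PC(38:6) isomers behind one
feature at m/z 850.5604 — and annotate it:

```sh
$ lipidrules simulate --scenario two-isomer --seed 7 --out demo/plasma
features: demo/plasma/sim_neg.csv
ms2: demo/plasma/sim_dd_neg.ms2
manifest: demo/plasma/sim_manifest.csv

$ lipidrules annotate --dir demo --classes PC
jobs: 1; features: 1; feature-lipid pairs: 6; identifications by confidence: {1: 2}
```

The annotated table (`demo/plasma/output/sim_neg_annotated.csv`) keeps
every input column and appends the results:

```
row ID    row m/z  row retention time top_annotation  top_confidence                                                              all_ids
  SIM1 850.560358                5.92  PC(16:0_22:6)               1 1|PC(16:0_22:6)|[M+HCO2]-|128650.5;1|PC(18:2_20:4)|[M+HCO2]-|83244.4
```

Six isobaric library candidates matched the precursor; exactly the two
planted isomers had both chain carboxylates above the intensity threshold,
so both are reported at confidence 1 — ranked by summed fragment
intensity (128650.5 vs 83244.4), matching the planted abundance order.
A per-class fragment table (`sim_neg_PC_fragments.csv`) records every
(feature, candidate, fragment) observation: scan counts, maximum
intensity, mean observed m/z and RT at maximum.

Other subcommands: `build-library` (write the in silico library CSV and
editable class/rule configs), `combine` (align two feature tables by
ppm/RT windows and append another tool's annotations), and `simulate
--scenario shared-fragment|off-apex` for the documented ranking
pathologies.

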