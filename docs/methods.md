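# Methods

## Mass model

All masses are computed from an embedded monoisotopic atomic-mass table
(IUPAC/CODATA values: C 12, H 1.00782503207, N 14.0030740048,
O 15.9949146196, P 30.97376163, S 31.97207100, Na 22.9897692809, …), so
generated library files are reproducible bit-exact across machines. Ion
m/z is `(M + Δ_adduct)/z` with the electron mass (0.00054857990907 Da)
folded into every adduct delta — subtracted per charge for cations, added
for anions. Fragment ions specified by elemental composition get the same
per-charge electron correction. Omitting the electron shifts singly
charged ions by ~0.00055 m/z, which is visible at the 4-decimal precision
used throughout lipidomics (e.g. the phosphocholine head-group ion is
184.0733, not 184.0739). Displayed m/z rounds half-up to 4 decimals;
library files store 6 decimals and matching always uses the stored value,
never the display rounding.

## Lipid assembly

A chain is a fatty acyl defined by carbon count, double bonds, linkage
and oxidation state. Its composition is the free fatty acid
C(n)H(2n−2d)O2, modified by:

- linkage: O-alkyl (plasmanyl) = −O +2H, O-alkenyl (plasmenyl) = −O.
  These deltas reproduce LIPID MAPS sum formulas (PC(O-34:1) =
  PC(34:1) − O + 2H; PC(P-34:1) = PC(34:1) − O); the per-class hydrogen
  bookkeeping of ether lipids is a convention of this package.
- oxidation: hydroxyl +O, hydroperoxide +2O, ketone-or-epoxide +O by
  default. The keto tautomer (+O, −2H) exists as the opt-in modification
  `O(keto)`; the default follows the common oxidized-lipid sum-formula
  convention of treating the single-oxygen addition as epoxide-like.
- short-chain termini (cleavage products): aldehyde CHO = +O −2H,
  carboxyl COOH = +2O −2H (so 18:1 Δ9 cleaves to 9-oxononanoic acid
  C9H16O3 and azelaic acid C9H16O4).

A lipid class is a backbone composition plus a chain count; the neutral
species is `backbone + Σ chain − n·H2O` (ester/amide condensation, with
the ether delta carried by the chain). Sphingolipids fix a d18:1
sphingoid base in the backbone and treat the N-acyl as the enumerated
chain, rendering `SM(d18:1/17:0)` at chain level and `SM(d35:1)` at sum
level.

## Library generation

Chain sets are multisets (combinations with repetition), so 18:0_20:0 and
20:0_18:0 are one species; for an n-chain class over a p-chain pool there
are C(p+n−1, n) sets. The shipped endogenous pool has 39 chains (6:0 to
28:0, up to 6 double bonds), giving 780 pairs and 10 660 triples; it is a
curation of commonly reported mammalian fatty acids and fully
user-replaceable.

Oxidized chains derive only from unsaturated parents: up to one
modification per double bond, products identical in elemental composition
collapsed (a hydroxyl and an epoxide oxygen are indistinguishable by
exact mass). Short-chain products cleave at each double-bond position of
a shipped Δ-position table, keeping the double bonds below the cleavage
site. Default oxidized-class libraries (OxPC, OxTG) combine exactly one
oxidized chain with endogenous co-chains — the dominant composition of
biologically observed oxidized species, and the choice that keeps the
library a few tens of thousands of entries instead of millions;
multi-oxidized species can be built explicitly through `build_library`.
OxTG ships as ammonium adducts only. Cardiolipin (4 chains) is supported
by the template mechanism but no default CL template is shipped.

Fragment templates come in six modes: fixed m/z, chain carboxylate anion,
chain acylium cation, precursor − constant, precursor − chain, and
precursor − chain − constant (a negative constant expresses ketene loss =
acid loss − H2O). Chain-indexed templates expand once per chain slot.
Class definitions and rules round-trip through documented CSV layouts so
users can add classes or change required fragments without touching code.

## Identification parameters

| parameter | default | units | notes |
|---|---|---|---|
| MS1 tolerance | 0.005 | Da | absolute, per the precursor-matching design |
| fragment tolerance | 10 | ppm | relative |
| RT window | 0.3 | min | scan assignment around the feature apex |
| isolation window | 1.0 | m/z | full width; matching uses half-width each side |
| min fragment intensity | 1000 | counts | analyzer-dependent; orbitrap-typical |
| min scans | 1 | — | raise for noisier analyzers |

Confidence 1 requires every rule group; confidence 3 requires all
class-indicative groups (when the rule has any) with chain evidence
missing; confidence 4 (precursor-only) is off by default and switched on
automatically for feature tables that have no MS2 file of matching
polarity. Confidence 2 is reserved for data-independent acquisition,
which this package does not implement.

Ranking sums, per candidate, the maximum intensity of every in silico
fragment seen in ≥ 1 scan — deliberately including fragments below the
confirmation threshold and fragments not required by the rule, because
the sum estimates the candidate's signal contribution to the feature, not
its identification confidence. Ties break lexicographically on annotation
text then adduct: a determinism guarantee, not a scientific claim. A
single experimental peak may serve multiple candidates' fragments; no
de-sharing is attempted, so shared fragments inflate the sums of all
sharers (see below).

## Synthetic data

The simulator plants library entries as Gaussian chromatographic peaks
(configurable apex, width σ in minutes, precursor intensity, per-fragment
intensity scale) and writes the exact file set the pipeline discovers:
feature table, `.ms2` scans at configurable RT offsets, and a manifest of
expected annotations, confidence codes and rank order. Peaks closer than
a small merge window (default 3 ppm) are summed, emulating co-added ion
current. Noise peaks are uniform in m/z and intensity; fragment m/z
jitter is Gaussian in ppm. One integer seed fixes everything;
byte-identical outputs are a tested invariant.

What it emulates: co-eluting isobars sharing a feature, shared fragments
between candidates, off-apex scan sampling, m/z jitter, uniform noise.
What it does not: isotope envelopes, chimeric co-isolation beyond planted
co-elution, intensity-dependent mass error, retention-time drift, or
realistic fragmentation efficiency. Passing tests therefore demonstrate
the correctness of the matching/rule/ranking logic under controlled
conditions, not identification accuracy on real spectra.

Three canonical scenarios exercise the documented behaviours:

- *two-isomer*: two PC(38:6) formate isomers on one feature, both
  recovered at confidence 1 and ranked by planted abundance;
- *shared-fragment*: three TG(52:2) isomers where a rare isomer shares a
  high-intensity neutral loss with the abundant one — its summed
  intensity is inflated and it overtakes a more abundant non-sharing
  isomer. This is expected behaviour of intensity-sum ranking and is
  asserted as such, not corrected;
- *off-apex*: scans taken at one lipid's apex sample the co-eluting
  lipid down its peak flank, reducing its summed intensity.

## Numerical and design choices

- Absolute Da at MS1 vs ppm at MS2 mirrors how the two tolerances are
  specified by acquisition software.
- When several peaks of one scan fall inside a fragment's ppm window, the
  most intense is taken.
- Filename conventions for discovery: `…neg`/`…pos` suffixes, or a single
  trailing `n`/`p` only when preceded by a non-letter (so `fusion.csv` is
  not negative mode); `dd`/`aif` substrings select acquisition mode;
  everything case-insensitive; non-conforming files are reported, never
  silently dropped.
- Retention times are minutes everywhere; an explicit flag converts
  `.ms2` files whose RTime lines are seconds — no unit heuristics.
- Cross-table alignment (`combine`) uses best-match semantics: smallest
  |ppm| (relative to the base feature), ties by |ΔRT|, then row order;
  one other-row may annotate several base rows. Appending never alters
  existing cells or row count.
- Feature tables are annotated strictly additively and row order is
  preserved; output column names (`top_annotation`, `all_ids`, …) are a
  convention of this package.

## Known limitations

- No spectral-similarity scoring, false-discovery modelling, isotope
  deconvolution, or in-source fragment/dimer handling.
- Rule defaults encode HCD/orbitrap fragmentation behaviour; other
  fragmentation modes may need edited rules.
- The shipped class set covers the common glycerophospholipid, glycerol
  ester, sphingolipid and sterol ester classes; everything else is
  user-addable via the template CSVs.
- Data-independent (AIF) spectra are discovered and reported but not
  processed.
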