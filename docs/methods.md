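# Methods

## The problem

Plant gums — arabic gum (Acacia exudate), tragacanth (Astragalus exudate)
and fruit tree gum (cherry/Prunus exudate) — were used for millennia as
paint binders. After acid hydrolysis and derivatisation, GC-MS yields the
relative monosaccharide composition of a paint micro-sample, and the gum
is recognised from that fingerprint. In practice the fingerprint is
distorted: pigments alter sugar recoveries during ageing and
derivatisation, proteinaceous co-binders (egg, glue, milk) contribute
their own sugars, and plant tissue (wooden supports, paper, straw,
airborne particulate) contaminates the profile, most visibly with xylose
and glucose. `gumid` implements a rule-based identification model that is
conditioned on this context, together with the reference data that
justify it.

## Data model

Profiles are relative percentages over a closed vocabulary of nine
sugars: xylose, arabinose, rhamnose, fucose, galacturonic acid,
glucuronic acid, mannose, galactose, glucose. Two analytical dialects are
represented: `GCI` (neutral sugars only) and `DCCI` (neutral sugars plus
uronic acids). *Missing* (not quantified) is distinct from a measured
zero. Glucose is carried for contamination evidence but excluded from all
marker logic and correlation vectors: reference replicas never report it
and it is ubiquitous in supports and microbial growth. In several case
records of the packaged database glucose is only a presence flag
(yes/no), because the source tables report it qualitatively.

All marker comparisons are made on values rounded to one decimal — the
precision of the tabulated data — and are strict: a value of exactly
1.0 % counts as trace.

## Reference database

105 replica records (3 gums × pigments × ageing regimes, two dialects)
and 53 historical case samples are packaged as CSV fixtures and verified
by integrity checks (counts per gum/case, unique keys, row sums within
printed rounding). Three defects of the printed source data are kept
verbatim and documented rather than repaired:

* one replica row (arabic, unpigmented, solar-box aged, DCCI) sums to
  113.6; it is whitelisted in the sum check;
* binning the printed replica correlations at their stated cut points
  (≥0.99 excellent, 0.96–0.98 good, <0.96 poor) yields 53/22/30, while
  the prose census says 53/21/31 — one borderline printed 0.96
  presumably sat below 0.96 unrounded;
* the prose range for arabinose (28.4–90.9 %) is contradicted by printed
  arabic rows down to 23.0 %.

One case row (97-2) is transcribed with galactose 0.0 and glucose 18.5:
the alternative column alignment (galactose 18.5) is inconsistent with
the published "not identified" result for that sample.

Case contexts (support, protein status, provenance plausibility, fungal
growth) are encoded to express the judgments evident in the published
case assignments: supports count as contaminating only where the
analysts treated them so (a cleanly sampled gouache on paper is not a
case-d sample; a polychromed wooden ushabti is), and straw confined to a
preparation layer is not flagged for a paint-layer sample.

## The decisional model

**Presence gate.** Arabinose and galactose occur in all three gums; a
profile lacking either cannot be called a gum. On failure the verdict is
*no saccharide binder* when arabinose is absent and a detected protein
source that carries galactose (animal glue via collagen glycosides, milk
via lactose) is present — then every major observed sugar has a non-gum
origin (xylose/glucose from plant contamination, mannose from egg or
milk). Egg alone cannot account for galactose, and a galactose-free but
arabinose-bearing profile is merely anomalous; both give *not
identified*.

**Markers.** X = xylose > 1.0 %, FU = fucose > 1.0 %, M = mannose >
1.0 %. Arabic gum: no marker. Tragacanth: X and FU. Fruit tree: X and M.
Rhamnose and the uronic acids are too unstable under pigments/ageing to
enter the rules, though the uronic acids re-enter as auxiliary evidence
at reconciliation.

**Schemes.**

* *a* (no proteins, no contamination): the three patterns above;
  anything else is not identified.
* *b* (protein status unknown): mannose may be egg-derived, so it can
  neither support a fruit-tree call nor be ignored — only the arabic
  (no markers) and tragacanth (X∧FU∧¬M) calls survive.
* *c* (proteins known): trace xylose → arabic regardless of mannose
  (the co-binder explains it); X∧FU → tragacanth if mannose is trace or
  explained by a paint-layer mannose source (egg, milk, cochineal);
  X∧¬FU∧M → fruit tree.
* *d* (contamination): xylose is uninformative. FU with trace or
  binder-explained mannose → tragacanth; no FU and trace mannose →
  arabic; no FU with mannose → *fruit tree or arabic* when any mannose
  source is available (including softwood support tissue, whose
  glucomannan mimics the fruit-tree marker), else fruit tree.

The asymmetry in scheme d — support tissue may explain mannose in the
fruit-vs-arabic split but not rescue a tragacanth call — is a
reconstruction choice validated against every published case row: a
glue-bound sample on wood with fucose and mannose is published as not
identified, while a protein-free sample on wood without fucose is
published as fruit-or-arabic.

**Scheme selection.** Case d whenever contamination evidence fires
(xyl/ara ratio above 1 with measurable arabinose, or a plant-derived
support, or straw); otherwise c if protein sources are identified, a if
proteins were analysed and absent, b otherwise. An arabinose-free profile
is not a ratio flag — it fails the gate instead, which keeps such samples
in the case their protein knowledge assigns.

**Correlation matching.** Pearson correlation over the sugars recorded
in both profiles (glucose excluded), both sides renormalized over the
shared set; at least three shared sugars are required. Quality bins:
≥0.99 excellent, 0.96–0.98 good, <0.96 poor, at two-decimal precision.
Matching is auxiliary: 31 of the 105 replicas correlate poorly with
their own gum, which is the model's argument for not classifying by
correlation alone. For the 53 encoded case samples, reconciliation uses
the correlation entries published with them (computed at the time
against reference vectors from an earlier campaign that are not part of
this database); freshly measured samples are matched against the 105
replicas. The metric is configurable in the API; Pearson is the default.

**Reconciliation.** In order: (1) single-gum and no-binder verdicts
stand; (2) *not identified* with a unique excellent (≥0.99) correlation
is promoted to that gum unless the uronic acids contradict it
(glucuronic acid >1 % fits arabic/fruit tree, galacturonic acid >1 %
fits tragacanth; only uronic-quantifying profiles testify); (3) a
*fruit-or-arabic* suggestion with mannose ≤ 3 % and an excellent arabic
correlation is promoted to arabic — the ceiling is a documented,
configurable choice bracketing the published promotions (mannose 1.4 and
2.0 promoted, 4.0 not); (4) a suggestion under fungal growth is
withdrawn to *not identified* (fungus floods profiles with glucose,
mannose and galactose); (5) a call for a gum implausible for the
provenance becomes *uncertain* (e.g. pre-contact Peru, where none of the
three modeled gums grew). Final calls are categorised as identified
(single gum or no-binder), suggestion (fruit-or-arabic, uncertain) or
not identified; summary percentages are truncated to integers, the
convention under which 28/53, 12/53 and 13/53 print as 52/22/24. An
object-level pass can additionally promote suggestions that agree with a
sibling layer's single-gum call; it never overrides conflicting
single-gum calls (multi-layer objects legitimately mix binders) and is
not applied before the summary.

## Mixtures

A mixture's profile is the saccharide-weighted mean of its components:
weight = mass fraction × saccharide content, renormalized to 100. Egg is
≈1 % saccharide (default), so in a 1:1 mass mixture with a gum (gum
saccharide contents default to the measured paint-layer recoveries:
arabic 0.65, tragacanth 0.23, fruit tree 0.62) it shifts each sugar by
at most ~1.5 points — yet that is enough to put mannose above the 1 %
marker cutoff, which is the whole failure mode the schemes guard
against. Contamination by fraction *f* of the saccharide content is the
linear blend (1−f)·gum + f·contaminant on the same basis. The published
theoretical mixture tables cannot serve as numerical oracles because the
component reference profiles (raw gums, proteins, woods) come from a
prior publication not reprinted with the model; mixture tests therefore
use synthetic components and the structural invariants (conservation,
convexity, monotonicity, and the 10 %-wood-defeats-xylose property).

## Synthetic samples

The generator draws a base profile from an unpigmented replica (or any
chosen record), resamples it on the simplex from a Dirichlet centred on
the base — keeping non-negativity and the sum constraint without
clipping; zero components stay zero — and optionally admixes a protein
or contaminant through the mixture arithmetic. The Dirichlet
concentration is mapped from a target standard deviation in percentage
points of a mid-abundance (40 %) component; the default (7.5) makes the
synthetic arabic population's arabinose span roughly the 25–55 % spread
seen across pigmented/aged arabic replicas. Component profiles for egg,
glue, milk and wood are synthetic stand-ins (plausible compositions
labelled as such), since the measured references are not available here.
What passing recovery tests show is therefore internal consistency of
the rules under compositional noise and admixture — not performance on
real aged paints, whose pigment-specific distortions (e.g. malachite
wiping out mannose and galactose) are represented only insofar as they
are present in the replica base profiles.

Recovery experiments run the full pipeline on n samples per gum
(default contexts declare exactly what the recipe admixed). At zero
noise recovery is 100 % for all three gums; mean recovery degrades
monotonically across the tested noise levels (0, 5, 15 points, fixed
seeds, n = 100 per gum, < 1 s). Undeclared egg under scheme a turns
tragacanth samples into *not identified* — never into a wrong gum —
reproducing the documented failure mode that motivates scheme c.

## Numerical choices

* Marker and gate comparisons at one-decimal precision, strict
  inequalities.
* Correlations rounded to two decimals before binning and tie-breaking;
  best-match ties broken by lexicographic replica key, so results are
  independent of database order.
* Report threshold for "no match": 0.85 (the published tables print
  values down to 0.84–0.86 and "no" below; the exact cutoff is not
  stated and is exposed as an option).
* Percent summaries truncated, not rounded.
* Degenerate inputs: all-zero chromatograms, empty restrictions,
  sub-3-sugar overlaps and zero-variance vectors raise errors rather
  than returning sentinel values.

## Known limitations

* The scheme rules are a reconstruction from the published threshold
  prose plus all 53 published case rows; the graphic form of the
  original decision trees carries no machine-readable detail.
* Only arabic, tragacanth and fruit tree gums are modeled; honey,
  starch and regional gums (mesquite, cashew) are out of scope — the
  provenance rule can only flag them as *uncertain*.
* Protein identification is consumed as metadata, never inferred from
  sugars.
* Printed correlations for the case samples are trusted data;
  recomputation against the packaged replicas gives different values
  because the original reference vectors are not available.
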