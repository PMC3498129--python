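# gumid

Identification of saccharide paint binders — arabic, tragacanth and
fruit tree (cherry) gum — from GC-MS monosaccharide compositions of
paint micro-samples.

Conservation scientists hydrolyse a few micrograms of paint, derivatise
the released sugars and quantify them by GC-MS; the relative composition
(percent xylose, arabinose, rhamnose, fucose, uronic acids, mannose,
galactose, glucose) is the fingerprint of the binder. The fingerprint is
rarely clean: pigments distort sugar recoveries under ageing, egg or
glue or milk add their own sugars, and wooden supports, paper, straw and
airborne plant particulate contaminate the profile. `gumid` implements a
context-conditional, rule-based identification model for this situation,
together with a packaged reference database of 105 laboratory paint
replicas and 53 historical case samples that validate it.

## The model in brief

A profile passes a *presence gate* (arabinose > 0 and galactose > 0 —
both sugars occur in every gum), then three markers at a strict 1.0 %
relative cutoff drive the call:

| marker | meaning |
|---|---|
| xylose > 1.0 % | not arabic gum (unless contaminated) |
| fucose > 1.0 % | tragacanth |
| mannose > 1.0 % | fruit tree gum — *if* no egg/milk/cochineal/softwood can explain it |

Which rule tree applies depends on the sample context: **a** proteins
analysed and absent; **b** protein status unknown (mannose becomes
uninterpretable); **c** protein sources known (their mannose is
exempted); **d** contamination — plant-derived support, straw, or a
xylose/arabinose ratio above 1 — which makes xylose uninformative.
Pearson correlation against the replica database, uronic-acid auxiliary
markers, provenance plausibility and fungal growth then reconcile the
scheme verdict into a final call: a single gum, *no saccharide binder*,
a suggestion (*fruit tree or arabic*, *uncertain*) or *not identified*.

See `docs/methods.md` for the full rule set and its rationale.

## Worked example

`samples.csv`:

```csv
sample_id,dialect,xylose,arabinose,rhamnose,fucose,galacturonic_acid,glucuronic_acid,mannose,galactose,protein_analysed,protein_detected,protein_sources,support
ms-1,GCI,0.5,35.5,17.0,0.0,-,-,0.5,46.5,yes,no,,none
ms-2,DCCI,51.3,6.3,2.5,0.0,0.0,0.0,16.2,23.7,yes,yes,animal_glue,none
ms-3,DCCI,2.4,18.3,9.9,1.3,0.0,0.0,29.9,38.2,yes,yes,egg,plaster
```

```
$ gumid identify samples.csv
ms-1: scheme a → arabic   [markers: xylose ≤ 1.0%, fucose ≤ 1.0%, mannose ≤ 1.0% | no marker above cutoff → arabic gum]
ms-2: scheme d → fruit_tree   [markers: xylose > 1.0%, fucose ≤ 1.0%, mannose > 1.0% | unexplained mannose → fruit tree]
ms-3: scheme c → tragacanth   [markers: xylose > 1.0%, fucose > 1.0%, mannose > 1.0% | mannose explained by egg → tragacanth]
```

ms-1 has every marker at trace level: arabic gum under scheme a. ms-2's
xylose/arabinose ratio (8.1) flags contamination, so scheme d ignores
xylose; its mannose has no non-gum source (glue contributes none), so it
is fruit tree gum. ms-3 contains egg, which exempts the mannose and
leaves the fucose to indicate tragacanth. `gumid interpret samples.csv
--out report.csv` adds the replica correlations, the reconciled final
call and a category summary footer; the same functions are available
from Python (`gumid.identify`, `gumid.identify_case`,
`gumid.best_matches`, ...).

Other subcommands: `gumid db check` / `gumid db export` (packaged
reference tables), `gumid mix` (theoretical mixture profiles on the
saccharide basis), `gumid simulate` (seeded synthetic samples with
compositional noise and protein/contaminant admixture).

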