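# Methods

## Token grammar

SMILES has no single canonical tokenization; this package fixes one and
documents it. Outside brackets, atom tokens are the organic subset
(`B C N O P S F I`), the two-character halogens `Cl`/`Br` as single
tokens, the aromatic symbols `b c n o s p`, and the wildcard `*`. A ring
closure is one token — a digit, or `%` plus two digits; a bond symbol
before a ring digit (`=1`) stays a separate token. Inside a bracket group
exactly one token is an atom (any element symbol, longest match first, or
a two-letter aromatic like `se`); isotope digit runs, `@`/`@@` chirality
marks, `H`-counts (`H`, `H2`) and charge groups (`+`, `-`, `+2`, `++` —
one token per sign group) are separate non-atom tokens. `H` is the atom
only when it occupies the element position (`[H]`, `[2H]`). Atom-map
suffixes (`[CH3:1]`) are outside the grammar and raise a lexing error.

Two invariants anchor everything downstream: concatenating token texts
reproduces the input exactly, and the number of atom tokens equals the
atom count of the parsed molecular graph. To keep the second invariant the
molecule is parsed with explicit hydrogens retained
(`SmilesParserParams(removeHs=False)`); default parsing drops `[H]` atoms
and would desynchronize atom indices from atom tokens. The input string is
never re-canonicalized — scores are bound to the string as given, since
re-writing the SMILES would scramble the score order.

## Hover semantics

Highlights are resolved to explicit token/atom index sets at render time:

* *atom token* → its atom; if the token sits in a bracket group, the whole
  group (the group's tokens and its single atom) — hovering any token of
  `[N+]` highlights the nitrogen.
* *parenthesis* → the matched branch span (stack matching), atoms of all
  atom tokens inside, nested branches included.
* *ring digit* → both partner digits (paired by number, honouring number
  reuse) and the atoms of the smallest perceived ring (SSSR) containing
  the closure bond; among equally small rings the one with the lowest
  atom-index sum is chosen, a deterministic tie-break. Ring *atoms* are
  highlighted, not ring bonds; highlighting bonds as well would be a
  reasonable alternative.
* *bond/dot* → the token plus the string-adjacent atom tokens (none for a
  lone dot). For a bond written before a branch or ring digit this is the
  string neighbourhood, not the graph bond — a deliberate simplification.

Atom coordinates come straight from the toolkit's 2-D conformer (and, for
rendering, from the drawing object's pixel transform), not from parsing
depiction SVG text.

## Scores, domain, thresholds

Input vectors may be per-atom or per-token; any other length is an error
naming both admissible lengths. Per-atom vectors are spread with exact 0.0
on non-atom tokens, conserving the score sum. Normalization divides each
sign by its own domain bound (asymmetric domains are allowed; the built-in
default is symmetric at max |s|) and clamps to [−1, 1]; an all-zero vector
falls back to the domain (−1, 1) with a warning. Threshold comparison is
inclusive (|s| ≥ τ·d₊), matching the worked example "greater or equal";
exactly-zero scores are never highlighted, so τ = 0 selects precisely the
atoms with nonzero attribution and highlight sets are nested in τ.

## Color

Built-in palettes are three colorblind-friendly diverging 5-color schemes
with Color Brewer anchors (`red_blue`, `pink_green`, `purple_orange`);
their hex values are a repository convention. Custom palettes must be
odd-length (neutral middle). Interpolation runs in CIELAB: chroma (a*, b*)
follows the anchors of the relevant half piecewise-linearly, while L* is
replaced by a linear ramp from the neutral middle's lightness to the
endpoint's — this is the "lightness correction" that makes perceived
intensity strictly monotone in |normalized score| (checked numerically in
the tests). Endpoint and neutral colors are returned exactly at |t| ∈
{0, 1}.

## Rendering

Panels are assembled by a small deterministic string builder (fixed
two-decimal float formatting, ordered attributes), so identical inputs give
byte-identical SVG — a property the tests assert. Layer order is negative
heatmap, positive heatmap, threshold circles, structure drawing, score
labels, hover overlays: color fields sit beneath the skeletal drawing so
bond lines stay crisp. The heatmap kernel is one radial gradient per atom,
radius 0.9 × median bond length (in drawing pixels), peak opacity 0.75 ×
|normalized score|, fading to transparent; overlapping marks blend
naturally in SVG compositing. Threshold circles are white-stroked with
radius r₀ + k·(|normalized| − τ), r₀ = font size, k = one bond length —
only the monotone growth is semantically meaningful. Numeric atom labels
use two decimals. The HTML gallery embeds each panel's hover map as JSON in
a `<metadata>` element plus hidden two-ring overlays per atom (inner ring
in the score's sign color, outer ring in a fixed contrasting highlight
color); the generated script only toggles CSS classes, so all highlight
decisions remain server-side and unit-testable. Standalone SVG files carry
the same data and degrade to static images.

## Substitution attribution

Substitution occludes the token's *text* in the raw string — a string
edit, not a graph edit — so substituted strings can be invalid; invalid
ones are skipped, and a position where every substitution fails scores 0.0
with a logged warning. The original token is not excluded from the
vocabulary average. Means use exact (`fsum`) summation, which makes
vocabulary-order invariance hold exactly in floating point. The predictor
is a plug-in contract (callable + vocabulary); the bundled toy predictor
returns the Crippen logP of the parsed string with a 12-token atoms-only
vocabulary. With that vocabulary, valid substitutions at
symmetry-equivalent positions yield isomorphic molecules, so equivalent
atoms receive *exactly* equal scores — the property the symmetry test
asserts on hexabromobenzene. Per-atom Crippen logP contributions are
computed on the hydrogen-complete molecule with each hydrogen's share
folded into its heavy neighbour, making the vector sum exactly to the
molecule-level Crippen logP.

## Demo data

`make_fixtures(n, seed, method)` draws molecules from a fixed list of 36
drug-like SMILES covering the full grammar (rings, `%nn` closures, nested
branches, charges, isotopes, chirality, directional bonds, salts) and
attaches Crippen per-atom scores, substitution scores against the toy
predictor, or seeded standard-normal per-token scores. Record *i* depends
only on (seed, *i*), so record lists are prefix-stable in *n*. The property
test fixture set expands the list combinatorially (scaffold × substituent)
to 276 distinct valid strings. These fixtures exercise syntax, not
chemistry: passing tests show the machinery is correct on realistic
strings, not that any particular model's attributions are meaningful, and
scores from the toy logP predictor are stand-ins for real model output.

## Input format

The JSON schema (see `docs/input_schema.json`) is versioned via
`schema_version`; a record carries `smiles`, `scores`, optional ordered
`attributes`, an optional per-record `config` override and an optional
`id` (defaulting to the record index). Validation checks the score length
against both admissible lengths; the default loading mode skips invalid
records with a warning, strict mode aborts on the first. Unknown fields
round-trip unchanged. Byte-compatibility with any other tool's JSON layout
is not claimed.

## Problem sizes and limitations

Tests and the acceptance script run on desk-scale inputs: single molecules
up to ~40 tokens, fixture sets of a few hundred strings, substitution
attribution at |tokens| × |vocabulary| ≈ a few hundred predictor calls.
Known limitations: no SELFIES/InChI tokenization; no per-bond scores; no
live notebook widgets or pan/zoom; visual equivalence with any external
drawing stack is not a goal (heatmap appearance depends on the kernel
parameters above); extended bracket chirality tags (`@TH1` etc.) are not
lexed.
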