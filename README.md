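# smilight

Coordinated visualization of attribution scores on SMILES strings.

XAI methods for molecular property models assign attribution (sensitivity,
contribution) scores either to the atoms of a molecule or to the tokens of
its SMILES string. Atom scores can be painted onto a structure diagram, but
SMILES-based models also score *non-atom* tokens — brackets, ring-closure
digits, parentheses, charges — which have no place on a diagram: the
substring `[N+]` contains one atom token and three non-atom tokens, and
their scores need not say anything about the nitrogen. smilight renders
both kinds of score in one panel: a 2-D molecule diagram drawn over
per-atom heatmap layers, coordinated with a bar chart that shows one bar
per SMILES token, plus an optional attributes table. Token ↔ substructure
highlighting (atom, branch, bracket group, ring) is resolved ahead of time
into explicit index sets and embedded in the output, so the interactive
HTML gallery needs no runtime structure analysis.

It is a library plus a small CLI, aimed at data scientists and
computational chemists who want to screen model explanations across sets
of molecules.

## The model

For a SMILES string with tokens *t₁…tₙ* and scores *s₁…sₙ* (a per-atom
vector is spread onto the atom tokens with 0 elsewhere):

* **Colormap domain** *(d₋, 0, d₊)*: positive scores are normalized as
  *s/d₊*, negative as *s/|d₋|*, clamped to [−1, 1]. By default *d₊ = |d₋|*
  = max |sᵢ| over the molecule. Scores outside the domain get full bar
  height and the strongest palette color, so a deliberately tiny domain
  displays sign only.
* **Diverging palettes** are odd-length color lists with a neutral middle;
  interpolation runs in CIELAB with lightness forced to decrease
  monotonically from the middle toward each endpoint.
* **Thresholds** are fractions *τ ∈ [0, 1]* of the domain maximum: an atom
  is highlighted when |sᵢ| ≥ τ·d₊ (e.g. τ = 0.5 under domain (−0.5, 0, 0.5)
  highlights |s| ≥ 0.25), marked by white circles on the diagram and
  horizontal guide lines on the bar chart (defaults 0.5 and 1.0 when no
  thresholds are set).
* **Substitution attribution** scores token *i* of a black-box predictor
  *f* as *f(x) − mean_v f(x with token i replaced by v)* over a token
  vocabulary, skipping substitutions that produce invalid SMILES. Per-atom
  Wildman–Crippen logP contributions are provided as an additive
  comparator (they sum exactly to the molecule's Crippen logP).

## Worked example

```sh
$ python examples/03_scores_and_colors.py
token scores: (0.1, 0.0, 0.2, 0.6, 0.0)
default domain: (-0.6, 0.6)
normalize(0.6) in (-0.33, 0.33): 1.0
color at 0.6 (clamped to endpoint): #ca0020
color at 0: #f7f7f7
threshold 0.5 under domain (-0.5, 0, 0.5) cuts at |score| >= 0.25
```

The 3-atom vector `[0.1, 0.2, 0.6]` is spread over the 5 tokens of
`C1CC1` (ring digits get 0.0). The default domain is ±0.6 — the max
absolute score. Overriding the domain to (−0.33, 0.33) clamps the 0.6
score to normalized 1.0, i.e. a full-height bar in the strongest positive
red; a zero score maps to the neutral near-white middle.

From the shell:

```sh
smilight fixtures --n 4 --method crippen --out fixtures.json
smilight render fixtures.json --out out/ --format both -t 0.5
smilight inspect "C1CC1"
```

`render` writes one standalone SVG per molecule and a self-contained
`gallery.html` with hover highlighting; `inspect` prints the token table
and what each token highlights. See `examples/` for library usage, one
script per capability.

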