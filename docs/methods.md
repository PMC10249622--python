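# Methods

This note documents the models and conventions behind `mxprime`, the
defaults that matter, and what the synthetic fixtures do and do not show
about real data.

## Diagnostic-site model

A site is diagnostic for species *t* when (i) the modal residue of *t* at
that column reaches a conservation fraction ≥ `min_conservation` of the
non-gap residues (default 1.0: fully fixed within the species), and (ii)
that residue's share in every other species is ≤ `max_nontarget_share`
(default 0: strict absence). Gaps never count as diagnostic residues, and a
gap-majority target column never qualifies. Ambiguity codes count toward the
modal residue only on exact code equality — diagnosis is deliberately
conservative, while annealing prediction elsewhere is permissive
(intersection matching). The two thresholds exist because real alignments of
field data rarely contain perfectly fixed differences at every useful
column; the strict defaults reproduce the fixed-difference sites a careful
visual inspection of a clean alignment identifies.

Both knobs are monotone: tightening either can only shrink the returned
site set (property-tested).

## Primer thermodynamics and structure

* **Wallace rule** (default): Tm = 2·(A+T) + 4·(G+C) °C — the quick screen
  primer-analysis tools report for short oligos. Ambiguity codes contribute
  fractionally via |set ∩ {G,C}|/|set|.
* **Nearest-neighbor Tm**: two-state model with the unified DNA/DNA stack
  table (ΔH kcal/mol, ΔS cal/mol/K), terminal initiation terms, a −1.4
  cal/mol/K symmetry correction for self-complementary oligos, the entropic
  salt correction ΔS′ = ΔS + 0.368·(N−1)·ln[Na⁺], and
  Tm = 1000·ΔH/(ΔS′ + R·ln(Cₜ/x)) − 273.15 with x = 4 (x = 1 for
  palindromes). Defaults: 50 mM Na⁺, 0.25 µM total strand. Unambiguous
  sequences only. Cross-checked in the tests against an independent
  thermodynamics library to ≤1e-6 °C on the shared parameterization.
* **Self-structure / dimers**: strict Watson–Crick pairing (G·T wobbles
  never pair; ambiguity codes pair when their base sets intersect under
  complementation). The dimer scan evaluates every ungapped antiparallel
  offset of one primer against the other and reports the longest
  complementary run, the most-paired offset's total, and whether a run
  touches either 3' terminus. Free-energy dimer models are out of scope —
  run length is what rule-based primer checkers flag.

### Default thresholds (calibrated against working panels)

QC windows: length 15–30 nt, GC 0.30–0.70, Wallace Tm 45–80 °C, 3'-window
(5 nt) G+C ≤ 4, self-complementary run ≤ 6. Dimer flags: any run ≥ 7, or a
run ≥ 6 touching a 3' terminus. These are deliberately permissive: the
packaged, wet-lab-validated panels contain a universal reverse with a 6-bp
self-complementary run, pairwise runs up to 6 bp, 3'-touching runs up to 5
bp, and a Wallace Tm spread of 52–80 °C — yet co-amplify cleanly at a
single annealing temperature. Defaults are therefore set just above what
these field-proven primers exhibit, so that a validated panel passes and
anything worse is flagged; users designing de novo should tighten
`DimerPolicy` and `QCConstraints`. The hairpin flag (stem ≥ 4, loop ≥ 3) is
reported but not a hard failure: three of the published primers form such
stems and still perform.

The wide Tm window also means panel assembly treats Tm spread as a soft
constraint by default rather than a hard per-panel criterion.

## Panel assembly

Candidates for species *t* are all windows of the target consensus with
length in 18–22 nt (the packaged species primers are 18–20 nt) whose
3'-terminal base maps to a diagnostic column and which pass QC. The product
length convention is primer-inclusive: 5' start of the forward footprint
through the template position complementary to the reverse primer's 5' end
— the standard gel-visible product size. Assembly selects one candidate per
species maximizing the **minimum pairwise band separation**, control band
included, subject to pairwise dimer compatibility and the Tm window. No
published objective exists for band spacing; max-min separation is the
natural choice for ladder-readable gels and is verified against exhaustive
search. Default `min_band_separation` is 50 bp, comfortably below the
packaged panels' minimum gaps (61 bp COI, 129 bp CR). Search is exhaustive
up to 10⁶ combinations, then deterministic greedy with single-candidate
swap improvement; ties break by larger gap, then more diagnostic columns
covered, then lexicographic primer names, so the result is invariant under
candidate-list permutation.

## In-silico PCR

A primer anneals wherever the template matches it with at most
`max_mismatches` (default 2) and **zero** mismatches within the 3'-terminal
`protected_window` (default 3) — the mechanistic reading of species-specific
priming, where discrimination concentrates at the 3' end. Matching is IUPAC
base-set intersection by default. Scanning is vectorized with 4-bit base
masks over numpy arrays; an independent per-position Python scanner in the
test suite must agree on 1000 random (template ≤ 5 kb, primer 15–30 nt,
policy) cases.

A product requires one primer's site on the + strand upstream of the
other's on the − strand; either primer may take either role, which makes
prediction invariant under reverse-complementing the template. Products
shorter than the two primers combined are synthesis artifacts and rejected;
products above `max_product` (default 2000 bp) are dropped. Bands are
binary — amplification efficiency, primer concentration and template
quantity are explicitly out of scope, so wet-lab sensitivity limits cannot
be reproduced here.

Observed-vs-expected band comparison uses ±5 bp or ±3% (whichever is
larger), reflecting gel-estimated "approximately N bp" sizes.

Lane verdicts are a pure function of band lengths: control band + exactly
one species band → that species; control only → non-target; no control →
assay failure (e.g. the water lane); anything else — including a different
species' band than the lane's label — ambiguous.

## Virtual gel

First-order agarose behavior: d(L) = a + b·log₁₀L, least-squares fitted to
ladder points, with b < 0 enforced. The default calibration is a
**synthetic** 100–1000 bp ladder generated from (a, b) = (160, −50) mm —
a rendering convention, not an empirical mobility curve for any gel
percentage. Resolvability uses a 2 mm threshold; under the default model
the closest packaged bands (405 vs 466 bp) sit 3.05 mm apart. Species
calls never use millimetres, only band lengths with the shared tolerance,
so calls are independent of the cosmetic migration model.

## Synthetic fixtures

`simulate_species_alignment` draws one random ancestor, gives each species
`inter_div`·columns background substitutions plus exactly
`n_planted_diagnostics` private substitutions at columns disjoint across
species and excluded from all other mutation draws, then mutates
individuals at `intra_div` per site. Substitutions are uniform over the
three alternative bases (Jukes–Cantor flavored). Defaults (3 species × 5
records × 600 columns, intra 0.002, inter 0.05, 2 planted columns) emulate
the scale of a single-marker species-ID alignment: hundreds of columns,
a handful of sequences per species, intraspecific variation an order of
magnitude below interspecific. What this does **not** emulate: indels,
transition bias, codon structure, rate heterogeneity along the sequence, or
phylogenetic structure among the non-target species — so passing
planted-truth tests demonstrates correctness of the site-calling logic, not
robustness to real alignment pathology.

`synthesize_templates` embeds a panel's actual primer sequences (and
reverse complements) at the exact spacings its expected band sizes imply,
with random flanks; flanks and fillers are rejection-resampled until the
panel's predicted band set equals the planted one, so accidental primer
matches in random sequence are scrubbed and planted truth is exact. These
templates validate the geometry and verdict logic of the pipeline; they do
not substitute for real marker sequences, whose primer-site context,
trimming state and off-site similarity the generator does not model.

## Numerical and degenerate-input conventions

User-facing coordinates are 1-based inclusive (alignment columns, template
positions, binding-site spans); internals are 0-based half-open. Gap-only
columns yield undefined (None) conservation. Modal-residue ties break
alphabetically; consensus ties between gap and residue favor the residue.
`'.'` gaps are normalized to `'-'` on input with a warning. FASTA output
wraps at 70 columns. Seeds feed `numpy.random.default_rng` /
`random.Random` directly; identical seeds give byte-identical fixtures.

## Problem sizes used in the checks

The oracle-equivalence checks run 1000 random binding cases (templates up
to 5 kb) and 20–30 random assembly instances (≤4 species × ≤6 candidates,
where exhaustive search is exact); planted-truth recovery uses 20 alignment
seeds and 100 template sets per assay (600 lanes total). These sizes make
the whole suite and the acceptance script each run in well under a minute
on one CPU while exercising every code path the larger-scale runs would.

## Known limitations

* No thermodynamic annealing probability, degenerate-primer expansion
  beyond IUPAC intersection, or quantitative PCR model.
* Universal reverse and control primers are inputs, not designed de novo.
* Indel-based diagnostics are unsupported (a gap is never a diagnostic
  residue).
* The gel model is cosmetic; no band-intensity or artifact modeling.
* The control-region assay's per-species primer coordinate systems are
  assumed independent; primer names embedding positions are not reconciled
  to a shared anchor.
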