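# mxprime

Species-diagnostic multiplex PCR panel design and in-silico validation for
DNA-barcoding-based species authentication.

## The problem

Morphologically similar fish species — here the three commercially
exploited Amazonian catfishes *Brachyplatystoma rousseauxii*,
*B. vaillantii* and *B. filamentosum* — are routinely substituted for one
another once processed into fillets, because the diagnostic external traits
are gone. A cheap bench assay for authentication is multiplex PCR: one
species-specific forward primer per species, a shared universal reverse
primer, and a 16S rDNA control pair, combined in a single reaction. Each
species then yields a double band on an agarose gel — its own
species-specific product plus the control band — at sizes chosen to be
distinguishable against a 100-bp ladder.

`mxprime` turns every step of developing and validating such an assay into
computable operations:

1. **Diagnostic-site discovery** (`diagnostics`): in a species-grouped
   alignment, find columns where the target species' residue is conserved
   within the species (conservation = modal-residue share ≥ *c*, default 1)
   and occurs in every other species at a share ≤ *s* (default 0). A forward
   primer whose 3'-terminal base sits on such a column only extends on
   target DNA.
2. **Primer QC** (`primer_eval`): length, GC, 3'-window GC, Wallace Tm
   (2·(A+T) + 4·(G+C)), nearest-neighbor Tm (unified stack parameters with
   entropic monovalent-salt correction), self-complementarity, hairpins and
   all pairwise cross-primer dimers (run-based, 3'-aware).
3. **Panel assembly** (`panel_design`): enumerate QC-passing consensus
   windows anchored on diagnostic columns, then pick one forward per species
   maximizing the minimum pairwise band separation (control band included),
   subject to dimer and Tm compatibility.
4. **In-silico PCR** (`insilico_pcr`): 3'-anchored approximate matching
   (default ≤2 mismatches, none in the 3'-terminal 3 bases, IUPAC
   intersection matching), product prediction, multiplex band patterns and
   a specificity matrix with per-lane verdicts.
5. **Virtual gel** (`gel_sim`): log-linear migration d(L) = a + b·log₁₀L
   calibrated on a ladder, band resolvability, species calls from band
   patterns, ASCII gel rendering.
6. **Synthetic fixtures** (`synthetic`): seeded alignments with planted
   diagnostic columns and templates with planted primer sites, so the whole
   pipeline is testable offline with exact expected output.

The two published panels ship as fixtures (`mxprime.builtin_panel("coi")`
and `"cr"`): COI bands 254/405/466 bp with a 650 bp control, and
control-region bands 580/451/290 bp with a 160 bp control.

## Worked example

```sh
$ mxprime simulate templates --panel coi --seed 3 --out sim/
wrote sim/
$ mxprime ispcr --panel coi --templates sim/templates.fasta --labels sim/labels.tsv
lane	species	bands	called	verdict
lane1|synthetic|B._rousseauxii	B. rousseauxii	254,650	B. rousseauxii	target-confirmed
lane2|synthetic|B._vaillantii	B. vaillantii	405,650	B. vaillantii	target-confirmed
lane3|synthetic|B._filamentosum	B. filamentosum	466,650	B. filamentosum	target-confirmed
```

Each lane shows the double banding pattern the assay is designed around:
the species-specific product (254, 405 or 466 bp) plus the 650 bp 16S
control band, and the verdict column confirms the band-pattern call matches
the template's true species. Primer QC of the same panel:

```sh
$ mxprime qc --primer GGGGCCATTAACTTTATC --name Bro385
Bro385: len 18 gc 0.44 tm 52C 3'GC 1 self-duplex 4 PASS
```

(length 18 nt, GC fraction 8/18, Wallace Tm 52 °C, one G/C in the 3'-terminal
five bases, longest self-complementary run 4 — all inside the default QC
windows.)

The same operations are available as library calls; `mxprime gel` renders
the corresponding ASCII gel, and `mxprime design` runs the full
alignment-to-panel design on user data.

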