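# aqpkit

A toolkit for genome-wide characterisation of plant aquaporins (AQPs), the
major intrinsic protein (MIP) channel family, aimed at researchers studying
woody crops such as sweet cherry (*Prunus avium*). It packages, as testable
Python, the desk-side half of a family survey: residue-level motif
annotation, subfamily and substrate inference, promoter cis-element
scanning, gene-structure and selection statistics, and relative qPCR
expression analysis — together with seeded synthetic-data generators so
every step has a planted-truth recovery test.

## What it computes

- **Motif annotation** (`aqpkit.annotate`). The loop-B/E NPA triplets
  (grammar `N-P-[ASTLVI]`, with a template-alignment fallback for fully
  degenerate variants such as SLV/SPA), the four ar/R selectivity-filter
  residues (H2, H5, LE1, LE2), Froger's positions P1–P5 and the nine
  specificity-determining positions (SDPs) per substrate, all extracted by
  mapping a query through a global BLOSUM62 alignment to a subfamily
  position template. Physicochemistry follows ProtParam conventions:
  average-mass Mw (kDa), Bjellqvist pI, Kyte–Doolittle GRAVY, plus a
  sliding-window hydropathy heuristic for transmembrane segments.
- **Classification** (`aqpkit.classify`). A decision tree over the Froger
  and ar/R signatures assigns the five higher-plant subfamilies
  (PIP/TIP/NIP/SIP/XIP): P5 ≠ W → NIP; P4=F, P5=W → PIP (P1 ∈ {E,Q}) or
  XIP (P2=C); P4=Y, P5=W → TIP (P1 ∈ {T,V}) or SIP. Substrate inference
  counts SDP residues outside each substrate's allowed sets; a member is a
  putative transporter of ammonia, boric acid, CO₂, H₂O₂, silicic acid or
  urea when mismatches ≤ tolerance (strict 0 by default). Distance trees
  use p-distance + neighbor joining.
- **Promoter scanning** (`aqpkit.promoters`). IUPAC consensus matching of
  nine stress-related cis-regulatory elements (ARE, WRE3, WUN, STRE, LTR,
  MBS, DRE, AT-rich, TC-rich) on both strands of 2000 bp upstream windows,
  with presence matrices and per-element gene counts.
- **Structure & selection** (`aqpkit.evolution`). Exon–intron statistics
  from GFF3 gene models, and Nei–Gojobori (1986) Ka/Ks with
  pathway-averaged difference counting and Jukes–Cantor correction:
  Ka/Ks < 1 indicates purifying selection.
- **Expression** (`aqpkit.expression`). Efficiency-corrected (Pfaffl)
  relative quantification, `ratio = E_t^ΔCt_t / E_ref^ΔCt_ref` with
  ΔCt = Ct(calibrator) − Ct(sample), log2 matrices with not-detected
  masking, up/down regulation calls, and average-linkage clustering of
  profiles.
- **Synthetic data** (`aqpkit.simulate`). Pure functions of (parameters,
  seed) that emit proteins with planted motifs, promoters realising a
  given presence matrix over motif-free background, gene models, codon
  pairs with controlled synonymous/nonsynonymous change, and replicated
  Ct tables with planted fold-changes — each with a ground-truth sidecar.

The package ships curated fixtures for the 28-member sweet cherry AQP
roster (subfamily, length, NPA I/II, ar/R, Froger, Mw, pI, Ka/Ks, GRAVY)
and the per-substrate SDP consensus sets and member residue vectors.

## Worked example

```python
from aqpkit import classify
from aqpkit.io import load_roster, load_sdp_tables

roster = load_roster()
calls = [classify.classify_subfamily(e.froger, e.arR, e.name) for e in roster]
tallies = {}
for c in calls:
    tallies[c.subfamily] = tallies.get(c.subfamily, 0) + 1
print(tallies)

consensi, vectors = load_sdp_tables()
tip21 = next(v for v in vectors
             if v.protein == "PruavTIP2;1" and v.substrate_context == "ammonia")
ammonia = next(c for c in consensi if c.substrate == "ammonia")
print(classify.count_sdp_mismatches(tip21, ammonia))
```

prints

```
{'NIP': 8, 'PIP': 7, 'SIP': 3, 'TIP': 8, 'XIP': 2}
(3, (3, 6, 9))
```

i.e. the signature tree reproduces the family's subfamily composition
(7 PIP, 8 NIP, 8 TIP, 3 SIP, 2 XIP) without a single fallback call, and
PruavTIP2;1 differs from the ammonia-transporter consensus at exactly
three SDPs (SDP3, SDP6, SDP9) — the pattern under which it is still the
family's only inferred ammonia transporter.

The `examples/` directory has one short narrative script per capability
(`annotate_proteins.py`, `classify_subfamilies.py`,
`substrate_inference.py`, `scan_promoters.py`,
`gene_structure_and_kaks.py`, `expression_profiles.py`); each builds a
small input, runs the method and explains the numbers it prints. A thin
CLI mirrors the same operations (`aqpkit --help`).

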