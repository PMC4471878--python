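# mirsponge

Design and evaluation toolkit for **miRNA sponges**: transgene-encoded
competitive inhibitors that sequester a microRNA away from its
endogenous targets. A sponge transcript carries a tandem array of
*bulged* binding sites — perfectly complementary to the target miRNA
except at central positions 9–12, so the duplex bulges and escapes
Argonaute-catalysed slicing — cloned into a reporter 3′UTR. The package
is written for groups building conditional miRNA loss-of-function
reagents (e.g. Gal4/UAS-driven sponge libraries in *Drosophila*) and for
analysing the screens run with them.

It provides:

- **Registry handling** — miRBase-style mature FASTA parsing, seed
  k-mers, seed-family grouping (identical positions 2–8).
- **Construct design** — bulged binding sites; cassettes of *N* sites
  (default 20) separated by variable 4-nt linkers chosen so that no
  7–8-nt sliding window spanning a linker junction matches the seed
  site of any other miRNA in the registry; NotI/XbaI cloning flanks;
  composition-preserving scramble controls that match nothing.
- **Off-target scanning** — a k-mer index of canonical site types
  (6mer, 7mer-A1, 7mer-m8, 8mer) plus a brute-force oracle used to
  verify the index scanner.
- **Screen statistics** — balancer-corrected percent viability with a
  mean − 1 s.d. collection cutoff; flight-assay non-flier scoring with
  a 2-s.d.-of-scramble threshold confirmed by one-way ANOVA and
  Tukey–Kramer; and a concordance classifier benchmarking sponge
  phenotypes against independent null-mutant calls (confirmed /
  false-negative / false-positive / seed-family).
- **Synthetic fixtures** — seeded generators for registries, viability
  tables, flight tables and benchmark tables with known planted truth.

## The model in brief

For a miRNA *m* of length *L* (positions 1..*L* from the 5′ end), a
binding site is the DNA reverse complement of *m* with the bases
opposite positions 9–12 replaced by the *self-mismatch* base — the DNA
equivalent of the miRNA base itself — which can form neither a
Watson–Crick nor a G·U wobble pair. A transcript k-mer is a seed-match
site of type 7mer-m8 when it equals rc(*m*[2..8]), 8mer when it equals
rc(*m*[2..8])+A, and so on. Linker selection enumerates the 256
candidate 4-mers (lexicographically, or seeded-random) and accepts the
first whose junction windows contain no enabled site type of any
non-exempt miRNA — the target and its seed family are exempt — and no
restriction flank sequence.

Viability hit-calling uses cutoff = mean − 1×s.d. (sample s.d.) of
percent viability across the collection, hits inclusive at the cutoff;
phenotypes bin as lethal [0–5], semilethal (5–50], subviable (50–70],
viable >70. Flight hit-calling thresholds the mean non-flier fraction
at 2×s.d. of the scramble control, then requires ANOVA plus a
Tukey–Kramer comparison against scramble at *P* ≤ 0.001.

## Worked example

```python
from mirsponge import (MatureMiRNA, Registry, assemble_cassette,
                       design_bulged_site, generate_scramble, naive_scan)

reg = Registry([
    MatureMiRNA("dme-miR-8-3p",  "UAAUACUGUCAGGUAAAGAUGUC", "MIMAT0000130"),
    MatureMiRNA("dme-miR-2a-3p", "UAUCACAGCCAGCUUUGAUGAGC", "MIMAT0000107"),
    MatureMiRNA("dme-let-7-5p",  "UGAGGUAGUAGGUUGUAUAGU",   "MIMAT0000063"),
])

site = design_bulged_site(reg["dme-miR-8-3p"])
print(site.site_seq)           # GACATCTTTACGACTCAGTATTA  (23 nt)

cassette = assemble_cassette(reg["dme-miR-8-3p"], reg)
print(len(cassette.full_seq))  # 550
print(cassette.full_seq[:60])
# GCGGCCGCGACATCTTTACGACTCAGTATTAAAAAGACATCTTTACGACTCAGTATTAAA

report = naive_scan(cassette.full_seq, reg,
                    exempt=reg.family_of("dme-miR-8-3p"),
                    region_map=cassette.blocks)
print(len(report.in_region("junction")))   # 0

print(generate_scramble(site.site_seq, reg))
# TTTCGCTTAAATGAACTCGTAAC
```

The site is the reverse complement of miR-8-3p with positions 9–12
self-mismatched (`...ACGACT...` in place of the perfect
`...ACCTGA...`). The 550-nt cassette is NotI (8) + 20×23-nt sites +
19×4-nt linkers + XbaI (6); with only three registry miRNAs no linker
junction collides, so the lexicographically first linker `AAAA` is
accepted at every junction, and the scan confirms zero junction seed
matches. The scramble is a shuffle of the site with the same base
composition and no seed match to any registry miRNA.

The same operations are exposed as a CLI:

```bash
mirsponge design registry.fa dme-miR-8-3p --out-prefix mir8SP
mirsponge scan mir8SP.fasta registry.fa
mirsponge screen-viability viability.csv
mirsponge screen-flight flight.csv
mirsponge benchmark benchmark.csv
mirsponge fixtures spec.yaml --out-dir fixtures/
```

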