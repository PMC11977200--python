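# karyomorph

Comparative cytogenetics of allopolyploid karyotypes from arm-length
measurements and FISH marker maps — built around the clawed frogs
(*Xenopus*), where allotetraploid genomes carry two parental subgenomes
(L/S or a/b) whose chromosomes can be told apart, measured, and compared.

The package is for cytogeneticists who have pixel measurements of metaphase
chromosomes and arm-resolved FISH localizations, and want the downstream
analysis: which chromosome is which, how far homeologs have diverged,
which rearrangements separate species, and how labile features such as
nucleolus organizer regions (NORs) moved on the phylogeny.

## What it computes

**Karyomorphometrics.** From per-chromatid arm lengths `p`, `q` (pixels):
relative length `l = 100(p+q)/Σ(p+q)`, arm ratios `r1 = p/q`, `r2 = q/p`,
and centromeric index `i = 100p/(p+q)` (0–50 scale), classified into the
Levan-style intervals m (`i ≥ 37.5`), sm (`25 ≤ i < 37.5`),
st (`12.5 ≤ i < 25`), a (`0 < i < 12.5`), t (`i = 0`). Chromosomes are
identified against a karyotype template by globally optimal assignment in
normalized `(l, i)` space; per-type medians and IQRs are aggregated across
metaphases; homeolog pairs are compared by IQR overlap and by one-way
ANOVA + Tukey HSD.

**Rearrangement inference.** A target species' marker map is compared to a
reference (ancestral-proxy) map: minority synteny-group membership calls
translocations; two groups co-occupying one chromosome call an end-to-end
fusion, with fused arms and centromere fate inferred from marker arm
patterns and order; homeologous copies on different arms call a
pericentromeric inversion polarized by an outgroup. Conflicting markers are
reported, never dropped. A summary of 28S (NOR) and 5S rDNA FISH signals
reports NOR count/location and 5S presence patterns.

**NOR jumps.** Treating each species' NOR-bearing chromosome as an
unordered character, uniform-cost Sankoff parsimony (Fitch on binary trees,
polytomies handled natively) counts the minimum number of relocations on
the species tree and classifies each as intra- or inter-subgenome.

**Simulation.** A seeded generator produces chromatid measurement tables
(lognormal scale and measurement noise around a template), rearrangement
scenarios with ground truth, and FISH signal tables with dropout — the
substrate for every test.

Bundled fixtures (`karyomorph.datasets`) include the published *X. pygmaeus*
18-type karyotype template, the marker maps of *X. tropicalis*,
*X. laevis*, *X. pygmaeus* and *X. mellotropicalis*, the rDNA signal table,
and a 13-species tree with NOR states.

## Worked example

```bash
python examples/rearrangement_calls.py
```

prints, for *X. pygmaeus* against the diploid *X. tropicalis* reference:

```
=== X. pygmaeus vs X. tropicalis ===
  fusion: 9+10 -> 9_10L [L-copy] genes: bmp7, fn1, ndufs1, nomo3, sox9
    fused arms q-q, centromere of 9 lost, 10 retained; conflicting markers: sox9
  inversion: 2 -> 2S [S-copy] genes: cept1, gyg2
```

Meaning: no translocation separates chromosomes 9 and 2 in this species;
ancestral chromosomes 9 and 10 fused through their long (q) arms with the
chromosome-9 centromere lost (sox9's p-arm position is inconsistent with
the simple fusion model and is surfaced as a conflict); and cept1/gyg2
moved between arms of chromosome 2S — a pericentromeric inversion in the
S-subgenome. `examples/karyotype_analysis.py` reconstructs the karyotype
from simulated measurements (2n = 36; 10 m + 1 sm + 7 st haploid types),
and `examples/nor_jumps.py` reports the minimum of 5 NOR relocations on the
bundled tree (2 within-subgenome, 2 between-subgenome, 1 unclassifiable).

The same stages are exposed as a CLI:

```bash
karyomorph simulate --seed 1 --out sim/
karyomorph karyotype --measurements sim/measurements.csv --out karyo/
karyomorph rdna --out rdna/
karyomorph norjump --out jumps/
```

## Layout

- `src/karyomorph/` — `types`, `io`, `datasets`, `morphometrics`,
  `identification`, `rearrangements`, `norjump`, `simulate`, `pipeline`,
  `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — models, assumptions, parameter defaults, limitations
- `tests/` — unit, property (hypothesis) and acceptance tests
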