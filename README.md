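# karyoevol

Karyotype morphometrics and minimum-event ancestral reconstruction of
chromosomal rearrangements, built around the comparative cytogenetics of the
endemic Malagasy velvet geckos (*Blaesodactylus*) and their relatives
*Geckolepis* and *Homopholis*.

These geckos differ in diploid chromosome number (2n = 40–42) and in how many
chromosomes are biarmed. Given measured karyograms (per-pair relative lengths
and centromeric indices) and a fixed rooted phylogeny, the package answers two
questions a cytogeneticist asks:

1. **What is each karyotype?** — Levan morphology classes from the
   centromeric index, diploid number 2n, fundamental number FN (total arm
   count).
2. **How did the karyotypes evolve?** — the minimum-cost scenario of centric
   (Robertsonian) fusions, centric fissions, pericentric inversions and
   centromere repositionings over the tree, by exact Sankoff parsimony.

## The model

**Morphometrics.** For a chromosome of total length *c* and short arm *p*,
the relative length is RL = 100·*c*/Σ*c* and the centromeric index is
CI = 100·*p*/*c* ∈ [0, 50]. Levan classes by CI: telocentric (t) < 12.5 <
subtelocentric (st) < 25.0 < submetacentric (sm) < 37.5 < metacentric (m).
A CI exactly on a boundary is reported as a two-class token (e.g. `st/sm`).
FN counts 2 arms per biarmed and 1 per telocentric chromosome, over the
diploid complement: FN = 2n + 2·(biarmed pairs).

**Rearrangement events** act on abstract haploid states — counts of
chromosomes per morphology class:

| event | state change | 2n | diploid FN |
|---|---|---|---|
| centric fusion | t + t → one biarmed | −2 | unchanged |
| centric fission | one biarmed → t + t | +2 | unchanged |
| pericentric inversion | reclassify one chromosome | unchanged | ±2 or 0 |
| centromere repositioning | same as inversion (different mechanism) | unchanged | ±2 or 0 |

**Reconstruction.** Pairwise transition costs between states are minimal
total event costs (uniform-cost search); exact Sankoff dynamic programming
over an explicitly enumerated state space then yields all minimal root
states, one deterministic optimal labeling, and per-branch event
decompositions. The default costs (fusion = inversion = repositioning = 1,
fission = 5) penalise fissions, encoding the standard squamate prior that
high chromosome numbers are ancestral; all costs are configurable, and
lowering the fission penalty to 1 visibly moves the reconstructed root
(2n = 42 → 2n = 40) — cost sensitivity is part of the analysis, not a bug.

Packaged fixtures carry the published morphometric tables for the four
measured *Blaesodactylus* karyotypes, literature karyotype states for
*G. typica*, *H. walbergii* and *H. fasciata*, the specimen table, the study
phylogeny, and the default cost configuration (see
`src/karyoevol/fixtures/MANIFEST.tsv`).

## Worked example

```sh
$ karyoevol classify --karyogram src/karyoevol/fixtures/sakalavaB.tsv
taxon: sakalavaB
2n = 40   FN = 44
haploid class counts: m:2, sm:0, st:0, t:18
RL sum = 99.9 (printed rounding allows [98, 102])
...
```

*B. sakalava* clade B has 20 chromosome pairs (2n = 40), two of them
metacentric (pairs 1 and 6, CI 43.1 and 46.3), hence FN = 40 + 2·2 = 44.

```sh
$ karyoevol distance --from t=21 --to m=2,t=18
cost: 2
  centric fusion (t + t -> m)
  inv/repo (t -> m)
```

Turning the all-telocentric 2n = 42 complement into the 2n = 40
two-metacentric one needs two events. Note this is *not* two fusions: two
fusions would drop 2n to 38, so the cheapest consistent path is one fusion
plus one inversion.

```sh
$ karyoevol casestudy --out-dir out/
$ head out/casestudy.txt
karyoevol case study (package version 0.1.0)

measured karyotypes:
  antongilensis  2n=40  FN=44  {m:1, st:1, t:18}  RL sum=100.0
  sakalavaA      2n=40  FN=44  {m:2, t:18}  RL sum=101.7
  sakalavaB      2n=40  FN=44  {m:2, t:18}  RL sum=99.9
  boivini        2n=42  FN=42  {t:21}  RL sum=99.8

ancestral reconstruction:
  total cost: 11
```

The full pipeline classifies the four measured karyograms, merges them with
the literature states, and reconstructs ancestral karyotypes. Under the
default costs the unique minimum-event root is a 2n = 42 karyotype carrying
one metacentric (`{m:1, t:20}`, total cost 11); forcing the root to the
all-telocentric `{t:21}` condition costs exactly one event more (12). The
descendant branches recover the classical narrative: three inversions on the
*G. typica* branch, two fusions down to the *Homopholis* ancestor
(2n = 36, FN = 44), two inversions in *H. fasciata* (FN 44 → 40). See
`docs/methods.md` for why the optimum and the narrative root differ by that
single event.

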