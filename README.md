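# quartetconv

Detection of gene conversion between duplicate genes created by
polyploidization, via homologous gene quartets.

## The problem

After a whole-genome duplication (WGD), a genome carries thousands of
duplicate (paralog) gene pairs.  Gene conversion — unidirectional
homologous recombination that overwrites one duplicate (the *acceptor*)
with its partner's (the *donor's*) sequence, wholly or over a short tract —
keeps such pairs artificially similar, distorts molecular-clock dating, and
reshapes the evolution of gene families.  In a pair of related genomes that
share the WGD (for example poplar and willow, which share the Salicaceae
tetraploidization), conversion is detectable through **homologous gene
quartets**: paralogs P1 and P2 in genome A together with their respective
orthologs S1 and S2 in genome B.  Because speciation postdates the WGD,
orthologs should be the more similar pairs; conversion after speciation
flips that relationship, globally (whole-gene conversion, WCV) or locally
(partial-gene conversion, PCV).

`quartetconv` is for comparative genomicists who have CDS FASTA files, gene
coordinates and an all-vs-all protein search for two such genomes, and want
tested, reproducible conversion calls plus the usual downstream statistics.

## What it computes

* **Collinear blocks** — homolog pairs chained on gene order (max gap 50
  genes, >= 4 anchors, gene families of >= 50 members removed), labeled by
  polyploidy event from the block-median synonymous distance.
* **Distances** — Nei–Gojobori (NG86) Ka/Ks from protein-guided codon
  alignments, Jukes–Cantor corrected:
  `d = -(3/4) ln(1 - 4p/3)`, saturation flagged at p >= 0.745.
* **Ks dating** — Gaussian KDE (bandwidth 0.05) of anchor Ks plus a
  minimal Gaussian-mixture curve fit (smallest k with R^2 >= 0.95) locating
  WGD peaks and defining event windows.
* **Quartets** — assembled from tetraploidy-labeled paralog anchors and
  ortholog anchors; dropped when any pairwise gap fraction > 50% or
  amino-acid identity < 40%.
* **WCV calls** — Ks(paralogs) below both ortholog Ks, a paralogs-sister
  neighbor-joining topology, and codon-bootstrap support >= 0.95 (B=1000).
* **PCV calls** — per-column score `mean(ortholog mismatch) − paralog
  mismatch`; Ruzzo–Tompa maximal scoring segments (>= 10 nt), codon-block
  permutation p-values (B=1000, alpha 0.05), recursive masking for multiple
  tracts.
* **Downstream statistics** — conversion rates with exact counts,
  chromosome-decile and 1-Mb-window positional analyses, duplicate-density
  correlations, converted-vs-nonconverted Pn/Ps comparisons, TPM expression
  divergence, GO chi-square enrichment.
* **Synthetic data** — a fully ground-truthed generator (quartets, genome
  pairs, expression tables) matching the divergence structure of the
  poplar/willow system (paralog Ks ~ 0.25, ortholog Ks ~ 0.12), used by the
  test suite for calibration and power experiments.

## Worked example

Simulate one quartet with a 107-nt conversion tract implanted into P2 at
nucleotides 454–560, then scan it:

```python
from quartetconv import PipelineConfig
from quartetconv.simulate import ConversionSpec, QuartetSimConfig, simulate_quartet
from quartetconv.quartets import quartet_from_sequences
from quartetconv.conversion import detect_pcv

conv = ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                      tract_start=454, tract_end=560, time_fraction=1.0)
seqs, truth = simulate_quartet(QuartetSimConfig(n_codons=500, conversion=conv), seed=3)
q = quartet_from_sequences("demo", seqs)
print("Ks(P1,P2) =", round(q.stats["P1P2"].ks, 4))
print("Ks(P1,S1) =", round(q.stats["P1S1"].ks, 4))
print("Ks(P2,S2) =", round(q.stats["P2S2"].ks, 4))
for call in detect_pcv(q, PipelineConfig(), seed=3):
    print(f"{call.call_type}: {call.acceptor} converted by {call.donor}, "
          f"tract {call.tract_start}-{call.tract_end}, "
          f"score {call.score:.1f}, p = {call.p_value:.4g}")
```

prints

```
Ks(P1,P2) = 0.2621
Ks(P1,S1) = 0.1067
Ks(P2,S2) = 0.1365
PCV: demo_P2 converted by demo_P1, tract 455-560, score 7.0, p = 0.001
```

Read: genome-wide the paralogs are the older pair (Ks 0.26 vs ortholog Ks
0.11–0.14), but one significant high-scoring segment marks a region where
P2 matches P1 better than it matches its own ortholog S2 — the detector
recovers the implanted tract to within one nucleotide, identifies P2 as the
acceptor, and the elevated Ks(P2,S2) reflects the overwritten history.

The same pipeline runs from the shell on files
(`quartetconv simulate | blocks | kaks | ksfit | quartets | convscan |
stats | expr | goenrich`); see `quartetconv --help`.

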