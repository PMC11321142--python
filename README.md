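# cerealcas

A computational companion to a CRISPR Cas9 + Cas12a GoldenGate mutagenesis
toolkit for barley (*Hordeum vulgare*) and wheat (*Triticum aestivum*).  It
is written for people designing multiplex editing constructs in cereals and
for people analysing the resulting T0 screening data, and it covers the dry
half of that workflow end to end:

* **Guide design** (`guide_design`) — scan target sequences for SpCas9
  (20-nt protospacer, NGG PAM 3′) and LbCas12a (23-nt protospacer, TTTV PAM
  5′) sites on both strands, and emit cloning-ready oligo pairs for the
  level-1 guide accepters.  Each oligo pair is the annealed protospacer
  duplex with architecture-specific 4-nt overhangs
  (`CTTG/AAAC` for TaU6-driven Cas9 guides, `AGCA/AAAC` for TaU3/HvU3,
  `AGAT/GGCC` for Cas12a V2 arrays, `AGAT/ATTA` for V3).
* **Assembly planning** (`assembly_planner`) — choose the correct level-2
  binary vector from the species × nuclease × GRF-GIF catalogue (nine EC
  vectors), alternate U6-/U3-class pol III promoters along tandem guide
  arrays, and route 1–26 guides through the hierarchy: up to four level-1
  cassettes go straight into the binary vector (BsaI + BpiI); more than
  four are first stacked, four at a time, in level-M intermediates (BpiI).
* **Assembly simulation** (`assembly_sim`) — verify a plan in silico by
  modelling type-IIS digestion (BsaI `GGTCTC N1`, BpiI `GAAGAC N2`, 4-nt 5′
  overhangs) and overhang-directed ligation.  A reaction succeeds only if a
  unique circular product exists, and products are checked for residual
  recognition sites (one-pot GoldenGate must be irreversible).
* **Amplicon mutation calling** (`amplicon_caller`) — re-implementation of
  the deep-sequencing indel caller: infer amplicon boundaries as the modal
  read-pair start positions, keep only pairs with both mates exactly at
  those boundaries, extract insertion/deletion patterns from CIGAR strings
  within a window around the cut site, and report %WT / %mutant plus the
  full pattern spectrum per sample and locus.  A pairwise-alignment
  classifier handles Sanger reads the same way (gaps in the cut window
  count, substitutions never do).
* **Efficiency statistics** (`efficiency_stats`) — binomial GLMs with logit
  link and chi-squared likelihood-ratio tests for mutated/not-mutated T0
  proportions, sequential (type-I) crossed ANOVA for per-plant mutant-allele
  percentages, per-construct means ± SE over genes, the all-targets rate
  (which under nested outcomes equals the lowest per-gene efficiency), and
  the D156R × intron synergy decomposition
  `synergy = combined − base − Δa − Δb`.
* **Synthetic data** (`fixtures`) — seed-deterministic generators for
  references, paired-end amplicon SAM with controlled indel frequencies
  (exact quota sampling), nested or independent T0 cohorts, and toy
  GoldenGate parts, so everything above is testable without downloads.

## Worked example

```python
from cerealcas.guide_design import CAS9, scan_targets, design_oligo_pair

seq = "GCTTACGTGGACTAGTCAGTTAGTGGATCAACTTGAAGGCCACTTCAGGTTTAGGCTAGCA"
sites = scan_targets(seq, CAS9, seq_id="demo")
print(f"{len(sites)} Cas9 sites")
for t in sites[:3]:
    print(t.start, t.strand, t.protospacer, t.pam)

pair = design_oligo_pair(sites[0].protospacer, "CAS9_A_TaU6")
print("F:", pair.forward)
print("R:", pair.reverse)
```

prints

```
4 Cas9 sites
3 + TACGTGGACTAGTCAGTTAG TGG
16 + CAGTTAGTGGATCAACTTGA AGG
26 + ATCAACTTGAAGGCCACTTC AGG
F: CTTGTACGTGGACTAGTCAGTTAG
R: AAACCTAACTGACTAGTCCACGTA
```

i.e. four NGG-adjacent 20-mers were found (start is 0-based, minus-strand
sites report the protospacer in their own orientation), and the first site
becomes a forward oligo carrying the `CTTG` TaU6 cloning overhang plus the
protospacer, with the reverse oligo as `AAAC` plus the reverse complement —
ready to anneal and drop into the level-1 accepter with BsaI.

The same workflow is available from the shell:

```bash
cerealcas scan --nuclease cas9 --fasta targets.fa
cerealcas plan --species wheat --cas12a --grf GRF_GIF --guides guides.tsv -o plan.json
cerealcas assemble --plan plan.json --guides guides.tsv --report report.json
cerealcas call --sam sample.sam --loci loci.json --sample plant_07
cerealcas stats synergy --base 5 --with-a 17 --with-b 13 --combined 68
```

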