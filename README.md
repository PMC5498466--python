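# tascreen

Screen annotated bacterial genomes for **type II toxin–antitoxin (TA)
operons** and characterize the candidates. The pipeline mirrors a classic
homology-driven TA survey:

1. **reference_db** — load a reference set of toxin/antitoxin proteins
   (FASTA, `id|family|role` headers), single-linkage cluster it
   (coverage ≥ 0.75 of the shorter sequence, score density ≥ 1 bit/column)
   and pick cluster representatives.
2. **homology_search** — in-process Smith–Waterman local alignment
   (BLOSUM62, affine gaps 11/1) with Karlin–Altschul E-values; each genome
   protein is assigned to the family of its highest-scoring hit at
   E ≤ 0.01.
3. **pairing** — co-directed neighboring genes, one toxin and one
   antitoxin of different families, within 150 nt (configurable) become TA
   pair calls; 1–3 nt ORF overlaps are flagged as transcriptionally
   coupled.
4. **physchem** — length, average molecular weight, isoelectric point
   (bisection on a Henderson–Hasselbalch charge model; EMBOSS or
   Bjellqvist pKa sets), and the basic-toxin/acidic-antitoxin asymmetry
   flag.
5. **islands** — genomic-island context: maximal runs of user-designated
   non-core genes spanning > 8 kb; pairs fully inside an island are
   flagged.
6. **stress_expression** — specific growth rate, per-gene log2 fold
   changes, permutation-test significance, and per-condition TA activation
   calls (toxin-up / antitoxin-down / both / none) plus toxin:antitoxin
   ratios.
7. **synthetic** — generator for genomes with planted TA operons (plus
   adversarial decoys) and negative-binomial expression tables with
   planted fold changes, for fully offline benchmarking.

## CLI

A small curated demo reference set ships with the package and is the
default wherever `--refs` is optional.

```sh
# simulate a genome with 3 planted operons + expression counts
tascreen simulate -o sim --n-pairs 3 --n-decoys 12 --seed 7

# full screen across one or more genomes, driven by a flat key=value config
cat > screen.cfg <<EOF
genomes = demo:sim/proteins.faa:sim/genes.gff3
out_dir = screen_out
seed = 7
EOF
tascreen screen --config screen.cfg          # exit 0 ok / 2 partial / 1 fatal

# individual stages
tascreen cluster-refs --refs refs.faa -o clusters.tsv
tascreen assign --refs refs.faa --proteins p.faa --gff g.gff3 -o assignments.tsv
tascreen pair --refs refs.faa --proteins p.faa --gff g.gff3 -o pair_out
tascreen physchem p.faa -o physchem.tsv
tascreen islands --gff g.gff3 --core-genes core.txt -o islands.bed
tascreen expression --counts counts.tsv --conditions conditions.tsv \
    --pairs pair_out/pairs.tsv -o expr_out
```

Any config key can be overridden with `--set key=value`; precedence is
CLI > config > default. Every output table starts with a header comment
carrying the tool version, a hash of the resolved configuration, and the
seed, so reruns are verifiably identical.

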