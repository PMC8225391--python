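# phylofoot

Phylogenetic footprinting for transcription-factor (TF) target-gene
prediction, and motif-signature statistics that classify how a TF relates
to a cell type's effector-gene battery.

TF binding sites are short and occur by chance throughout a genome, so a
single motif match near a gene says little.  The signal becomes usable
when the orthologs of that gene, across a panel of related genomes, also
carry matches: recurrent, independently annotated sites near orthologous
genes are much more likely to be functional.  `phylofoot` implements this
idea end to end for researchers studying gene-regulatory programs (the
motivating system is cell-type specification in compact animal genomes,
where a "terminal selector" TF may directly co-regulate most of a cell
type's effector genes):

1. **Scan** — a DNA binding motif in MEME minimal format is turned into a
   log-odds PSSM (bits, background-weighted pseudocount smoothing) and
   every genome in the species panel is scanned on both strands.  Match
   p-values are exact: the score distribution of a random background word
   is computed by dynamic programming on a discretized score lattice, and
   hits with p ≤ 1e-4 (configurable) are kept.
2. **Assign** — each hit is assigned to adjacent protein-coding genes with
   a compartment label: upstream (the intergenic interval 5′ of the TSS,
   shared in full by divergently transcribed pairs), intron, exon or
   downstream.  Only upstream and intronic matches are scored; exonic and
   downstream matches are annotated but unused.
3. **Features** — through an ortholog map, each reference gene receives an
   alignment-free feature vector over the S-species panel: per species the
   upstream/intronic match counts, maximum and mean PSSM scores (6·S
   features), plus two conservation counts — the number of species with at
   least one upstream (respectively intronic) match.
4. **Rank** — a probabilistic classifier (Gaussian process by default;
   logistic regression and random forest available) is trained on
   validated target genes versus an equal-sized random draw of candidate
   genes, and every candidate gene is ranked by its posterior probability
   of being a target.  Ranks are rescaled to a normalized rank in [1, 100]
   (100 = best).  A 10 × 2-fold cross-validation harness reports per-fold
   recall and rank-sums Z.
5. **Signatures** — within a gene battery (the genes differentially
   expressed by one cell class), two tests are run per expressed TF: a
   hypergeometric enrichment test of motif-bearing battery genes against
   the genome-wide candidate proportion, and a Wilcoxon rank-sums test of
   the battery genes' normalized ranks against the genome-wide ranking.
   After Benjamini–Hochberg correction, each (TF, battery) pair is called
   **coordinated** (enriched *and* well ranked), **piecemeal** (not
   enriched, but motif-bearing members well ranked) or **other**.
6. **Cofactors** — for pairs of co-expressed TFs, genes carrying both
   motifs are tested against an independence expectation (the product of
   the genome-wide marginal proportions) and rank-tested per motif,
   yielding **co_coordinated**, **common_piecemeal** or **independent**.

A bundled synthetic-data generator (`phylofoot.simulate`) builds
multi-species worlds — orthologous gene structures, i.i.d. background
sequence, binding sites planted into designated target genes with a
controlled per-species conservation probability — so the whole pipeline is
testable without any genome downloads.

## Worked example

```bash
python examples/rank_targets.py
```

generates a 4-species, 600-gene world with 12 true target genes, scans it,
trains on the known targets and prints:

```
115 candidate genes (>=1 upstream/intronic match)
top 10 predicted targets:
  * s01_g00475  P(target)=0.868  normalized rank=100.0
  * s01_g00259  P(target)=0.802  normalized rank=99.1
  ...
100% of the 12 planted targets (marked *) fall in the top decile of the ranking.
```

`P(target)` is the classifier posterior that the gene is a true TF target;
the normalized rank rescales its position in the genome-wide candidate
ranking to [1, 100].  All planted targets landing in the top decile is the
expected outcome for strongly conserved sites.  The other examples
(`scan_motif.py`, `cross_validation.py`, `signature_analysis.py`,
`cofactor_analysis.py`) each exercise one capability and print a short
interpretation.

## Command line

Every stage is also a subcommand of the `phylofoot` CLI, mirroring the
conventional scanner options (`-p` match p-value threshold, `-d` maximum
upstream search distance — omit to search the full intergenic region,
`-r` reference species, `-s` species panel file):

```bash
phylofoot simulate --n-species 4 --n-genes 600 --seed 1 --out world/
phylofoot rank --motif motif.meme --genomes world/ -s world/species.txt \
    --orthologs world/orthologs.tsv --positives world/targets.txt --out run/
phylofoot cv ... ; phylofoot signature ... ; phylofoot cofactor ...
```

`rank` writes a per-gene summary table (probability, rank, normalized
rank, the full feature block) and one match-detail file per species.

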