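# homogene

Homology-based gene prediction for a target genome from a well-annotated
related reference, using conservation of proteins **and** of intron
positions, optionally guided by RNA-seq splice evidence.

`homogene` is for genome annotators who have (i) a reference genome with a
trusted gene annotation, (ii) an assembly of a related species to annotate,
and optionally (iii) mapped RNA-seq reads of the target species. It is a
homology mapper, not an ab-initio predictor: genes without a reference
homolog are out of reach by construction.

## Method

For every reference mRNA the coding sequence is decomposed into its coding
exon parts with phases; each part peptide is located on the target by
translated local alignment (Smith–Waterman, BLOSUM62, affine gaps 11/1)
against all six reading frames. Colinear hits are chained per sequence and
strand, and every neighboring exon pair is joined by enumerating the
in-frame (donor, acceptor) splice-site combinations — experimental splice
sites from split reads where available, conserved GT/GC..AG dinucleotides
otherwise — scoring each combination by aligning the re-translated junction
against the reference peptide around the corresponding reference intron
(intron position conservation), and keeping the arg-max. Terminal exons are
adjusted to an in-frame ATG and stop codon; each model is scored by global
alignment of its protein against the reference protein.

Predictions carry the evidence statistics

* **tie** — fraction of predicted introns exactly supported by split reads
  (NA for single-coding-exon models),
* **tpc** — fraction of coding bases covered by reads,
* **tae**, **tde** — fractions of acceptor/donor sites with evidence,
* **minCov**, **avgCov** — minimum and mean coverage over coding bases,
* **minSplitReads** — minimum split-read count over the introns,
* **pAA**, **iAA** — percent positive-scoring and identical amino acids
  versus the reference protein,

and are combined by the annotation filter: relative-score filtering
(score per residue), merging of border-identical predictions across
reference species (#evidence), same-strand overlap clustering, selection of
the top-scoring representative, common-border alternative transcripts,
and nested-gene recovery. Predictions are evaluated against an annotation
as sensitivity Sn, specificity Sp and F1 = 2·Sn·Sp/(Sn+Sp) at the gene,
transcript and exon level (CDS coordinates only).

## Worked example

Everything below is generated by the package itself — no downloads:

```python
import json
from homogene import (generate_reference, derive_target, simulate_spliced_sam,
                      extract_evidence, predict, annotate_all, evaluate)

genome, refs = generate_reference(n_genes=20, seed=1)
target, truth = derive_target(genome, refs, aa_identity=0.9, seed=2)
sam = simulate_spliced_sam(truth, target, reads_per_intron=2, read_len=50, seed=3)
introns, coverage = extract_evidence(sam, with_coverage=True)

predictions = predict(refs, target, introns=introns, k=1)
annotate_all(predictions, introns, coverage, refs)

p = predictions[0]
print(p.prediction_id, p.seq_id, p.strand, len(p.parts), "exons")
print({k: (round(v, 3) if isinstance(v, float) else v)
       for k, v in p.attributes.items() if k != "ref_gene"})
print(json.dumps(evaluate(predictions, truth).as_dict(), indent=2))
```

prints

```
g000.t1_R1 chr1 - 5 exons
{'tie': 1.0, 'tde': 1.0, 'tae': 1.0, 'minSplitReads': 2, 'tpc': 1.0,
 'minCov': 1, 'avgCov': 2.615, 'pAA': 90.541, 'iAA': 90.541}
{"gene": {"Sn": 100.0, "Sp": 100.0, "F1": 100.0},
 "transcript": {"Sn": 100.0, "Sp": 100.0, "F1": 100.0},
 "exon": {"Sn": 100.0, "Sp": 100.0, "F1": 100.0}}
```

i.e. all 20 diverged orthologs are recovered exactly; the first prediction
is a 5-exon minus-strand model, every intron supported by ≥ 2 split reads
(tie = 1), all coding bases covered (tpc = 1), and ~90 % identical to its
reference protein — matching the simulated divergence.

The same pipeline is available from the shell:

```bash
homogene simulate --out-dir demo --n-genes 20 --seed 1
homogene ere --sam demo/rnaseq.sam --out demo/introns.bed --coverage demo/cov.bedgraph
homogene predict --reference-fasta demo/reference.fasta --reference-gff demo/reference.gff3 \
    --target-fasta demo/target.fasta --introns demo/introns.bed \
    --coverage demo/cov.bedgraph --out demo/predictions.gff3
homogene gaf --gff myref demo/predictions.gff3 --out demo/final.gff3
homogene compare --predictions demo/final.gff3 \
    --annotation-fasta demo/target.fasta --annotation-gff demo/truth.gff3
```

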