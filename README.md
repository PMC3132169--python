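# oakbes

Genome-composition analysis from BAC-end sequences (BES), built as a
tested, reusable pipeline with a synthetic-data generator that plants
fully known truth.

## The problem

Before a genome is sequenced, a BAC library plus a few tens of
thousands of Sanger end reads is often all that is known about it.
Those end reads — two per clone, one from each end of a 50–205 kb
insert — are a sparse random sample of the genome, yet they support a
surprising amount of inference:

* **Library coverage.** The Clarke–Carbon relation
  `N = ln(1−P) / ln(1−I/GS)` links clone count *N*, insert size *I* and
  genome size *GS* to the probability *P* of recovering any locus; fold
  coverage is the effective cloned length over the genome size after
  discounting empty and organelle-contaminant clones.
* **Ab-initio repeat discovery.** All-vs-all self-comparison of the
  reads, keeping alignments in which *every* 100-bp sliding window has
  ≥ 90% identity. Under a null model of i.i.d. random sequence, the
  probability that two 100-bp windows match is
  `p0 = (Σᵢ fᵢ²)⁹⁰` (≈ 6.5 × 10⁻⁵⁵ at uniform base frequencies), so the
  number of matches per read is Binomial(n, p0) and even a single match
  is significant: repeats announce themselves. Reads with ≥ 6 matches
  are clustered into families, and family copy numbers observed in the
  read sample extrapolate to genome copy numbers by
  `copies × GS / total_BES_bp`.
* **Microsatellites.** Maximal perfect tandem repeats of primitive
  1–6 bp motifs, classified into canonical motif classes under rotation
  and reverse complement (AG/GA/TC/CT → "AG").
* **Gene content.** The genic fraction of the read sample, scaled to
  the genome and divided by a mean gene length:
  `genes ≈ (n_hit × L̄ / total_bp) × GS / gene_len`.
* **Microsynteny.** Mate pairs mapped onto a reference genome are
  classified (no hit / single end / paired end / colocalized / gapped /
  non-gapped / collinear / rearranged) by whether both ends land on one
  target 15–250 kb apart and face inward as BAC ends do.

Every stage can be exercised end-to-end on synthetic data in which the
repeat copies, SSR loci, gene segments and clone coordinates are planted
and therefore known exactly.

## Worked example

```python
from oakbes.library_stats import LibraryParams, coverage_depth, recovery_probability
from oakbes.repeat_analysis import NullModel, extrapolate_copies
from oakbes.gene_content import GeneEstimateParams, estimate_gene_number

model = NullModel(base_freqs=(0.25, 0.25, 0.25, 0.25))
print(f"null p0 = {model.p0:.1e}")
print(f"repeat-call threshold T = {model.threshold}")

params = LibraryParams(92_160, 135_000, 740e6,
                       empty_fraction=0.07, organelle_fraction=0.022)
print(f"coverage depth = {coverage_depth(params):.1f}x")
print(f"recovery probability = {recovery_probability(92_160*0.93, 135_000, 740e6):.7f}")

print(f"genome copies of a 119-copy family = {extrapolate_copies(119, 740e6, 12_018_238)}")
gp = GeneEstimateParams(1_591, 599, 12_018_238, 740e6, 2_000)
print(f"gene estimate = {estimate_gene_number(gp)}")
```

prints

```
null p0 = 6.5e-55
repeat-call threshold T = 1
coverage depth = 15.3x
recovery probability = 0.9999998
genome copies of a 119-copy family = 7327
gene estimate = 29340
```

Reading the output: with p0 astronomically small, the binomial threshold
is T = 1 — any self-match certifies a repeat. A library of 92,160 clones
(7% empty, 2.2% chloroplast) with 135 kb inserts holds ~15 genome
equivalents of a 740 Mb genome and recovers any locus with probability
\> 99.99%. A repeat family seen 119 times in a 12.0 Mb read sample
scales to ~7,327 genome copies, and 1,591 protein-matching reads of
599 bp imply ~29,340 genes at 2 kb per gene.

The CLI wraps the same functions:

```bash
oakbes simulate --genome-length 300000 --n-clones 30 \
    --insert-mean 60000 --insert-min 30000 --insert-max 90000 \
    --seed 2 --out-dir sim
oakbes stats sim/reads.fasta
oakbes ssr sim/reads.fasta --summary
oakbes run --out-dir full_run      # simulate -> ... -> consolidated report
```

`oakbes run` executes the whole pipeline on a synthetic genome and
writes `report.json` (plus per-stage TSV/FASTA/BED outputs and a
manifest with the seed and output checksums); identical config and seed
reproduce byte-identical payloads.

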