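# codonbias

Codon and codon-pair usage bias analysis for coding-sequence (ORF) corpora,
aimed at researchers studying translational selection, mutational bias and
molecular evolution in non-model organisms — e.g. characterising codon
biology from an assembled transcriptome, or comparing usage patterns across
vertebrate genomes.

## What it computes

Given a FASTA of full-length ORFs (start codon, stop codon, no internal
stop, no ambiguous bases, length > 300 bp, optionally cross-checked against
homolog reference lengths), the package produces:

* **Single-codon statistics** — counts and per-mille frequencies over all 64
  codons; RSCU (relative synonymous codon usage), a codon's count divided by
  the mean count of its synonymous family, so RSCU = 1 means no bias; SCUO
  (synonymous codon usage order), the entropy-based bias index
  `SCUO = Σᵢ Fᵢ·(log₂Sᵢ − Hᵢ)/log₂Sᵢ` in [0, 1]; positional GC content
  GC₁/GC₂/GC₃; high-frequency codon calls (RSCU > 1.5 or within-family share
  > 60%); abundant/rare top-15 sets; and the NCG:NCC CpG-suppression ratio.
* **Codon-pair statistics** — ordered sense-codon pairs (61 × 61 = 3721) at
  junction distances 0–5 intervening codons; RSCPU (the pair-level analogue
  of RSCU, expected count = amino-acid-pair count divided by the product of
  the two codon degeneracies); preferred/avoided pair calling with the
  Audic–Claverie count test (p < 0.01) plus a |log₂ obs/exp| ≥ 1.5 cutoff;
  junction-dinucleotide profiles.
* **Position-dependent bias** — Kullback–Leibler divergence
  `KLD(k) = Σᵢ Σⱼ p_{i,j}(k) ln(p_{i,j}(k)/q_{i,j})` of each 10-codon bin's
  within-family codon usage against the corpus background, corrected by the
  SSC (shuffled-synonymous-codons) null baseline; bias of the codon
  following the start codon vs internal ATGs; WebLogo-style information
  content of 18-nt start/stop context windows; AU₃ profiles.
* **Composition** — dinucleotide/trinucleotide relative abundance odds
  ratios ρ_CG = f_CG/(f_C·f_G) and ρ_CWG; GC₃ terciles with bootstrap
  composition contrasts; SCUO-vs-GC₃ polynomial fits.
* **Cross-species comparison** — per-species RSCU profiles, hierarchical
  clustering (Euclidean/average-linkage on per-codon z-scores, Newick
  output), PCA, and codon-context trees built from 61 × 61 adjusted-residual
  matrices.
* **Synthetic corpora** — a generator with controllable codon weights,
  first-order codon-pair coupling, positional overrides and flanking-motif
  profiles, plus the SSC and SC (shuffled-codons) null models. Every
  generated corpus carries its ground truth, which is how the whole
  pipeline is validated.

## Worked example

Generate a 646-gene corpus with a known GAG preference (Glu weights
0.25/0.75, so target RSCU(GAG) = 1.5) and one coupled codon pair
(TCG→TCG, 8-fold), then run the full pipeline:

```python
import json
from codonbias import GeneratorSpec, generate_corpus, RunConfig, run_pipeline
from codonbias.synth import write_fasta, write_flank_tsv

spec = GeneratorSpec(
    n_genes=646, seed=4,
    codon_weights={"E": [0.25, 0.75]},          # family order (GAA, GAG)
    pair_coupling={("TCG", "TCG"): 8.0},
)
records, truth = generate_corpus(spec)
write_fasta(records, "corpus.fa")
write_flank_tsv(records, "flanks.tsv")

cfg = RunConfig(fasta="corpus.fa", flanks="flanks.tsv", out_dir="results", seed=4)
manifest = run_pipeline(cfg)
```

The run prints/writes (abridged):

```
filter:  {'input': 646, 'kept': 646, 'rejected': 0}
usage:   n_codons 139820, high_frequency_codons ['GAG'], SCUO 0.0107, GC3 0.556
pairs:   d0 preferred 1 / avoided 1 of 3721;  d1 preferred 0
```

and `results/pairs_d0.tsv` contains the injected pair as the sole strong
preferred call:

```
pair    obs_count  exp_count  log2_ratio  p          verdict
UCGUCG  81         11         2.8804      1.000e-10  preferred
```

Reading it: the corpus-wide GAG bias is recovered exactly as the one
high-frequency codon; the coupled pair is observed 81 times against 11
expected (log₂ ≈ 2.9, close to the injected log₂ 8 = 3), while spaced
pairs (d ≥ 1) show no bias — neighbour coupling does not propagate, as
expected from a first-order process. SCUO is near 0 because all other
families were generated uniformly.

The same pipeline is available from the shell:

```bash
codonbias simulate --spec spec.json --out corpus.fa --flank-tsv flanks.tsv
codonbias run-all --fasta corpus.fa --flanks flanks.tsv --out-dir results --seed 4
codonbias compare --species-manifest species.tsv --out-dir results
```

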