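# ikgm — identify key genes of macroevolution with attention

`ikgm` asks which genes carry the signal of a binary macroevolutionary
split — say, diurnal butterflies vs. nocturnal moths — by turning the
question into whole-proteome document classification. Each species'
proteome is a *text* whose sentences are proteins; the words of a
sentence are either the protein's functional-domain names (the *domain
view*, v=1) or the short peptides obtained by splitting the sequence at
high-frequency k-mers (the *variant-kmer view*, v=2). A hierarchical
attention network (HAN) — a BiLSTM word encoder with word attention,
a BiLSTM sentence encoder with sentence attention, and a softmax
classifier — is trained per view to predict the taxon label, and the
sentence attentions α_i of the trained model become per-protein
importance scores:

* **PAS** — the attention a protein receives within its species' document;
* **GAS** — per-gene PAS summed over a taxon's species, normalized to sum
  to one within the taxon;
* **DAS** = normalize(GAS_taxon1) + normalize(GAS_taxon2) — the gene
  importance measure that is ranked; a third, *fused* view (v=3) gates the
  mean of the two views' gene scores by the cosine similarity of their
  cross-species profiles.

Genes in the top 1 % of DAS are the key-gene candidates; they can be
tested against GMT gene sets with a hypergeometric test (BH-corrected).

Because real two-taxon proteome panels are small, each genome is expanded
by near-neutral augmentation (random block rearrangement of gene order
plus <1 % random residue substitution) before training, and a synthetic
fixture generator plants discriminative genes of the three mechanism
classes the views are designed to detect (copy-number change, taxon-fixed
substitutions, domain indel) so the whole pipeline is testable end to
end without any download.

The package is aimed at comparative genomicists who have per-species
protein FASTA files, Pfam-style domain annotations, and a protein-to-gene
map, and want a ranked list of candidate genes behind a binary phenotype
split.

## Worked example

Generate a synthetic two-taxon study and run the full pipeline:

```sh
ikgm fixtures --seed 7 --out study/
cat > run.yaml <<EOF
out_dir: study/run
manifest: study/manifest.tsv
annotations: study/annotations.tsv
gene_map: study/gene_map.tsv
seed: 7
EOF
ikgm run --config run.yaml
```

or, equivalently, from Python:

```python
from ikgm.pipeline import PipelineConfig, run_pipeline
from ikgm.synthetic_fixtures import FixtureConfig

result = run_pipeline(PipelineConfig(out_dir="study/run",
                                     fixture=FixtureConfig(seed=7), seed=7))
print(round(result.mean_held_out_accuracy(), 3))
print(result.das_tables[3].sort_values("score", ascending=False).head(3))
print(result.recovery)
```

which prints (numbers from this exact invocation):

```
0.944
    view gene_symbol     score
50     3       COPY0  0.525242
51     3      INDEL0  0.347856
26     3       BG026  0.157301
```

The held-out accuracy of 0.944 says genomes of unseen species are almost
perfectly assigned to their taxon; the fused-view DAS ranking puts the
planted copy-number gene (COPY0) and domain-indel gene (INDEL0) far above
the 50 shared background genes, i.e. the classifiers earned their
accuracy by attending to the planted signals. `result.recovery` reports,
per mechanism and view, whether each planted gene landed in the top
fraction of its matched view — at this seed the substitution gene was not
recovered, which is a real property of the method at this scale (see the
limitations section of `docs/methods.md`: which of several valid
discriminative genes a single training run discovers varies from seed to
seed). The run directory contains the PAS/GAS/DAS tables per view (TSV),
the ranked top-gene lists, training histories, and a run log.

Stage subcommands (`ikgm augment|tokenize|embed|train|score|rank|enrich`)
expose each step individually on files.

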