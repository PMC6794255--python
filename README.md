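# mitobait

Iterative read baiting and de novo assembly of mitochondrial genomes from
bulk RNA-Seq data, with a labeled synthetic-data generator so the whole
pipeline is testable offline.

The pipeline mirrors the classic bait-and-assemble loop: sensitive seeded
local alignment recruits candidate mitochondrial reads against a
(non-conspecific) reference mitogenome; the recruited reads are de novo
assembled; the contigs become the reference for the next round, until
recruitment is stationary or an iteration cap is hit. Finishing then
validates/orders/orients the contigs against the closest guide reference,
fills gaps from the raw reads, circularizes, transfers annotations and
checks ORFs. Companion modules triage leftover contigs into
target / contaminant / nuclear leakage and profile per-gene coverage
(including below-4x flagging of hard regions such as tRNAs).

## Layout

| module               | role |
|----------------------|------|
| `mitobait.seqio`     | FASTQ/FASTA/GFF3 I/O, quality trimming (leading/trailing + sliding window) |
| `mitobait.simulate`  | synthetic mitogenomes (13 PCGs + 22 tRNAs + 2 rRNAs + control region), mutated/rearranged references, labeled expression-weighted reads |
| `mitobait.recruit`   | k-mer seeded (default k=10, 1 seed mismatch) local-alignment read recruitment |
| `mitobait.assemble`  | single-k canonical De Bruijn graph assembler (k=25, tips + bubbles) |
| `mitobait.iterate`   | map→assemble loop, plateau detection, per-iteration stats |
| `mitobait.finishing` | scaffolding, OLC gap filling, circularization, annotation transfer, ORF checks |
| `mitobait.leakage`   | contig classification and count-(percentage) summary table |
| `mitobait.coverage`  | per-position/per-gene depth, low-coverage intervals, BED/BEDGraph output |

## CLI

```bash
mitobait simulate --config sim.yaml --seed 1 --outdir sim/
mitobait trim     --in sim/reads.fq --minlen 45 --window 25:33 --out trimmed/
mitobait run      --reads trimmed/trimmed.fq --refs congeneric.fa --max-iter 10 --outdir run1/
mitobait finish   --contigs run1/contigs.fa --reads trimmed/trimmed.fq \
                  --guide closest.fa --guide-gff closest.gff3 \
                  --out mito.fa --gff mito.gff3 --report finish_report.json
mitobait leakage  --contigs run1/contigs.fa --target mito.fa \
                  --nuclear nuc.fa --contaminants cont.fa --out leakage.tsv
mitobait coverage --reads trimmed/trimmed.fq --mito mito.fa --gff mito.gff3 --outdir cov/
```

`mitobait recruit` and `mitobait assemble` expose the two inner steps
individually; `mitobait run --no-early-stop` reproduces a fixed iteration
count instead of stopping at the recruitment plateau.

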