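# viroscan

Reusable pipeline for insect RNA-virome analysis: viral-contig triage from
transcriptome assemblies, virus-derived small-RNA (vsRNA) profiling with
siRNA/piRNA signature classification, and viral abundance quantification
(qPCR-based and read-count-based). Ships with a 13-virus / 16-record
medfly virus catalogue and a synthetic-data generator that plants known
ground truth for every stage.

## Modules

| module               | what it does |
|----------------------|--------------|
| `viroscan.catalog`   | Typed virus catalogue (TSV + optional FASTA integrity check), summaries, per-virus queries. |
| `viroscan.triage`    | Contig filtering cascade (viral hit ≤ 1e-5 → length ≥ 2000 nt → no host hit ≤ 1e-100 → has ORF), built-in six-frame ORF scanner, terminal-coverage confirmation. |
| `viroscan.srnamap`   | FASTQ cleaning (18–32 nt window, >20% low-quality removal, low-complexity), built-in seed-and-verify matcher (exact or ≤1 mismatch, both strands). |
| `viroscan.profile`   | Read collapsing; per-virus profiles: unique-read %, length-by-strand histograms, 5′-base composition, per-strand coverage, breadth. |
| `viroscan.classify`  | Signature calls — siRNA (21±1 nt peak, bidirectional), piRNA (24–29 nt modal, 5′-U bias), degradation, absent — plus a recovery power-curve harness. |
| `viroscan.abundance` | qPCR relative abundance `E_v^-Ct_v / E_r^-Ct_r`, standard-curve fitting and genomes-per-µg inversion, read-count relative abundance, prevalence matrices. |
| `viroscan.simulate`  | Deterministic generators: genomes, class-labelled sRNA libraries, Ct values on a standard curve, contig sets with planted keep/discard truth. |
| `viroscan.cli`       | `viroscan` command wiring the workflows together. |

## CLI

```bash
# catalogue facts
viroscan catalog-summary

# contig triage: FASTA + two 12-column tabular homology-hit tables
viroscan discover --contigs contigs.fasta --viral-hits viral.tsv \
    --host-hits host.tsv --outdir out/

# small-RNA workflow: clean -> map -> collapse -> profile -> classify
viroscan srna-profile --fastq lib.fastq --genomes viruses.fasta \
    --sample-id ovary1 --outdir out/

# abundance from a Ct table (sample, target, ct, efficiency) or a
# counts table (sample, target, counts); reference target defaults to L23a
viroscan abundance --ct-table ct.tsv --outdir out/

# synthetic fixtures with serialized ground truth
viroscan simulate genome --length 2896 --seed 1 --out genome.fasta
viroscan simulate srna --genome-fasta genome.fasta --n-reads 10000 --outdir lib/
viroscan simulate contigs --n 200 --seed 7 --outdir ctg/
```

Every run writes `run_metadata.json` (version, resolved config, seeds) next
to its outputs. All thresholds are configurable via flags or `--config`
YAML; results are plain TSV.

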