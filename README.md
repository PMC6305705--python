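# darkmeter

Quantify **microbial dark matter** in 16S rRNA amplicon surveys: how
divergent environmental reads are from the nearest 16S rRNA gene of a
*completely sequenced* genome.

Marker-gene surveys routinely detect lineages for which no genome — and
hence no physiology, no metabolism, no model strain — is available.
`darkmeter` measures that gap. For every dereplicated ("unique") amplicon
read it finds the nearest reference genome on a 16S phylogeny and reports
the **map ratio**

> r = (identical aligned positions) / (read length)

from an optimal semi-global alignment of the read within the full-length
reference gene (reference overhangs free; `N` never matches). A map ratio
near 1 means the organism is well represented by a sequenced genome; low
values mark candidate dark matter. The package is aimed at microbial
ecologists who want a database-representation audit of an amplicon
dataset, not a taxonomy pipeline.

## What it computes

- **QC**: reads truncated at the first base below Q20, dropped under
  75 nt, then dereplicated into unique reads with per-sample counts
  (optional greedy 1-mismatch collapse of rare near-duplicates).
- **Domain assignment**: best semi-global alignment score against
  Bacteria/Archaea reference panels; ties and sub-cutoff scores are
  unassigned and excluded downstream.
- **Placement**: nearest reference(s) by identity, found with a shared
  k-mer prefilter that provably returns the exhaustive-scan result; a
  unique best reference places the read on that tip's edge, ties place it
  on the edge above the MRCA of the tied references.
- **Copy-number normalization**: each edge's read count divided by the
  16S gene copy number expected at that tree position (tip edges: the
  genome's copy number; internal edges: mean over subtended tips), since
  a taxon with 10 rRNA operons yields ~10× the reads per cell.
- **Survey statistics**: read-weighted per-sample mean map ratios with
  flagging (>1,000 reads and mean < 0.8); the dark-read rule
  `r < 0.075·log10(abundance) + 0.4`; top-10 most abundant low-identity
  edges per domain; analytic (hypergeometric) rarefaction curves; and the
  regression of unique-read richness on per-environment sampling effort.
- **Synthetic surveys**: a generator producing a reference tree +
  genomes + copy numbers and per-sample FASTQ reads from both in-database
  taxa and constructed dark lineages at *exact* divergences, with a full
  truth table — so every stage is testable without external data.

## Worked example

```python
from darkmeter import Config, SynthParams
from darkmeter.pipeline import run_all

manifest = run_all(Config(seed=1), "out", synth_params=SynthParams(seed=1))
print(manifest["ledger"])
print(manifest["regression"])
```

prints

```
{'reads_raw': 1842, 'reads_qc': 1766, 'uniques_dereplicated': 595,
 'uniques_final': 270, 'reads_bacteria': 220, 'reads_archaea': 1546,
 'reads_unassigned': 0, 'reads_placed': 1766}
{'r_squared': 0.9465065502183404, 'p_value': 0.14858695342352,
 'slope': 8.5, 'intercept': -2.666666666666666}
```

Of 1,842 simulated forward reads, 1,766 survive the Q20/75 nt filter and
dereplicate to 270 unique reads, all of which receive a domain and a
placement (read counts are conserved at every stage and checked). The
regression line says each additional sample in an environment recovers
about 8.5 additional unique bacterial reads, with sampling effort
explaining ~95% of the richness variance across the three synthetic
environments. `out/` contains the per-read placements
(`placements.tsv`), normalized edge abundances (`edge_abundance.tsv`),
sample/environment summaries, dark-read and dark-edge tables,
rarefaction curves, and a `manifest.json` sufficient to reproduce the
run byte for byte.

The same stages are available from the shell:

```bash
darkmeter synth --n-refs 20 --seed 1 --out-dir survey/
darkmeter qc --in survey/reads/run000.fastq --out-prefix run000
darkmeter run --seed 1 --out-dir out/
```

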