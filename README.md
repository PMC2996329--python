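# nahrkit

Tools for studying non-allelic homologous recombination (NAHR) between
dispersed repeat families. The package has two engines plus the glue to
run them end to end:

1. **Repeat-family homology profiler** — all-vs-all pairwise metrics over
   an annotated repeat catalog:
   * *overall identity*: percent identity of the optimal affine-gap global
     (Needleman–Wunsch) alignment, gap columns included in the denominator;
   * *longest block*: exact longest block of uninterrupted (100%) identity
     (longest common substring), with the local-hit-scanning heuristic
     available as a cross-check;
   * *local identity*: best Smith–Waterman score under +1/−3 with affine
     gaps, rescaled to a Karlin–Altschul bit score.
   On top of the matrices: MEPS binning (250-bp bins, inclusive ≥250
   threshold), within/between-family identity statistics, heat-map CSV
   export, and recipient→donor rankings with deterministic tie-breaking.
2. **Nonselective clone-assay outcome estimator** — genetic-class
   frequencies among cut clones, background subtraction with a
   >50%-background QC gate, normalization to 100%, plug-weighted outcome
   frequencies, a weighted binomial SEM (`sqrt(pq/n)` × class percent)
   with assigned-count edge cases, replicate-based chromosome-loss SEM,
   and derived summaries: break-distal-rearrangement (BDR) totals and
   copy-number-change categorization.

A synthetic-data module (`nahrkit.simulate`) generates repeat families
evolved from a common ancestor under uniform or clustered divergence
(with optional indels) and clone assays drawn from a known outcome truth,
so everything is testable offline.

## Command line

The console script `nahrkit` exposes five subcommands; every run writes a
JSON manifest next to its outputs.

```bash
# load + dump a catalog (FASTA + BED/GFF3)
nahrkit catalog --fasta elements.fasta --annotation elements.bed --out-dir out/

# all-vs-all metrics (long-form TSV + square CSV per metric)
nahrkit homology --fasta elements.fasta --annotation elements.bed \
    --families TY1,TY2 --out-dir out/

# MEPS fraction, heat-map CSV, family stats, donor rankings
nahrkit summary --fasta elements.fasta --annotation elements.bed \
    --recipient someTy1 --out-dir out/

# clone tables -> outcome-frequency table with SEMs and summaries
nahrkit estimate --clone-counts clone_counts.tsv --plugs plugs.tsv \
    --strain MH3359 --out-dir out/

# synthetic families / estimator recovery reports
nahrkit simulate --mode family --seed 1 --out-dir out/
nahrkit simulate --mode recovery --seed 1 --out-dir out/
```

Input TSV formats: `clone_counts.tsv` with columns
`strain condition n_scored n_hygS class_I class_II class_III class_other`,
and `plugs.tsv` with `strain class type count` (class `I`/`II`, type one
of `allelic internal_deletion intra_ty_deletion ty_gc isochromosome ring
translocation other`).

## Genome-scale reproduction (optional, external data)

The published genome-wide numbers (family identity means, 891/1225 and
544/46,665 MEPS fractions, specific donor ranks) require the original
deposited sequence catalog (GenBank GU224294/GU220389/GU220390 plus the
SGD non-ORF dataset of 2010-01-05), which is not bundled. Given those
sequences as FASTA/BED, the same workflow applies:

```bash
nahrkit homology --fasta ty_catalog.fasta --annotation ty_catalog.bed --out-dir genome/
nahrkit summary  --fasta ty_catalog.fasta --annotation ty_catalog.bed --out-dir genome/
```

Two conventions are deliberately configurable because the original
analysis does not pin them down: the global substitution matrix
(default +5/−4) and strand handling for oppositely oriented elements
(default: best of forward and reverse-complement).

## Layout

```
src/nahrkit/
  catalog.py    repeat elements, corrections, pair enumeration, FASTA/BED/GFF3 I/O
  homology.py   global identity, longest perfect block, local hits, bit scores, matrices
  summary.py    MEPS binning, family stats, heat-map tables, donor rankings
  estimator.py  clone-assay estimator, weighted SEM, BDR / copy-number summaries
  simulate.py   family evolution and clone-assay simulators, recovery experiments
  io.py         clone-table readers, outcome-table writer, run manifests
  cli.py        click CLI binding it together
tests/          pytest suite (unit, property and acceptance tests)
scripts/acceptance.py
```
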