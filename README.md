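# airr-repkit

A toolkit for the **AIRR Rearrangement data standard** — the tab-delimited,
schema-typed file format used to exchange annotated adaptive immune receptor
(antibody/IG and T cell receptor/TR) repertoire sequencing data between
annotation tools, analysis pipelines and repositories.

It is written for people who produce or consume AIRR-seq annotation tables:
tool authors who need strict, predictable I/O; analysts who need to validate
files arriving from heterogeneous pipelines; and engineers who need to read
very large repertoire files in parallel.

## What it does

* **Schema as data** — the Rearrangement column catalogue (standard v1.2.0:
  eight field categories, required-column flags, strict value types, the
  `X.Y.Z` semantic-versioning rules) is a bundled YAML document, loadable and
  replaceable at run time.
* **Strict typed TSV I/O** — UTF-8, tab-delimited, no quoting; every field is
  nullable via the empty string; readers accept any column order, writers emit
  the canonical order bit-stably; custom columns pass through untyped.
  Transparent gzip/bzip2/BGZF decompression.
* **Splittable access** — records can be read starting from *any* byte offset
  of a plain or BGZF (blocked gzip) file, with exact record-boundary recovery,
  so a large file can be ingested in parallel partitions. Plain gzip is
  detected and refused with a pointer to splittable alternatives.
* **Validation** — machine-readable rule registry (missing required columns,
  type violations, 1-based closed interval consistency, junction length
  arithmetic, CIGAR span vs. coordinate agreement, region bounds, alignment
  length equality, alphabet and identity-scale warnings), with stable rule ids
  and error/warning severities.
* **Alignment algebra** — CIGAR parsing/building, gapped-alignment
  reconstruction, BLAST BTOP → CIGAR conversion, and the coordinate
  bijections between 1-based closed intervals (SAM/VCF/GFF/IMGT convention)
  and 0-based half-open pairs, plus end↔length transforms for legacy dialects.
* **Legacy conversion** — mapping profiles (data files, not code) that convert
  Change-O-like and IMGT-summary-like tables into valid Rearrangement TSVs,
  including end-from-length interval arithmetic, base shifts, boolean
  normalization and BTOP→CIGAR.
* **Synthetic data** — a V(D)J recombination simulator over a bundled toy
  germline set (`TOY*` alleles, so nothing masquerades as a real gene) that
  emits fully self-consistent, validator-clean records with a hidden truth
  ledger, plus targeted single-rule corruptions for sensitivity testing.

## The model in brief

A rearrangement record describes one recombined receptor chain: the query
`sequence`, gene calls (`v_call`, `d_call`, `j_call`), the junction (the
nucleotide span from the conserved V-anchor codon through the conserved
J-anchor codon, whose translation is the CDR3 plus anchors), per-gene
alignments encoded as CIGAR strings with 1-based closed `*_start`/`*_end`
coordinates on both query and germline, framework/CDR region annotations, and
junction sub-region lengths (`np1_length`, `np2_length`, ...).

The simulator draws V, (D,) J uniformly; trims each recombination-exposed end
by a geometric number of nucleotides (mean 2); inserts Poisson-length (mean 4)
untemplated nucleotides between segments; and applies uniform point mutations
(default rate 0.01/nt). Every derived annotation is computed from that truth,
which is what makes the validator/simulator pair a closed test system: the
two are independent code paths, so agreement is evidence, not tautology.

## Worked example

```bash
$ airr-repkit simulate -n 500 --seed 7 -o repertoire.tsv
500 records simulated into repertoire.tsv
$ airr-repkit validate repertoire.tsv
{
  "total_records": 500,
  "error_count": 0,
  "warning_count": 0,
  "passed": true,
  "by_rule": {}
}
$ airr-repkit stats repertoire.tsv
records 500
productive_fraction 0.2580
mean_junction_length 47.00
```

The simulated file carries 66 typed columns plus a `repertoire.tsv.truth.yaml`
sidecar with the hidden generation parameters per record. `passed: true`
means zero error-severity rule violations across all 500 records. The
productive fraction (~0.26) is what raw, selection-free V(D)J recombination
gives: roughly one third of junctions land in frame, and some of those carry
stop codons. Mean junction length reflects the toy germline anchors plus two
Poisson(4) insertions and geometric(mean 2) trims.

Library use mirrors the CLI:

```python
import airr_repkit as ark

report, records = ark.read_rearrangements("repertoire.tsv")
for rec in records:
    if rec["productive"]:
        print(rec["sequence_id"], rec["junction_aa"])
```

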