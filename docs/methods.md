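# Methods

This note documents the design of airr-repkit: the data model it implements,
the conventions it fixes where the standard leaves room, the synthetic-data
generator's model and its limits, and the numerical/tie-break choices that
matter for reproducibility.

## The schema model

The Rearrangement schema ships as a YAML document
(`src/airr_repkit/data/rearrangement_schema.yaml`), not as code. Each field
declares a name, one of eight categories (input, primary annotations,
alignment annotations, alignment positions, region sequence, region
positions, junction lengths), a value kind, and a required flag. Value kinds
are derived from name suffixes where a convention exists (`_aa` → amino acid
sequence, `_start`/`_end` → 1-based coordinate, `_cigar` → CIGAR text,
`_alignment` → gapped nucleotide sequence, `_score`/`_identity`/`_support` →
number); a declared kind that contradicts its suffix is a load-time error.
Loading also enforces that every `*_start` has a `*_end` partner in the same
category. "Required" means the column must be present in the header — every
field, required or not, is nullable, encoded as the empty string on disk.
The required set marks the catalogue's core columns (identifiers, sequence,
gene calls, orientation/productivity flags, junction and its translation,
per-gene CIGARs, the aligned sequence pair); `sequence_aa` and `c_call` are
optional. Because field names are stable by policy (deprecate-and-replace,
never rename), corrections to the catalogue are config edits.

Version numbers follow X.Y.Z semantics: major for changes spanning multiple
standards, minor for schema/API changes, patch for software/documentation
updates. `classify_version_change` reports the highest-order differing
component and is direction-symmetric.

## TSV dialect

The dialect is deliberately minimal so that a newline is always a record
boundary: no quoting, no escaping, no comment or meta-information section.
Tab and newline are therefore forbidden inside values and rejected at write
time. Readers accept any column order and `\r\n` line endings; writers
always emit the canonical schema order (then custom columns in first-seen
order), `\n` endings, and canonical value spellings — booleans as `T`/`F`
(`TRUE/true/FALSE/false` accepted on read), floats via the shortest
round-tripping decimal representation, gaps as `-` (`.` accepted on read as
an IMGT-habit synonym). These canonical forms are what make
write→read→write byte-identical; a file using non-canonical but legal
spellings re-canonicalizes on the first write and is byte-stable thereafter.

Strict reads abort on a missing required column, a wrong cell count, or an
unparseable cell; lenient reads record these as structured issues (bad rows
skipped, bad cells nulled) that dataset validation re-surfaces as `ROW_SHAPE`
and `TYPE` errors.

## Splittable access

Compression containers are detected from magic bytes, never file names.
Plain files and BGZF (blocked gzip) support reading from an arbitrary byte
offset; standard gzip is refused with an explanatory error. bzip2 is read
transparently and labelled splittable in principle, but arbitrary-offset
decoding is not implemented: its block boundaries are bit-aligned rather
than byte-aligned, and BGZF covers the parallel-ingestion use case.

Record-to-partition assignment uses the line-start rule: a record belongs to
the partition `[a, b)` that contains its first byte. The reader seeking to
offset `a > 0` checks whether byte `a-1` is a newline — if so it is already
at a record boundary, otherwise it discards through the next newline (the
straddling record belongs to the previous partition). For BGZF the offsets
address the compressed stream; a record's position is the pair (compressed
block offset, within-block offset) taken from the reader's virtual offset,
which interleaves totally with raw byte offsets. A partition boundary
falling mid-block is resolved by decompressing the preceding block to learn
whether the next block begins at a record boundary. This makes the multiset
union over any partition equal the sequential read exactly, with no record
lost or duplicated — the property the acceptance checks measure.

Dataset concatenation treats an ordered list of files (or a directory) as
one logical dataset. Compatibility requires an identical set of
schema-required columns across members; optional and custom columns are
resolved as the union, null-filled where absent. This is the permissive
reading of "compatible schema"; requiring identical optional columns would
reject legitimately mergeable outputs of the same pipeline version.

## Validation rules

Rules have stable ids and severities (see `validation.py` for the registry).
Two policies shape them. First, cross-field rules fire only when every
participating field is non-null — nullability is universal, so absence is
never a record-level error. Second, context-dependent fields
(`_score`, `_identity`, `_support`) are checked for numeric parseability
only, since their definitions legitimately vary between annotation tools;
identity additionally warns outside both the fraction and percent scales.

The CIGAR span rule compares the *aligned* spans of a gene CIGAR — query
consumption excluding soft clips (S), reference consumption excluding skips
(N) — against the `*_start`/`*_end` interval lengths. This is the only
definition consistent with CIGARs that cover the whole read using S for
query nucleotides outside the gene segment, which is how this package (and
AIRR-emitting annotators) write them. The general `spans()` accounting
function still counts S and N as consuming, per the SAM consumption table.

The productive flag is validated as a boolean only by default; the
frame/stop cross-check is opt-in (`RuleConfig(strict_productive=True)`,
CLI `--strict`) because annotation tools differ on what "productive"
incorporates (V frame, junction frame, stops outside the junction).
The junction-length rule checks internal string/length consistency only
(`junction_length == len(junction)`), not anchor semantics.

## Conversion profiles

Legacy-dialect correspondence lives in YAML profiles with an ordered list of
(source column, target field, transform) entries plus dialect options
(delimiter, null-token vocabulary, coordinate base). Transforms:
copy/rename, end-from-length and length-from-end (closed-interval
arithmetic, delegating to the coordinate algebra; a zero-length feature maps
to a null end, since a closed interval cannot be empty), base shift,
boolean normalization with configurable token sets, BTOP→CIGAR, and drop.
The two bundled profiles are best-effort renditions of the Change-O-like and
IMGT-summary-like dialects, versioned in their own documents precisely
because such correspondences get revised.

Export (`export_legacy`) inverts the invertible transforms; BTOP→CIGAR is
not invertible without the aligned sequences, so round-trip workflows pass
the profile through `invertible_profile()` first. Conversion never invents
values: every non-null target traces to exactly one source cell.

## The synthetic-data generator

The generator emulates the *structure* of annotated rearrangement data, not
the biology of recombination. Per record it draws V, (D,) J uniformly from
the bundled toy set (4 V of 69–75 nt, 3 D of 12–18 nt, 3 J of 33 nt, named
with a `TOY` prefix; conserved Cys/Trp anchor codons and tiling V-region
boundaries are germline metadata in the YAML sidecar, so the junction
convention — V anchor through J anchor, both inclusive — is explicit data).

Stochastic parameters (defaults chosen once as field-realistic): geometric
trims with success parameter 1/3 (mean 2 nt) per exposed end, truncated by
rejection so the V and J anchor codons and at least one templated D
nucleotide survive; Poisson(4) untemplated-insertion lengths per np region;
uniform point substitutions at rate 0.01/nt applied to the assembled
sequence; duplicate counts 1+Poisson(1.5). A geometry that cannot satisfy
the trim bounds resamples the offending draw, erroring only after 1000
retries (unreachable under the bundled set). The same seed yields
byte-identical datasets.

Annotations are derived from the truth: per-gene CIGARs cover the full query
(M over the aligned segment, S elsewhere — the simulator introduces no
indels, so mutations are M-run-preserving substitutions);
`germline_alignment` is the pre-mutation assembled sequence, so the aligned
pair differs exactly at the mutated positions (np nucleotides are carried
as-is rather than N-masked); `productive` is recomputed from the mutated
sequence as in-frame junction with stop-free translation, so roughly a
quarter of records are productive — raw recombination without selection.
Region coordinates reuse the V germline intervals (valid because V aligns
from query position 1 without indels), CDR3 is the junction minus both
anchor codons, FWR4 the remainder of J.

What passing tests therefore show: the reader/writer, validator, coordinate
algebra and converters are exact on data whose ground truth is known and
whose geometry spans the schema's null patterns (light-chain sets exercise
null D fields; out-of-frame junctions exercise null translations). What
they do not show: robustness to real annotation-tool quirks (indel-bearing
alignments, IMGT-gapped numbering, allele-call ambiguity strings), or any
statistical realism of repertoires — there is no clonal structure, no
gene-usage bias, no position-dependent mutation hotspots.

Targeted corruptions (`corrupt_record`) perturb exactly the fields governed
by one rule, chosen so no other rule starts firing (for instance the
interval corruption swaps a region pair that stays inside the sequence
bounds; the type corruption plants a wrong-typed in-memory value and is
therefore excluded from corruptions that must be writable to disk).

## Numerical and statistical choices

Coordinates are validated as integers ≥ 1; the 1-based-closed ↔
0-based-half-open maps are exact bijections, tested as such. Floats render
via Python's shortest round-tripping `repr`; NaN and infinities are rejected
at coercion since record equality and byte stability both break under them.
CIGAR canonical form merges adjacent equal operators; M-style emission is
the default (maximal tool compatibility), `=X`-style is available and both
are accepted on read.

The statistical self-checks compare simulator output against its own model:
the observed mutation fraction must fall within 3 binomial standard errors
of the rate; trim histograms are tested by chi-square against the exact
per-record bound-truncated geometric mixture (truncation is not ignorable —
the shortest V tolerates only 6 nt of trimming); insertion histograms
against Poisson with a tail bin, merging bins upward until expected counts
reach 5. At α=0.01 these tests are calibrated (≈1% rejection over repeated
seeds), so a rare failure on one seed is the expected behavior of a correct
generator, not a regression signal in itself.

Problem sizes in the test suite and acceptance script (1,000-record round
trips, 10,000-record split-read files with 50 partitions per container,
10,000 random alignments and BTOP strings, n=5,000 statistical checks) were
chosen as the package's own desk-scale reference conditions; the whole suite
runs in well under a minute.

## Known limitations

* No IMGT/KABAT numbering support in `_alignment` fields ("lack thereof" is
  implemented); gapped germline reconstruction is out of scope.
* bzip2 offset reads unimplemented (see above).
* The multi-file join helper for IMGT-style outputs is a plain outer join on
  a user-named key; it does not reconcile duplicated column names beyond
  last-writer-wins.
* Companion metadata documents are read and written as opaque
  well-formedness-checked YAML; no metadata element vocabulary is enforced.
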