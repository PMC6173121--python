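# Best-effort correspondence for an IMGT/HighV-QUEST-style summary table.
# Only a single joined summary-style table is supported per invocation; the
# multi-file outputs of the original tool can be pre-joined on a key column
# (see converters.join_on_key).
name: imgt-summary-like
profile_version: "0.1"
dialect:
  delimiter: "\t"
  null_tokens: ["", "null", "-"]
  base: 1
mappings:
  - {source: Sequence ID, target: sequence_id, transform: copy}
  - {source: Sequence, target: sequence, transform: copy}
  - {source: Functionality, target: productive, transform: bool_norm,
     args: {true_tokens: [productive], false_tokens: [unproductive, "non-productive"]}}
  - {source: Orientation, target: rev_comp, transform: bool_norm,
     args: {true_tokens: ["rev-comp"], false_tokens: ["+"]}}
  - {source: V-GENE and allele, target: v_call, transform: copy}
  - {source: D-GENE and allele, target: d_call, transform: copy}
  - {source: J-GENE and allele, target: j_call, transform: copy}
  - {source: JUNCTION, target: junction, transform: copy}
  - {source: JUNCTION (AA), target: junction_aa, transform: copy}
  - {source: JUNCTION frame, transform: drop}
  - {source: V-REGION identity %, target: v_identity, transform: copy}
  - {source: V-REGION score, target: v_score, transform: copy}
  - {source: CDR1-IMGT, target: cdr1, transform: copy}
  - {source: CDR2-IMGT, target: cdr2, transform: copy}
  - {source: CDR3-IMGT, target: cdr3, transform: copy}
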