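# Best-effort correspondence for Change-O-style annotation tables.
# Profile documents are data, versioned independently of the code, because
# the source dialect may be revised; unknown columns in a source file are
# simply ignored, and unmapped target fields stay null.
name: changeo-like
profile_version: "0.1"
dialect:
  delimiter: "\t"
  null_tokens: ["", "None", "NA"]
  base: 1
mappings:
  - {source: SEQUENCE_ID, target: sequence_id, transform: copy}
  - {source: SEQUENCE_INPUT, target: sequence, transform: copy}
  - {source: LOCUS, target: locus, transform: copy}
  - {source: REV_COMP, target: rev_comp, transform: bool_norm}
  - {source: FUNCTIONAL, target: productive, transform: bool_norm}
  - {source: V_CALL, target: v_call, transform: copy}
  - {source: D_CALL, target: d_call, transform: copy}
  - {source: J_CALL, target: j_call, transform: copy}
  - {source: C_CALL, target: c_call, transform: copy}
  - {source: JUNCTION, target: junction, transform: copy}
  - {source: JUNCTION_AA, target: junction_aa, transform: copy}
  - {source: JUNCTION_LENGTH, target: junction_length, transform: copy}
  - {source: NP1_LENGTH, target: np1_length, transform: copy}
  - {source: NP2_LENGTH, target: np2_length, transform: copy}
  - {source: SEQUENCE_VDJ, target: sequence_alignment, transform: copy}
  - {source: GERMLINE_VDJ, target: germline_alignment, transform: copy}
  - {source: V_SCORE, target: v_score, transform: copy}
  - {source: V_IDENTITY, target: v_identity, transform: copy}
  - {source: V_EVALUE, target: v_support, transform: copy}
  - {source: V_BTOP, target: v_cigar, transform: btop_to_cigar}
  - {source: J_SCORE, target: j_score, transform: copy}
  - {source: J_IDENTITY, target: j_identity, transform: copy}
  - {source: J_EVALUE, target: j_support, transform: copy}
  - {source: J_BTOP, target: j_cigar, transform: btop_to_cigar}
  - {source: V_SEQ_START, target: v_sequence_start, transform: copy}
  - {source: V_SEQ_LENGTH, target: v_sequence_end, transform: end_from_length,
     args: {start_source: V_SEQ_START}}
  - {source: V_GERM_START_VDJ, target: v_germline_start, transform: copy}
  - {source: V_GERM_LENGTH_VDJ, target: v_germline_end, transform: end_from_length,
     args: {start_source: V_GERM_START_VDJ}}
  - {source: D_SEQ_START, target: d_sequence_start, transform: copy}
  - {source: D_SEQ_LENGTH, target: d_sequence_end, transform: end_from_length,
     args: {start_source: D_SEQ_START}}
  - {source: D_GERM_START, target: d_germline_start, transform: copy}
  - {source: D_GERM_LENGTH, target: d_germline_end, transform: end_from_length,
     args: {start_source: D_GERM_START}}
  - {source: J_SEQ_START, target: j_sequence_start, transform: copy}
  - {source: J_SEQ_LENGTH, target: j_sequence_end, transform: end_from_length,
     args: {start_source: J_SEQ_START}}
  - {source: J_GERM_START, target: j_germline_start, transform: copy}
  - {source: J_GERM_LENGTH, target: j_germline_end, transform: end_from_length,
     args: {start_source: J_GERM_START}}
  - {source: DUPCOUNT, target: duplicate_count, transform: copy}
  - {source: CONSCOUNT, target: consensus_count, transform: copy}
  - {source: IN_FRAME, transform: drop}
  - {source: STOP, transform: drop}
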