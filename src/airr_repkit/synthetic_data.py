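"""Stochastic V(D)J rearrangement simulator over a toy germline set.

The generator exists so the whole toolkit is exercisable with zero
downloads: it emits fully self-consistent annotated rearrangements
(every field the schema defines, with coherent coordinates, CIGARs and
gapped alignments) plus a hidden truth ledger, and targeted minimal
corruptions for validator-sensitivity fixtures.

Model: pick V, (D,) J uniformly from the germline set; trim each
recombination-exposed end by a geometric number of nucleotides; insert
untemplated (np) nucleotides of Poisson-distributed length between the
segments; apply uniform point mutations at rate ``mutation_rate`` per
nucleotide.  The junction runs from the conserved V anchor codon
through the conserved J anchor codon, both inclusive; the anchors are
germline metadata, not code.  No clonal structure, no indel errors, no
biological realism of the recombination statistics is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from Bio.Seq import Seq

from .alignment_utils import Interval
from .errors import SimulationError
from .tsv_io import RearrangementRecord, write_rearrangements
from .schema_model import RearrangementSchema, default_schema

NUCLEOTIDES = "ACGT"


@dataclass(frozen=True)
class GermlineGene:
    """A toy germline segment with its junction anchors and V regions.

    ``junction_start`` (V only): 1-based, codon-aligned position of the
    first nucleotide of the conserved Cys codon — the junction begins
    here.  ``junction_end`` (J only): 1-based position of the last
    nucleotide of the conserved Trp/Phe codon — the junction ends here.
    ``regions`` (V only) tile ``[1, junction_start - 1]`` without
    overlap.
    """

    name: str
    segment: str
    sequence: str
    junction_start: int | None = None
    junction_end: int | None = None
    regions: Mapping[str, Interval] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.segment not in ("V", "D", "J"):
            raise ValueError(f"unknown segment {self.segment!r}")
        n = len(self.sequence)
        if self.segment == "V":
            js = self.junction_start
            if js is None or not (1 <= js <= n) or js % 3 != 1:
                raise ValueError(f"{self.name}: junction_start {js!r} not codon-aligned "
                                 f"within [1, {n}]")
            cursor = 1
            for region, iv in self.regions.items():
                if iv.start != cursor:
                    raise ValueError(f"{self.name}: region {region} starts at {iv.start}, "
                                     f"expected {cursor} (regions must tile)")
                cursor = iv.end + 1
            if self.regions and cursor != js:
                raise ValueError(f"{self.name}: regions end at {cursor - 1}, expected "
                                 f"{js - 1}")
        if self.segment == "J":
            je = self.junction_end
            if je is None or not (3 <= je <= n):
                raise ValueError(f"{self.name}: junction_end {je!r} outside [3, {n}]")


@dataclass(frozen=True)
class GermlineSet:
    """Gene lists per segment; D may be empty (light-chain-like locus)."""

    v_genes: tuple[GermlineGene, ...]
    d_genes: tuple[GermlineGene, ...]
    j_genes: tuple[GermlineGene, ...]
    locus: str = "TOYH"

    def __post_init__(self) -> None:
        if not self.v_genes or not self.j_genes:
            raise ValueError("germline set needs at least one V and one J gene")

    @property
    def has_d(self) -> bool:
        return bool(self.d_genes)


def load_germline_set(fasta_path: str | Path, anchors_path: str | Path,
                      locus: str = "TOYH", include_d: bool = True) -> GermlineSet:
    """Assemble a :class:`GermlineSet` from FASTA + YAML anchor sidecar."""
    sequences: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(fasta_path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
    if name is not None:
        sequences[name] = "".join(parts)
    with open(anchors_path, "r", encoding="utf-8") as fh:
        anchors = yaml.safe_load(fh)
    by_segment: dict[str, list[GermlineGene]] = {"V": [], "D": [], "J": []}
    for entry in anchors["genes"]:
        gname = entry["name"]
        if gname not in sequences:
            raise ValueError(f"anchor sidecar names {gname!r} absent from FASTA")
        regions = {region: Interval(lo, hi)
                   for region, (lo, hi) in entry.get("regions", {}).items()}
        gene = GermlineGene(
            name=gname,
            segment=entry["segment"],
            sequence=sequences[gname],
            junction_start=entry.get("junction_start"),
            junction_end=entry.get("junction_end"),
            regions=regions,
        )
        by_segment[gene.segment].append(gene)
    return GermlineSet(
        v_genes=tuple(by_segment["V"]),
        d_genes=tuple(by_segment["D"]) if include_d else (),
        j_genes=tuple(by_segment["J"]),
        locus=locus,
    )


def toy_germline_set(include_d: bool = True) -> GermlineSet:
    """The bundled toy germline set; ``include_d=False`` gives a light-chain-like
    locus exercising the null paths for D-dependent fields."""
    data = resources.files("airr_repkit").joinpath("data")
    with resources.as_file(data.joinpath("toy_germline.fasta")) as fasta, \
            resources.as_file(data.joinpath("toy_germline_anchors.yaml")) as anchors:
        return load_germline_set(fasta, anchors,
                                 locus="TOYH" if include_d else "TOYL",
                                 include_d=include_d)


@dataclass(frozen=True)
class RecombinationModel:
    """Stochastic parameters of the simulator.

    ``trim_p``: geometric success parameter per trimmed end (support
    {0, 1, 2, ...}; mean (1-p)/p, so the default 1/3 trims 2 nt on
    average).  ``np1_mean``/``np2_mean``: Poisson means for untemplated
    insertion lengths.  ``mutation_rate``: per-nucleotide substitution
    probability in [0, 1).  ``seed`` makes dataset generation
    deterministic: same seed, same bytes.
    """

    trim_p: float = 1 / 3
    np1_mean: float = 4.0
    np2_mean: float = 4.0
    mutation_rate: float = 0.01
    duplicate_mean: float = 1.5
    consensus_extra_mean: float = 3.0
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if not (0 < self.trim_p <= 1):
            raise ValueError("trim_p must be in (0, 1]")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation_rate must be in [0, 1)")
        if self.np1_mean < 0 or self.np2_mean < 0:
            raise ValueError("insertion means must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """A simulated record plus the hidden ground truth it derives from."""

    record: RearrangementRecord
    v_name: str
    d_name: str | None
    j_name: str | None
    v_3_trim: int
    d_5_trim: int
    d_3_trim: int
    j_5_trim: int
    np1: str
    np2: str | None
    mutated_positions: tuple[int, ...]  # 1-based positions in the query
    premutation_sequence: str

    def truth_dict(self) -> dict:
        return {
            "v_name": self.v_name, "d_name": self.d_name, "j_name": self.j_name,
            "v_3_trim": self.v_3_trim, "d_5_trim": self.d_5_trim,
            "d_3_trim": self.d_3_trim, "j_5_trim": self.j_5_trim,
            "np1": self.np1, "np2": self.np2,
            "mutated_positions": list(self.mutated_positions),
            "premutation_sequence": self.premutation_sequence,
        }


def _bounded_geometric(rng: np.random.Generator, p: float, bound: int,
                       max_retries: int, what: str) -> int:
    """Geometric draw on {0,1,...}; resample while it exceeds ``bound``."""
    if bound < 0:
        raise SimulationError(f"impossible geometry: no room to trim {what}")
    for _ in range(max_retries):
        k = int(rng.geometric(p)) - 1  # numpy's support is {1,2,...}
        if k <= bound:
            return k
    raise SimulationError(f"could not draw a {what} trim <= {bound} after "
                          f"{max_retries} tries")


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(NUCLEOTIDES[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, sequence: str, rate: float,
            ) -> tuple[str, tuple[int, ...]]:
    if rate == 0 or not sequence:
        return sequence, ()
    hits = np.flatnonzero(rng.random(len(sequence)) < rate)
    chars = list(sequence)
    positions = []
    for i in hits:
        original = chars[i]
        alternatives = [b for b in NUCLEOTIDES if b != original]
        chars[i] = alternatives[int(rng.integers(0, 3))]
        positions.append(int(i) + 1)
    return "".join(chars), tuple(positions)


def simulate_rearrangement(germline_set: GermlineSet, model: RecombinationModel,
                           rng: np.random.Generator,
                           schema: RearrangementSchema | None = None,
                           sequence_id: str = "sim-000000") -> TruthRecord:
    """Draw one annotated rearrangement and its truth ledger.

    All coordinates in the emitted record are 1-based closed; per-gene
    CIGARs cover the entire query, with S for the query nucleotides
    outside the aligned gene segment.  ``productive`` is recomputed
    from the *mutated* sequence: in-frame junction and no stop codon in
    its translation.
    """
    if schema is None:
        schema = default_schema()
    v = germline_set.v_genes[int(rng.integers(0, len(germline_set.v_genes)))]
    j = germline_set.j_genes[int(rng.integers(0, len(germline_set.j_genes)))]
    d = None
    if germline_set.has_d:
        d = germline_set.d_genes[int(rng.integers(0, len(germline_set.d_genes)))]

    # trims: keep the whole V anchor codon, the whole J anchor codon, and
    # at least one templated D nucleotide
    v_3_trim = _bounded_geometric(rng, model.trim_p,
                                  len(v.sequence) - (v.junction_start + 2),
                                  model.max_retries, "V 3'")
    j_5_trim = _bounded_geometric(rng, model.trim_p, j.junction_end - 3,
                                  model.max_retries, "J 5'")
    if d is not None:
        d_5_trim = _bounded_geometric(rng, model.trim_p, len(d.sequence) - 1,
                                      model.max_retries, "D 5'")
        d_3_trim = _bounded_geometric(rng, model.trim_p,
                                      len(d.sequence) - 1 - d_5_trim,
                                      model.max_retries, "D 3'")
    else:
        d_5_trim = d_3_trim = 0

    np1 = _random_nt(rng, int(rng.poisson(model.np1_mean)))
    np2 = _random_nt(rng, int(rng.poisson(model.np2_mean))) if d is not None else None

    v_part = v.sequence[: len(v.sequence) - v_3_trim]
    d_part = d.sequence[d_5_trim: len(d.sequence) - d_3_trim] if d is not None else ""
    j_part = j.sequence[j_5_trim:]
    pre = v_part + np1 + d_part + (np2 or "") + j_part
    sequence, mutated = _mutate(rng, pre, model.mutation_rate)

    # 1-based closed geometry on the query
    v_q = Interval(1, len(v_part))
    d_q = None
    cursor = len(v_part) + len(np1)
    if d is not None:
        d_q = Interval(cursor + 1, cursor + len(d_part))
        cursor += len(d_part) + len(np2 or "")
    j_q = Interval(cursor + 1, cursor + len(j_part))
    junction_start_q = v.junction_start
    junction_end_q = j_q.start + (j.junction_end - j_5_trim) - 1
    junction = sequence[junction_start_q - 1: junction_end_q]
    junction_aa = None
    if len(junction) % 3 == 0:
        junction_aa = str(Seq(junction).translate())
    productive = junction_aa is not None and "*" not in junction_aa

    n = len(sequence)

    def gene_cigar(iv: Interval) -> str:
        parts = []
        if iv.start > 1:
            parts.append(f"{iv.start - 1}S")
        parts.append(f"{iv.length}M")
        if iv.end < n:
            parts.append(f"{n - iv.end}S")
        return "".join(parts)

    def identity(iv: Interval) -> tuple[float, float, float]:
        mismatches = sum(1 for p in mutated if iv.start <= p <= iv.end)
        matches = iv.length - mismatches
        score = 5.0 * matches - 4.0 * mismatches
        ident = round(100.0 * matches / iv.length, 3)
        support = 2.0 ** (-max(score, 0.0))
        return score, ident, support

    values: dict = {name: None for name in schema.field_names}
    values.update({
        "sequence_id": sequence_id,
        "sequence": sequence,
        "locus": germline_set.locus,
        "v_call": v.name,
        "d_call": d.name if d is not None else None,
        "j_call": j.name,
        "rev_comp": False,
        "productive": productive,
        "junction": junction,
        "junction_aa": junction_aa,
        "duplicate_count": 1 + int(rng.poisson(model.duplicate_mean)),
        "sequence_alignment": sequence,
        "germline_alignment": pre,
        "junction_length": len(junction),
        "junction_aa_length": len(junction_aa) if junction_aa is not None else None,
        "np1_length": len(np1),
        "np2_length": len(np2) if np2 is not None else None,
    })
    values["consensus_count"] = values["duplicate_count"] + int(
        rng.poisson(model.consensus_extra_mean))

    v_score, v_ident, v_support = identity(v_q)
    values.update({
        "v_score": v_score, "v_identity": v_ident, "v_support": v_support,
        "v_cigar": gene_cigar(v_q),
        "v_sequence_start": v_q.start, "v_sequence_end": v_q.end,
        "v_germline_start": 1, "v_germline_end": len(v_part),
    })
    j_score, j_ident, j_support = identity(j_q)
    values.update({
        "j_score": j_score, "j_identity": j_ident, "j_support": j_support,
        "j_cigar": gene_cigar(j_q),
        "j_sequence_start": j_q.start, "j_sequence_end": j_q.end,
        "j_germline_start": j_5_trim + 1, "j_germline_end": len(j.sequence),
    })
    if d is not None and d_q is not None:
        d_score, d_ident, d_support = identity(d_q)
        values.update({
            "d_score": d_score, "d_identity": d_ident, "d_support": d_support,
            "d_cigar": gene_cigar(d_q),
            "d_sequence_start": d_q.start, "d_sequence_end": d_q.end,
            "d_germline_start": d_5_trim + 1,
            "d_germline_end": len(d.sequence) - d_3_trim,
        })

    # regions: V regions sit at identical query coordinates (V aligns from
    # position 1 with no indels); CDR3 is the junction minus both anchors;
    # FWR4 is everything after the junction.
    for region, iv in v.regions.items():
        values[region] = sequence[iv.start - 1: iv.end]
        values[f"{region}_start"] = iv.start
        values[f"{region}_end"] = iv.end
    if junction_end_q - junction_start_q + 1 > 6:
        values["cdr3_start"] = junction_start_q + 3
        values["cdr3_end"] = junction_end_q - 3
        values["cdr3"] = sequence[values["cdr3_start"] - 1: values["cdr3_end"]]
    if junction_end_q < n:
        values["fwr4_start"] = junction_end_q + 1
        values["fwr4_end"] = n
        values["fwr4"] = sequence[junction_end_q:]

    record = RearrangementRecord(values=values)
    return TruthRecord(
        record=record,
        v_name=v.name, d_name=d.name if d is not None else None, j_name=j.name,
        v_3_trim=v_3_trim, d_5_trim=d_5_trim, d_3_trim=d_3_trim, j_5_trim=j_5_trim,
        np1=np1, np2=np2, mutated_positions=mutated, premutation_sequence=pre,
    )


def simulate_truths(n: int, germline_set: GermlineSet | None = None,
                    model: RecombinationModel | None = None,
                    rng: np.random.Generator | None = None) -> list[TruthRecord]:
    """Convenience: n truth records from a fresh seeded generator."""
    if germline_set is None:
        germline_set = toy_germline_set()
    if model is None:
        model = RecombinationModel()
    if rng is None:
        rng = np.random.default_rng(model.seed)
    return [simulate_rearrangement(germline_set, model, rng,
                                   sequence_id=f"sim-{i:06d}") for i in range(n)]


def simulate_dataset(n: int, germline_set: GermlineSet | None = None,
                     model: RecombinationModel | None = None,
                     sink: str | Path = "simulated.tsv",
                     schema: RearrangementSchema | None = None,
                     write_truth: bool = True) -> tuple[Path, list[TruthRecord]]:
    """Write n simulated records as an AIRR TSV plus a truth sidecar.

    Deterministic under ``model.seed``: the same seed yields
    byte-identical output.  ``n=0`` produces a valid header-only file.
    The truth sidecar is YAML at ``<sink>.truth.yaml``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if schema is None:
        schema = default_schema()
    truths = simulate_truths(n, germline_set, model)
    sink = Path(sink)
    write_rearrangements([t.record for t in truths], sink, schema)
    if write_truth:
        with open(f"{sink}.truth.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump({"records": [t.truth_dict() for t in truths]}, fh,
                           sort_keys=False)
    return sink, truths


# ---------------------------------------------------------------------------
# targeted corruption fixtures
# ---------------------------------------------------------------------------

CORRUPTIBLE_RULES = ("TYPE", "INTERVAL", "JUNC_LEN", "JUNC_AA", "CIGAR_SPAN",
                     "REGION_BOUNDS", "ALN_LEN")
#: corruptions whose records still render to TSV (TYPE plants a wrong-typed
#: in-memory value, which write_rearrangements rightly refuses)
FILE_SAFE_RULES = tuple(r for r in CORRUPTIBLE_RULES if r != "TYPE")


def corrupt_record(record: RearrangementRecord, rule_id: str,
                   rng: np.random.Generator) -> RearrangementRecord:
    """Minimally perturb exactly the fields governed by ``rule_id``.

    Returns a corrupted copy; the input record is untouched, so
    restoring is just keeping the original.  Perturbations are chosen
    so no *other* registered rule starts firing.
    """
    rec = record.copy()
    v = rec.values
    if rule_id == "TYPE":
        v["duplicate_count"] = "not-a-number"
    elif rule_id == "INTERVAL":
        if not (isinstance(v.get("cdr1_start"), int) and isinstance(v.get("cdr1_end"), int)):
            raise ValueError("record has no cdr1 interval to corrupt")
        v["cdr1_start"], v["cdr1_end"] = v["cdr1_end"], v["cdr1_start"]
    elif rule_id == "JUNC_LEN":
        if not isinstance(v.get("junction_length"), int):
            raise ValueError("record has no junction_length to corrupt")
        v["junction_length"] = v["junction_length"] + 1
    elif rule_id == "JUNC_AA":
        if isinstance(v.get("junction_aa"), str):
            v["junction_aa"] = v["junction_aa"] + "A"
        elif isinstance(v.get("junction"), str):
            v["junction_aa"] = "A" * (len(v["junction"]) // 3 + 1)
        else:
            raise ValueError("record has no junction to corrupt")
    elif rule_id == "CIGAR_SPAN":
        cigar = v.get("v_cigar")
        if not isinstance(cigar, str):
            raise ValueError("record has no v_cigar to corrupt")
        from .alignment_utils import CigarOp, cigar_to_string, parse_cigar
        ops = list(parse_cigar(cigar))
        m_idx = next(i for i, (op, _) in enumerate(ops) if op == "M")
        ops[m_idx] = CigarOp("M", ops[m_idx].length + 1)
        v["v_cigar"] = cigar_to_string(ops)
    elif rule_id == "REGION_BOUNDS":
        if not isinstance(v.get("sequence"), str):
            raise ValueError("record has no sequence to corrupt")
        target = "fwr4_end" if isinstance(v.get("fwr4_end"), int) else "fwr1_end"
        v[target] = len(v["sequence"]) + 5
        start_name = target.replace("_end", "_start")
        if not isinstance(v.get(start_name), int):
            v[start_name] = 1
    elif rule_id == "ALN_LEN":
        if not isinstance(v.get("germline_alignment"), str):
            raise ValueError("record has no germline_alignment to corrupt")
        v["germline_alignment"] = v["germline_alignment"] + "A"
    else:
        raise ValueError(f"unknown corruption rule {rule_id!r}")
    return rec
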