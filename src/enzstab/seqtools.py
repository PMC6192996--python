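"""Protein sequence utilities: global identity, alignment-column
conservation, and ProtParam-style physicochemical parameters.

Global alignment uses Needleman-Wunsch with BLOSUM62 and affine gaps
(open 10, extend 0.5) via Bio.Align.  Percent identity counts matches
over aligned columns excluding terminal-gap columns (overhangs from a
length difference do not dilute identity).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils.ProtParam import ProteinAnalysis

__all__ = [
    "SequenceRecord",
    "AlignmentSet",
    "ConservationReport",
    "global_align",
    "global_identity",
    "column_conservation",
    "molecular_weight",
    "extinction_coefficient_280",
    "read_fasta",
    "write_fasta",
]

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AA20 | {"X"}

WATER_MASS = 18.015


@dataclass(frozen=True)
class SequenceRecord:
    identifier: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence.upper()) - ALPHABET
        if bad:
            raise ValueError(f"invalid residue letters {sorted(bad)} in "
                             f"{self.identifier!r}")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentSet:
    """Aligned rows (equal length, '-' gaps) with a designated reference."""

    rows: list[tuple[str, str]]        # (identifier, aligned sequence)
    reference: str

    def __post_init__(self):
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        if self.reference not in {i for i, _ in self.rows}:
            raise ValueError(f"reference {self.reference!r} not among rows")

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    def row(self, identifier: str) -> str:
        for i, seq in self.rows:
            if i == identifier:
                return seq
        raise KeyError(identifier)


@dataclass
class ConservationReport:
    reference_position: int      # 1-based, ungapped in the reference
    column_index: int            # 0-based alignment column
    frequencies: dict[str, float]
    is_invariant: bool


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    al.mode = "global"
    return al


def global_align(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch global alignment; returns the two gapped rows."""
    aln = _aligner().align(a, b)[0]
    return str(aln[0]), str(aln[1])


def global_identity(a: SequenceRecord | str, b: SequenceRecord | str) -> float:
    """Percent identity from a global alignment.

    Denominator: aligned columns excluding terminal-gap columns.
    """
    sa = a.sequence if isinstance(a, SequenceRecord) else SequenceRecord("a", a).sequence
    sb = b.sequence if isinstance(b, SequenceRecord) else SequenceRecord("b", b).sequence
    row_a, row_b = global_align(sa, sb)

    def _core(row: str) -> tuple[int, int]:
        first = len(row) - len(row.lstrip("-"))
        last = len(row.rstrip("-")) - 1
        return first, last

    fa, la = _core(row_a)
    fb, lb = _core(row_b)
    start, end = max(fa, fb), min(la, lb)
    if end < start:
        return 0.0
    cols = end - start + 1
    matches = sum(1 for i in range(start, end + 1) if row_a[i] == row_b[i]
                  and row_a[i] != "-")
    return 100.0 * matches / cols


def column_conservation(aln: AlignmentSet, reference_position: int) -> ConservationReport:
    """Residue composition of the alignment column holding a reference
    position (1-based, counted over non-gap symbols of the reference)."""
    ref_row = aln.row(aln.reference)
    ungapped = 0
    column = -1
    for i, ch in enumerate(ref_row):
        if ch != "-":
            ungapped += 1
            if ungapped == reference_position:
                column = i
                break
    if column < 0:
        raise ValueError(f"reference position {reference_position} outside the "
                         f"reference sequence (length {ungapped})")
    symbols = [seq[column] for _, seq in aln.rows if seq[column] != "-"]
    total = len(symbols)
    freqs: dict[str, float] = {}
    for ch in symbols:
        freqs[ch] = freqs.get(ch, 0) + 1
    freqs = {ch: n / total for ch, n in sorted(freqs.items())}
    return ConservationReport(reference_position=reference_position,
                              column_index=column, frequencies=freqs,
                              is_invariant=len(freqs) == 1)


def molecular_weight(seq: SequenceRecord | str) -> float:
    """Average-isotopic molecular mass (Da) from amino-acid composition.

    Sum of average residue masses plus one water; 'X' residues have no
    defined mass and are rejected.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else SequenceRecord("q", seq).sequence
    if "X" in s:
        raise ValueError("sequence contains 'X': molecular mass undefined")
    return float(ProteinAnalysis(s).molecular_weight())


def extinction_coefficient_280(seq: SequenceRecord | str) -> dict[str, int]:
    """Molar extinction coefficient at 280 nm (Gill-von Hippel).

    eps = 5500*nTrp + 1490*nTyr (+ 125 per cystine).  Returns both the
    all-Cys-paired ("oxidized") and no-cystine ("reduced") variants.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else SequenceRecord("q", seq).sequence
    base = 5500 * s.count("W") + 1490 * s.count("Y")
    return {"reduced": base, "oxidized": base + 125 * (s.count("C") // 2)}


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    recs = [SequenceRecord(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise ValueError(f"no FASTA records in {path}")
    return recs


def read_alignment_fasta(path: str | Path, reference: str | None = None) -> AlignmentSet:
    rows = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not rows:
        raise ValueError(f"no FASTA records in {path}")
    return AlignmentSet(rows=rows, reference=reference or rows[0][0])


def write_fasta(records, path: str | Path) -> None:
    seq_records = []
    for r in records:
        if isinstance(r, SequenceRecord):
            seq_records.append(SeqRecord(Seq(r.sequence), id=r.identifier, description=""))
        else:
            ident, seq = r
            seq_records.append(SeqRecord(Seq(seq), id=ident, description=""))
    SeqIO.write(seq_records, str(path), "fasta")
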