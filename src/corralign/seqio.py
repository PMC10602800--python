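"""Sequence, MSA and alignment input/output in plain text formats."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrices import ALPHABET, UNKNOWN

GAP = "-"

# Non-standard residue mapping; anything else unexpected collapses to UNKNOWN.
_RESIDUE_MAP = {"B": "D", "Z": "E", "J": "L", "U": "C", "O": "K"}

_VALID = set(ALPHABET) | {UNKNOWN}


class SequenceError(ValueError):
    """Raised for malformed sequence or alignment input."""


def sanitize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase and map non-standard residues onto the 20-letter alphabet.

    B->D, Z->E, J->L, U->C, O->K; X and anything else alphabetic becomes the
    unknown symbol. Non-alphabetic characters are an error.
    """
    out = []
    for pos, ch in enumerate(raw.upper(), start=1):
        ch = _RESIDUE_MAP.get(ch, ch)
        if ch in _VALID:
            out.append(ch)
        elif ch.isalpha() or ch == "*":
            out.append(UNKNOWN)
        else:
            raise SequenceError(
                f"record {record_id}: invalid residue character {ch!r} at position {pos}"
            )
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus a sanitized residue string."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"record {self.id}: empty sequence")
        bad = set(self.residues) - _VALID
        if bad:
            raise SequenceError(f"record {self.id}: unsanitized residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class MSA:
    """Aligned records sharing one width; gap character '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != len(self.rows[0])]
            raise SequenceError(f"ragged MSA rows: {ragged}")
        if not self.rows:
            raise SequenceError("empty MSA")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)


# Alignment column operations: ("M", i, k), ("A", i, None) residue of A vs gap,
# ("B", None, k) residue of B vs gap. Indices are 0-based.
Op = tuple[str, int | None, int | None]


@dataclass
class AlignmentResult:
    """A global pairwise alignment as an ordered op list with its score."""

    ops: list[Op]
    score: float
    seq_ids: tuple[str, str]
    params: object | None = None
    meta: dict = field(default_factory=dict)

    def match_columns(self) -> list[tuple[int, int]]:
        return [(i, k) for kind, i, k in self.ops if kind == "M"]

    def validate(self, seq_a: ProteinSequence, seq_b: ProteinSequence) -> None:
        """Check the op list reconstructs both sequences exactly."""
        ia = ib = 0
        for kind, i, k in self.ops:
            if kind == "M":
                if i != ia or k != ib:
                    raise SequenceError(f"op {(kind, i, k)} out of order at ({ia},{ib})")
                ia += 1
                ib += 1
            elif kind == "A":
                if i != ia:
                    raise SequenceError(f"op {(kind, i, k)} out of order at ({ia},{ib})")
                ia += 1
            elif kind == "B":
                if k != ib:
                    raise SequenceError(f"op {(kind, i, k)} out of order at ({ia},{ib})")
                ib += 1
            else:
                raise SequenceError(f"unknown op kind {kind!r}")
        if ia != len(seq_a) or ib != len(seq_b):
            raise SequenceError(
                f"alignment covers {ia}/{len(seq_a)} of A and {ib}/{len(seq_b)} of B"
            )

    def gapped_strings(self, seq_a: ProteinSequence, seq_b: ProteinSequence) -> tuple[str, str]:
        self.validate(seq_a, seq_b)
        ga, gb = [], []
        for kind, i, k in self.ops:
            if kind == "M":
                ga.append(seq_a.residues[i])
                gb.append(seq_b.residues[k])
            elif kind == "A":
                ga.append(seq_a.residues[i])
                gb.append(GAP)
            else:
                ga.append(GAP)
                gb.append(seq_b.residues[k])
        return "".join(ga), "".join(gb)


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a FASTA file into sanitized sequences, order preserved."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no records")
    return [ProteinSequence(id=r.id, residues=sanitize_residues(str(r.seq), r.id)) for r in records]


def write_fasta(sequences: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n")
            for start in range(0, len(seq.residues), width):
                fh.write(seq.residues[start : start + width] + "\n")


def read_msa(path: str | Path, format: Literal["fasta", "stockholm"] = "fasta") -> MSA:
    """Read an aligned FASTA or Stockholm file. '.' gaps normalize to '-'."""
    try:
        aln = AlignIO.read(str(path), format)
    except ValueError as exc:
        # Biopython raises on ragged rows; surface the offending ids ourselves.
        records = list(SeqIO.parse(str(path), format)) if format == "fasta" else []
        widths = {len(r.seq) for r in records}
        if records and len(widths) > 1:
            w0 = len(records[0].seq)
            ragged = [r.id for r in records if len(r.seq) != w0]
            raise SequenceError(f"{path}: ragged rows {ragged}") from exc
        raise SequenceError(f"{path}: {exc}") from exc
    ids, rows = [], []
    for rec in aln:
        ids.append(rec.id)
        aligned = str(rec.seq).replace(".", GAP).upper()
        sanitized = []
        for ch in aligned:
            sanitized.append(ch if ch == GAP else sanitize_residues(ch, rec.id))
        rows.append("".join(sanitized))
    return MSA(ids=ids, rows=rows)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write an MSA as aligned FASTA."""
    records = [SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(msa.ids, msa.rows)]
    SeqIO.write(records, str(path), "fasta")


def _identity_line(ga: str, gb: str, m20=None) -> str:
    marks = []
    for a, b in zip(ga, gb):
        if a == GAP or b == GAP:
            marks.append(" ")
        elif a == b:
            marks.append("|")
        elif m20 is not None and m20.score(a, b) > 0:
            marks.append(":")
        else:
            marks.append(" ")
    return "".join(marks)


def write_alignment(
    result: AlignmentResult,
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    format: Literal["pair", "fasta"] = "pair",
    m20=None,
) -> str:
    """Render an alignment as gapped FASTA or an EMBOSS-needle-like pair report."""
    ga, gb = result.gapped_strings(seq_a, seq_b)
    if format == "fasta":
        return f">{seq_a.id}\n{ga}\n>{seq_b.id}\n{gb}\n"

    matches = result.match_columns()
    n_ident = sum(
        1 for i, k in matches if seq_a.residues[i] == seq_b.residues[k]
    )
    ncols = len(result.ops)
    lines = [
        "########################################",
        f"# A: {seq_a.id}",
        f"# B: {seq_b.id}",
        f"# Length: {ncols}",
        f"# Identity: {n_ident}/{ncols} ({100.0 * n_ident / ncols:.1f}%)",
        f"# Score: {result.score:.2f}",
        "########################################",
        "",
    ]
    marks = _identity_line(ga, gb, m20)
    pos_a = pos_b = 0
    for start in range(0, ncols, 50):
        ca, cb, cm = ga[start : start + 50], gb[start : start + 50], marks[start : start + 50]
        a_from = pos_a + 1
        b_from = pos_b + 1
        pos_a += sum(1 for ch in ca if ch != GAP)
        pos_b += sum(1 for ch in cb if ch != GAP)
        blk_a = " ".join(ca[i : i + 10] for i in range(0, len(ca), 10))
        blk_m = " ".join(cm[i : i + 10] for i in range(0, len(cm), 10))
        blk_b = " ".join(cb[i : i + 10] for i in range(0, len(cb), 10))
        lines.append(f"{seq_a.id[:13]:>13} {a_from:>5} {blk_a} {pos_a:>5}")
        lines.append(f"{'':>13} {'':>5} {blk_m}")
        lines.append(f"{seq_b.id[:13]:>13} {b_from:>5} {blk_b} {pos_b:>5}")
        lines.append("")
    return "\n".join(lines) + "\n"


def parse_alignment_fasta(text: str) -> tuple[list[Op], tuple[str, str]]:
    """Recover the op list from two gapped FASTA records (inverse of the writer)."""
    ids, seqs = [], []
    current: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            ids.append(line[1:].split()[0])
            if current or len(ids) > 1:
                seqs.append("".join(current))
                current = []
        elif line.strip():
            current.append(line.strip())
    seqs.append("".join(current))
    seqs = [s for s in seqs if s != ""] if len(seqs) > 2 else seqs
    if len(ids) != 2 or len(seqs) != 2:
        raise SequenceError("expected exactly two gapped records")
    ga, gb = seqs
    if len(ga) != len(gb):
        raise SequenceError("gapped records differ in length")
    ops: list[Op] = []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca != GAP and cb != GAP:
            ops.append(("M", ia, ib))
            ia += 1
            ib += 1
        elif ca != GAP:
            ops.append(("A", ia, None))
            ia += 1
        elif cb != GAP:
            ops.append(("B", None, ib))
            ib += 1
        else:
            raise SequenceError("double-gap column")
    return ops, (ids[0], ids[1])
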