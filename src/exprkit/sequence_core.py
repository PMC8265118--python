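"""Sequence alphabets, codon tables, translation and coordinates.

Every other module builds on the types defined here.  The coordinate
convention for regions around a start codon is the one used throughout
bacterial expression work: position +1 is the first nucleotide of the
start codon, position −1 the last nucleotide of the 5′UTR, and there is
no position 0.  Region bounds are inclusive on both ends in user space
and converted to half-open 0-based indices internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("exprkit")

DNA_ALPHABET = frozenset("ACGT")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Invalid sequence content or incompatible sequence operation."""


@dataclass(frozen=True)
class NucSeq:
    """A DNA sequence over {A,C,G,T}.

    RNA input (U) is normalised to T on construction; lowercase is
    accepted and upper-cased.  IUPAC ambiguity codes are rejected.
    """

    residues: str
    id: str = ""

    def __post_init__(self) -> None:
        seq = self.residues.upper().replace("U", "T")
        if not seq:
            raise SequenceError("empty nucleotide sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise SequenceError(
                f"invalid nucleotide characters {sorted(bad)} in sequence "
                f"{self.id or '<unnamed>'}"
            )
        object.__setattr__(self, "residues", seq)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, key) -> str:
        return self.residues[key]


@dataclass(frozen=True)
class ProtSeq:
    """A protein sequence over the 20 standard amino-acid letters.

    A single terminal ``*`` (stop) is permitted and retained; internal
    stops raise unless ``allow_internal_stop`` was requested by the
    caller (analysis-only use).
    """

    residues: str
    id: str = ""
    allow_internal_stop: bool = False

    def __post_init__(self) -> None:
        seq = self.residues.upper()
        if not seq:
            raise SequenceError("empty protein sequence")
        body, star = (seq[:-1], True) if seq.endswith("*") else (seq, False)
        bad = set(body) - PROTEIN_ALPHABET - ({"*"} if self.allow_internal_stop else set())
        if bad:
            if "*" in bad:
                raise SequenceError(
                    f"internal stop '*' in protein {self.id or '<unnamed>'}"
                )
            raise SequenceError(
                f"invalid amino-acid characters {sorted(bad)} in protein "
                f"{self.id or '<unnamed>'}"
            )
        object.__setattr__(self, "residues", body + ("*" if star else ""))

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def without_stop(self) -> "ProtSeq":
        if self.residues.endswith("*"):
            return ProtSeq(self.residues[:-1], self.id)
        return self


class CodonTable:
    """Codon→amino-acid map plus the inverse synonymous-codon map.

    Wraps Biopython's NCBI tables; the default is the standard genetic
    code (table 1).
    """

    def __init__(self, table_id: int = 1):
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.forward: dict[str, str] = dict(bio.forward_table)
        for stop in bio.stop_codons:
            self.forward[stop] = "*"
        if len(self.forward) != 64:
            raise SequenceError(f"codon table {table_id} does not cover all 64 codons")
        self.stop_codons = frozenset(bio.stop_codons)
        self.start_codons = frozenset(bio.start_codons)
        inverse: dict[str, set[str]] = {}
        for codon, aa in self.forward.items():
            inverse.setdefault(aa, set()).add(codon)
        self.inverse: dict[str, frozenset[str]] = {
            aa: frozenset(cs) for aa, cs in inverse.items()
        }

    def amino_acid(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        try:
            return self.forward[codon]
        except KeyError:
            raise SequenceError(f"invalid codon {codon!r}") from None


STANDARD_TABLE = CodonTable(1)


def translate(seq: NucSeq, table: CodonTable = STANDARD_TABLE,
              allow_internal_stop: bool = False) -> ProtSeq:
    """Translate a CDS; trailing stop renders as '*', internal stops error.

    Raises if the length is not a multiple of 3 or (by default) when a
    stop codon occurs before the final position; the error names the
    offending codon index (1-based).
    """
    n = len(seq)
    if n % 3 != 0:
        raise SequenceError(f"CDS length {n} not divisible by 3")
    aas = []
    n_codons = n // 3
    for i in range(n_codons):
        codon = seq.residues[3 * i:3 * i + 3]
        aa = table.amino_acid(codon)
        if aa == "*" and i < n_codons - 1 and not allow_internal_stop:
            raise SequenceError(
                f"internal stop codon {codon} at codon index {i + 1}"
            )
        aas.append(aa)
    return ProtSeq("".join(aas), seq.id, allow_internal_stop=allow_internal_stop)


def synonymous_codons(codon: str, table: CodonTable = STANDARD_TABLE) -> frozenset[str]:
    """All codons encoding the same residue as ``codon`` (itself included)."""
    codon = codon.upper().replace("U", "T")
    aa = table.amino_acid(codon)
    if aa == "*":
        raise SequenceError(f"{codon} is a stop codon; no synonymous set")
    return table.inverse[aa]


def reverse_complement(seq: NucSeq) -> NucSeq:
    return NucSeq(seq.residues.translate(_COMPLEMENT)[::-1], seq.id)


def count_nt_changes(a: NucSeq, b: NucSeq) -> int:
    """Hamming distance between equal-length sequences."""
    if len(a) != len(b):
        raise SequenceError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a.residues, b.residues))


@dataclass(frozen=True)
class Region:
    """Signed inclusive interval relative to the start codon.

    +1 is the first nucleotide of the start codon, −1 the last
    nucleotide of the 5′UTR; there is no position 0.  ``Region(-24, 24)``
    therefore spans 48 nucleotides.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start == 0 or self.end == 0:
            raise ValueError("region coordinates are 1-based signed; 0 is not a position")
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def __str__(self) -> str:
        return f"{self.start}:{self.end}"

    @property
    def length(self) -> int:
        """Number of nucleotide positions covered (no position 0)."""
        n = self.end - self.start + 1
        if self.start < 0 < self.end:
            n -= 1
        return n


def _signed_to_offset(pos: int) -> int:
    """Signed 1-based coordinate → 0-based offset from the start codon."""
    return pos - 1 if pos > 0 else pos


def region_to_indices(region: Region, utr_len: int, cds_len: int,
                      clip: bool = True) -> tuple[int, int]:
    """Map a signed region to a half-open 0-based interval on UTR+CDS.

    With ``clip=True`` (default) a region extending past the available
    sequence is clipped with a logged warning; with ``clip=False`` it is
    an error.  A region entirely outside the sequence always errors.
    """
    total = utr_len + cds_len
    lo = utr_len + _signed_to_offset(region.start)
    hi = utr_len + _signed_to_offset(region.end) + 1
    if hi <= 0 or lo >= total:
        raise SequenceError(
            f"region {region} entirely outside sequence (utr={utr_len}, cds={cds_len})"
        )
    if lo < 0 or hi > total:
        if not clip:
            raise SequenceError(
                f"region {region} exceeds sequence bounds (utr={utr_len}, cds={cds_len})"
            )
        clipped_lo, clipped_hi = max(lo, 0), min(hi, total)
        logger.warning(
            "region %s clipped to available sequence: [%d, %d) -> [%d, %d)",
            region, lo, hi, clipped_lo, clipped_hi,
        )
        lo, hi = clipped_lo, clipped_hi
    return lo, hi


# ---------------------------------------------------------------------------
# FASTA I/O (multi-record; wrapped at 60 columns on write)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: str = "auto") -> list[NucSeq] | list[ProtSeq]:
    """Read a FASTA file as NucSeq or ProtSeq records.

    ``kind`` is "nuc", "prot" or "auto"; auto-detection treats a record
    as nucleotide when its residues are all in {A,C,G,T,U}.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        s = str(rec.seq).upper()
        if kind == "nuc" or (kind == "auto" and set(s) <= DNA_ALPHABET | {"U"}):
            out.append(NucSeq(s, rec.id))
        else:
            out.append(ProtSeq(s, rec.id))
    return out


def write_fasta(seqs: Iterable[NucSeq | ProtSeq], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id or f"seq{i + 1}", description="")
        for i, s in enumerate(seqs)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
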