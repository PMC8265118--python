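"""Seeded synthetic-sequence generators for testing and calibration.

Every generator is deterministic given its seed, and each family
emulates one facet of real expression data:

* ``random_cds`` — a random protein back-translated with uniformly
  chosen synonymous codons, plus a random 5'UTR; the null model for
  initiation-region accessibility.
* ``structured_cds`` — as above, but the UTR 3' end is the reverse
  complement of the CDS start, planting a strong hairpin across the
  −24:24 initiation region (high opening energy by construction).
* ``sp_positive`` — proteins with a signal-peptide architecture:
  Met + charged n-region (1–5 aa, >= 1 K/R) + hydrophobic h-region
  (7–15 aa) + c-region ending in A-X-A, then a hydrophilic mature tail;
  the cleavage position is recorded.
* ``sp_negative`` — composition-matched shuffles of positives
  (Met kept first): same residues, no architecture.
* ``toxin_like`` / ``fungal_like`` — signal-peptide positives whose
  mature regions carry a cysteine-rich (toxin-like) or Ser/Thr-rich
  (fungal-like) signature.
* ``solubility_gradient`` — proteins whose composition interpolates
  between low- and high-weight residues, giving monotonically
  increasing SWI under the supplied weight configuration.

A single run seed is split into per-task child seeds through
``numpy.random.SeedSequence([seed, crc32(tag)])`` so that subsystems
remain independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequence_core import (NucSeq, ProtSeq, STANDARD_TABLE, CodonTable)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HYDROPHOBIC_SET = "AILVFM"
HYDROPHILIC_BIAS = "DEKNQRSTG"


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-task generator derived from the run seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(tag.encode())])
    )


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: kind, count, sizes and seed."""

    kind: str
    n: int = 10
    seed: int = 0
    protein_len: int = 30      # residues for CDS kinds (incl. Met)
    mature_len: int = 40       # mature-tail residues for SP kinds
    utr_len: int = 30          # 5'UTR length for CDS kinds
    strong_motif: bool = True  # SP positives end the c-region in A-X-A

    KINDS = ("random_cds", "structured_cds", "sp_positive", "sp_negative",
             "toxin_like", "fungal_like", "solubility_gradient")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.kind in ("random_cds", "structured_cds") and self.protein_len < 2:
            raise ValueError("protein_len must be >= 2 for CDS fixtures")
        if self.kind == "structured_cds" and self.utr_len < 16:
            raise ValueError("structured_cds needs utr_len >= 16 to host the hairpin")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(list(AA20), size=length - 1))


def _back_translate(rng: np.random.Generator, prot: str,
                    table: CodonTable = STANDARD_TABLE) -> str:
    codons = []
    for aa in prot:
        options = sorted(table.inverse[aa])
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _sp_architecture(rng: np.random.Generator, mature_len: int,
                     strong_motif: bool) -> tuple[str, int]:
    """A signal-peptide protein and its cleavage position (1-based)."""
    n_len = int(rng.integers(1, 6))
    n_region = list(rng.choice(list("KRKRNQS"), size=n_len))
    n_region[int(rng.integers(n_len))] = rng.choice(["K", "R"])
    h_len = int(rng.integers(7, 16))
    h_region = rng.choice(list(HYDROPHOBIC_SET), size=h_len)
    c_len = int(rng.integers(3, 7))
    c_region = list(rng.choice(list("SATG"), size=c_len))
    if strong_motif:
        x = rng.choice(list("SQTGN"))
        c_region[-3:] = ["A", x, "A"]
    mature = rng.choice(list(HYDROPHILIC_BIAS + AA20), size=mature_len)
    sp = "M" + "".join(n_region) + "".join(h_region) + "".join(c_region)
    return sp + "".join(mature), len(sp)


def generate_fixtures(spec: FixtureSpec) -> tuple[list, pd.DataFrame]:
    """Generate sequence records plus a consistent label table.

    Returns (records, labels): records are NucSeq (CDS kinds) or ProtSeq
    (protein kinds); the label table has one row per record (matching
    ids) with kind-specific columns (utr, cleavage_pos, label, ...).
    Byte-identical output for identical spec + seed.
    """
    rng = child_rng(spec.seed, spec.kind)
    records: list = []
    rows: list[dict] = []

    if spec.kind in ("random_cds", "structured_cds"):
        for i in range(spec.n):
            name = f"{spec.kind}_{i}"
            prot = _random_protein(rng, spec.protein_len)
            cds = _back_translate(rng, prot) + "TAA"
            if spec.kind == "structured_cds":
                stem = 12
                rc = str(NucSeq(cds[:stem]))
                rc = rc.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                loop = "AACA"
                prefix = _random_dna(rng, spec.utr_len - stem - len(loop))
                utr = prefix + rc + loop
            else:
                utr = _random_dna(rng, spec.utr_len)
            records.append(NucSeq(cds, name))
            rows.append({"id": name, "kind": spec.kind, "utr": utr})

    elif spec.kind in ("sp_positive", "toxin_like", "fungal_like"):
        for i in range(spec.n):
            name = f"{spec.kind}_{i}"
            seq, cp = _sp_architecture(rng, spec.mature_len, spec.strong_motif)
            if spec.kind == "toxin_like":
                # cysteine-rich mature region, the toxin knottin signature
                mature = list(seq[cp:])
                k = max(1, len(mature) // 5)
                for j in rng.choice(len(mature), size=k, replace=False):
                    mature[j] = "C"
                seq = seq[:cp] + "".join(mature)
            elif spec.kind == "fungal_like":
                # Ser/Thr-rich mature region (O-glycosylation-prone)
                mature = list(seq[cp:])
                k = max(1, len(mature) // 3)
                for j in rng.choice(len(mature), size=k, replace=False):
                    mature[j] = rng.choice(["S", "T"])
                seq = seq[:cp] + "".join(mature)
            records.append(ProtSeq(seq, name))
            rows.append({"id": name, "kind": spec.kind, "label": 1,
                         "cleavage_pos": cp})

    elif spec.kind == "sp_negative":
        for i in range(spec.n):
            name = f"{spec.kind}_{i}"
            seq, _ = _sp_architecture(rng, spec.mature_len, spec.strong_motif)
            body = list(seq[1:])
            rng.shuffle(body)
            records.append(ProtSeq("M" + "".join(body), name))
            rows.append({"id": name, "kind": spec.kind, "label": 0,
                         "cleavage_pos": None})

    elif spec.kind == "solubility_gradient":
        low, high = "FC", "EK"  # extreme residues under any solubility weighting
        length = max(spec.protein_len, 20)
        for i in range(spec.n):
            name = f"{spec.kind}_{i}"
            frac = i / max(spec.n - 1, 1)
            n_high = int(round(frac * length))
            res = [high[j % 2] for j in range(n_high)] + \
                  [low[j % 2] for j in range(length - n_high)]
            records.append(ProtSeq("".join(res), name))
            rows.append({"id": name, "kind": spec.kind, "frac_soluble": frac})

    labels = pd.DataFrame(rows)
    assert list(labels["id"]) == [r.id for r in records]
    return records, labels


def sp_training_set(n: int, seed: int, frac_positive: float = 0.5,
                    mature_len: int = 40, strong_motif: bool = True
                    ) -> list[tuple[ProtSeq, int, int | None]]:
    """Labelled (sequence, label, cleavage) triples for ensemble training."""
    n_pos = int(round(n * frac_positive))
    pos_records, pos_labels = generate_fixtures(FixtureSpec(
        "sp_positive", n=n_pos, seed=seed, mature_len=mature_len,
        strong_motif=strong_motif))
    neg_records, _ = generate_fixtures(FixtureSpec(
        "sp_negative", n=n - n_pos, seed=seed, mature_len=mature_len))
    out = [(r, 1, int(cp)) for r, cp in
           zip(pos_records, pos_labels["cleavage_pos"])]
    out += [(r, 0, None) for r in neg_records]
    return out
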