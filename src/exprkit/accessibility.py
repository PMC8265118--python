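"""Opening energy of an mRNA region from a secondary-structure ensemble.

The accessibility of a region is the free-energy cost of keeping every
base in it unpaired across the Boltzmann ensemble of nested secondary
structures:

    OE = -RT * ln( Z_constrained / Z_full )

where Z_full sums Boltzmann weights exp(-E/RT) over all nested
structures of the local context and Z_constrained restricts the sum to
structures that leave the region single-stranded.  Low opening energy
means high accessibility of the translation-initiation region and, in
expression hosts such as E. coli, higher expected protein output.

The energy model here is deliberately simple — a constant stabilisation
per base pair (GC, AU/AT, GU/GT wobble), no stacking terms — so that the
dynamic programme can be validated exactly against exhaustive structure
enumeration at small n.  Full nearest-neighbour thermodynamics can be
supplied through the external per-position unpaired-probability reader
(`load_external_openen`), which accepts the tabular output of local
folding tools.

Long contexts are truncated to a 210-nt window centred on the region of
interest before folding, so evaluation cost is independent of input
length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .sequence_core import NucSeq, Region, SequenceError, region_to_indices

GAS_CONSTANT = 1.98717e-3  # kcal/(mol*K)

#: window length for context truncation, matching the common local-folding
#: practice of a 210-nt folding window for initiation-region accessibility
CONTEXT_WINDOW = 210

_ENUM_LIMIT = 25  # exhaustive enumeration guard

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class EnergyModel:
    """Per-pair-type energies (kcal/mol) for the nested-structure ensemble.

    Defaults: GC −3.0, AU −2.0, GU −1.0 kcal/mol per pair; minimum
    hairpin loop of 3 unpaired bases; physiological temperature
    310.15 K giving RT ≈ 0.6163 kcal/mol.
    """

    pair_energy: dict = field(
        default_factory=lambda: {"GC": -3.0, "AU": -2.0, "GU": -1.0}
    )
    min_hairpin_loop: int = 3
    temperature_K: float = 310.15

    def __post_init__(self) -> None:
        if self.min_hairpin_loop < 3:
            raise ValueError("min_hairpin_loop must be >= 3")
        if any(e > 0 for e in self.pair_energy.values()):
            raise ValueError("pair energies must be <= 0 (stabilising)")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature_K

    def energy_matrix(self) -> np.ndarray:
        """4x4 matrix of pair energies (np.inf = pair not allowed), ACGT order."""
        m = np.full((4, 4), np.inf)
        gc, au, gu = (self.pair_energy["GC"], self.pair_energy["AU"],
                      self.pair_energy["GU"])
        m[_NT_INDEX["G"], _NT_INDEX["C"]] = m[_NT_INDEX["C"], _NT_INDEX["G"]] = gc
        m[_NT_INDEX["A"], _NT_INDEX["T"]] = m[_NT_INDEX["T"], _NT_INDEX["A"]] = au
        m[_NT_INDEX["G"], _NT_INDEX["T"]] = m[_NT_INDEX["T"], _NT_INDEX["G"]] = gu
        return m


DEFAULT_ENERGY_MODEL = EnergyModel()


@dataclass(frozen=True)
class OpeningEnergy:
    """Opening energy (kcal/mol) of a region within its folded context."""

    value: float
    region: Region
    context_len: int


def encode(seq: NucSeq | str) -> np.ndarray:
    s = seq.residues if isinstance(seq, NucSeq) else seq
    return np.fromiter((_NT_INDEX[c] for c in s), dtype=np.int8, count=len(s))


def can_pair(a: str, b: str, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> bool:
    """Whether nucleotides a, b form an allowed pair under the model."""
    m = model.energy_matrix()
    return math.isfinite(m[_NT_INDEX[a], _NT_INDEX[b]])


# ---------------------------------------------------------------------------
# Exhaustive enumeration (validation oracle; n <= 25)
# ---------------------------------------------------------------------------

def enumerate_structures(seq: NucSeq, model: EnergyModel = DEFAULT_ENERGY_MODEL
                         ) -> list[tuple[frozenset, float]]:
    """All nested secondary structures of a short sequence with energies.

    Returns every valid structure (sets of 0-based (i, j) pairs, i<j,
    non-crossing, hairpin loops >= the model minimum) including the
    empty structure at energy 0.  Exponential: guarded to n <= 25.
    """
    n = len(seq)
    if n > _ENUM_LIMIT:
        raise SequenceError(
            f"enumeration limited to {_ENUM_LIMIT} nt (got {n}); use partition_function"
        )
    emat = model.energy_matrix()
    idx = encode(seq)
    h = model.min_hairpin_loop

    def rec(i: int, j: int) -> list[tuple[frozenset, float]]:
        # all structures on the inclusive interval [i, j]
        if j - i < h + 1:
            return [(frozenset(), 0.0)]
        out = []
        # j unpaired
        out.extend(rec(i, j - 1))
        # j paired with k
        for k in range(i, j - h):
            e = emat[idx[k], idx[j]]
            if not math.isfinite(e):
                continue
            for left, el in rec(i, k - 1):
                for inner, ei in rec(k + 1, j - 1):
                    out.append((left | inner | {(k, j)}, el + ei + e))
        return out

    return rec(0, n - 1)


def count_structures(seq: NucSeq, model: EnergyModel = DEFAULT_ENERGY_MODEL) -> int:
    """Number of valid nested structures (independent recursion, no energies)."""
    n = len(seq)
    emat = model.energy_matrix()
    idx = encode(seq)
    h = model.min_hairpin_loop
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def c(i: int, j: int) -> int:
        if j - i < h + 1:
            return 1
        total = c(i, j - 1)
        for k in range(i, j - h):
            if math.isfinite(emat[idx[k], idx[j]]):
                total += c(i, k - 1) * c(k + 1, j - 1)
        return total

    return c(0, n - 1)


# ---------------------------------------------------------------------------
# O(n^3) partition function (log-domain interval DP)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _logz_dp(idx, logw, minloop, mask):  # pragma: no cover - compiled
    """log Z over nested structures of idx; masked positions stay unpaired.

    logw[a, b] = -E(a,b)/RT for allowed pairs, -inf otherwise.
    logZ[i, j] covers the inclusive interval [i, j]; empty interval -> 0.
    """
    n = idx.shape[0]
    logZ = np.zeros((n + 1, n + 1))  # logZ[i, j+1] for interval [i, j]
    for span in range(minloop + 1, n):
        for i in range(0, n - span):
            j = i + span
            acc = logZ[i, j]  # j unpaired: interval [i, j-1]
            for k in range(i, j - minloop):
                if mask[k] or mask[j]:
                    continue
                w = logw[idx[k], idx[j]]
                if w == -np.inf:
                    continue
                t = logZ[i, k] + logZ[k + 1, j] + w
                # online logaddexp
                if t > acc:
                    acc, t = t, acc
                acc = acc + np.log1p(np.exp(t - acc))
            logZ[i, j + 1] = acc
    return logZ[0, n]


def log_partition_function(seq: NucSeq, model: EnergyModel = DEFAULT_ENERGY_MODEL,
                           unpaired_mask=None) -> float:
    """ln Z over all nested structures (masked indices forced unpaired)."""
    n = len(seq)
    mask = np.zeros(n, dtype=np.bool_)
    if unpaired_mask is not None:
        for i in unpaired_mask:
            if not 0 <= i < n:
                raise SequenceError(f"mask index {i} out of range for length {n}")
            mask[i] = True
    emat = model.energy_matrix()
    logw = np.where(np.isfinite(emat), -emat / model.RT, -np.inf)
    return float(_logz_dp(encode(seq), logw, model.min_hairpin_loop, mask))


def partition_function(seq: NucSeq, model: EnergyModel = DEFAULT_ENERGY_MODEL,
                       unpaired_mask=None) -> float:
    """Z = sum over structures of exp(-E/RT); 1.0 when only the empty
    structure is possible.  May overflow to inf for long, structured
    sequences — use :func:`log_partition_function` there."""
    return math.exp(log_partition_function(seq, model, unpaired_mask))


# ---------------------------------------------------------------------------
# Opening energy
# ---------------------------------------------------------------------------

def _context_window(n: int, lo: int, hi: int, window: int) -> tuple[int, int]:
    """Start/end of a <=window-nt slice of [0, n) centred on [lo, hi)."""
    if n <= window:
        return 0, n
    centre = (lo + hi) / 2.0
    start = int(round(centre - window / 2.0))
    start = max(0, min(start, n - window))
    # never truncate the region itself
    start = min(start, lo)
    start = max(start, hi - window)
    return start, start + window


def opening_energy_from_indices(seq: NucSeq, lo: int, hi: int,
                                model: EnergyModel = DEFAULT_ENERGY_MODEL,
                                window: int = CONTEXT_WINDOW) -> float:
    """OE (kcal/mol) of the half-open index interval [lo, hi) of seq."""
    if not (0 <= lo < hi <= len(seq)):
        raise SequenceError(f"interval [{lo}, {hi}) outside sequence of length {len(seq)}")
    ws, we = _context_window(len(seq), lo, hi, window)
    sub = NucSeq(seq.residues[ws:we], seq.id)
    mask = range(lo - ws, hi - ws)
    lz_full = log_partition_function(sub, model)
    lz_con = log_partition_function(sub, model, unpaired_mask=mask)
    oe = model.RT * (lz_full - lz_con)
    return max(oe, 0.0)  # clip tiny negative rounding noise


def opening_energy(seq: NucSeq, region: Region,
                   model: EnergyModel = DEFAULT_ENERGY_MODEL,
                   utr_len: int | None = None,
                   window: int = CONTEXT_WINDOW) -> OpeningEnergy:
    """Opening energy of ``region`` within the UTR+CDS context ``seq``.

    ``utr_len`` gives the length of the 5′UTR prefix of ``seq`` (so that
    position +1 of the region lands on the first CDS base); it defaults
    to the upstream extent of the region itself.
    """
    if utr_len is None:
        utr_len = -region.start if region.start < 0 else 0
    lo, hi = region_to_indices(region, utr_len, len(seq) - utr_len)
    ws, we = _context_window(len(seq), lo, hi, window)
    value = opening_energy_from_indices(seq, lo, hi, model, window)
    return OpeningEnergy(value=value, region=region, context_len=we - ws)


# ---------------------------------------------------------------------------
# External backend hook: tabular unpaired-probability matrices
# ---------------------------------------------------------------------------

def load_external_openen(path: str | Path, region: Region, utr_len: int,
                         model: EnergyModel = DEFAULT_ENERGY_MODEL) -> OpeningEnergy:
    """Opening energy from an external per-position unpaired-probability table.

    Expected dialect (the "_openen"/"_unpaired" style written by local
    RNA-folding tools): comment lines start with '#'; each data row is
    whitespace-separated with the 1-based sequence position first,
    followed by the probability that the stretch of length u = 1, 2, ...
    ENDING at that position is entirely unpaired ('NA' where undefined).
    OE = -RT * ln(p) for the cell matching the region.
    """
    lo_signed = region.start
    length = region.length
    # 1-based end position on the UTR+CDS axis the table indexes
    end_offset = region.end - 1 if region.end > 0 else region.end
    end_pos = utr_len + end_offset + 1
    rows: dict[int, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                pos = int(fields[0])
            except ValueError:
                raise SequenceError(
                    f"{path}: malformed row at line {lineno}: {line[:40]!r}"
                ) from None
            rows[pos] = fields[1:]
    if end_pos not in rows:
        raise SequenceError(
            f"{path}: no row for position {end_pos} (region {region}, utr {utr_len})"
        )
    cells = rows[end_pos]
    if length > len(cells):
        raise SequenceError(
            f"{path}: row {end_pos} has no length-{length} cell (max u = {len(cells)})"
        )
    cell = cells[length - 1]
    if cell.upper() == "NA":
        raise SequenceError(f"{path}: cell for position {end_pos}, length {length} is NA")
    try:
        p = float(cell)
    except ValueError:
        raise SequenceError(
            f"{path}: non-numeric cell {cell!r} at position {end_pos}, length {length}"
        ) from None
    if not 0.0 < p <= 1.0:
        raise SequenceError(f"{path}: probability {p} outside (0, 1]")
    return OpeningEnergy(value=-model.RT * math.log(p), region=region,
                         context_len=0)
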