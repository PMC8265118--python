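"""Protein-solubility analysis on the solubility-weighted index (SWI).

SWI is the arithmetic mean of per-residue solubility weights over a
protein or region; a logistic curve maps SWI onto a probability of
solubility.  Alongside it this module computes GRAVY (mean
Kyte–Doolittle hydropathy), sliding-window flexibility profiles
(normalised B-factor scale), a boundary search that extends a region of
interest toward more soluble supersets, and comparison of common
solubility-enhancing fusion tags (TRX, MBP, SUMO, GST).

The bundled SWI weights and logistic coefficients are configuration
values with documented defaults; all weights live on [0, 1] with higher
meaning more solubility-promoting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import expit

from .sequence_core import ProtSeq, SequenceError, read_fasta

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: default per-residue solubility weights (re-derived defaults bundled as
#: configuration; higher = more solubility-promoting)
DEFAULT_SWI_WEIGHTS: dict[str, float] = {
    "A": 0.8356, "C": 0.5478, "D": 0.9083, "E": 0.9866, "F": 0.5821,
    "G": 0.7997, "H": 0.8947, "I": 0.6784, "K": 0.9267, "L": 0.6554,
    "M": 0.6296, "N": 0.8597, "P": 0.8263, "Q": 0.7894, "R": 0.7712,
    "S": 0.7440, "T": 0.8096, "V": 0.7455, "W": 0.6386, "Y": 0.6125,
}

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

#: normalised B-factor flexibility scale (Vihinen-style; 1.0 = average)
FLEXIBILITY_SCALE: dict[str, float] = {
    "A": 0.984, "C": 0.906, "D": 1.068, "E": 1.094, "F": 0.915, "G": 1.031,
    "H": 0.950, "I": 0.927, "K": 1.102, "L": 0.935, "M": 0.952, "N": 1.048,
    "P": 1.049, "Q": 1.037, "R": 1.008, "S": 1.046, "T": 0.997, "V": 0.931,
    "W": 0.904, "Y": 0.929,
}


@dataclass(frozen=True)
class ResidueScale:
    """A named 20-entry amino-acid → value map (hydropathy, flexibility...)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, aa: str) -> float:
        try:
            return self.values[aa]
        except KeyError:
            raise SequenceError(f"residue {aa!r} not in scale {self.name!r}") from None


GRAVY_SCALE = ResidueScale("kyte_doolittle", KYTE_DOOLITTLE)
FLEX_SCALE = ResidueScale("norm_bfactor", FLEXIBILITY_SCALE)


@dataclass(frozen=True)
class SolubilityModel:
    """SWI weights plus the logistic map from SWI to P(soluble).

    p_sol = logistic(a * SWI + b) with a > 0, so higher SWI means higher
    probability of solubility.  Defaults for (a, b) are re-derived from
    this package's synthetic solubility-gradient fixtures.
    """

    swi_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SWI_WEIGHTS)
    )
    logistic_a: float = 30.0
    logistic_b: float = -23.0

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.swi_weights)
        if missing:
            raise ValueError(f"SWI weights missing residues {sorted(missing)}")
        if self.logistic_a <= 0:
            raise ValueError("logistic_a must be > 0 (higher SWI -> more soluble)")


DEFAULT_SOLUBILITY_MODEL = SolubilityModel()


@dataclass(frozen=True)
class ProteinRegion:
    """Inclusive 1-based residue interval within a protein."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid protein region {self.start}:{self.end}")

    def __str__(self) -> str:
        return f"{self.start}:{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "ProteinRegion") -> bool:
        return self.start <= other.start and other.end <= self.end

    def slice(self, prot: ProtSeq) -> ProtSeq:
        if self.end > len(prot.without_stop()):
            raise SequenceError(f"region {self} outside protein of length {len(prot)}")
        return ProtSeq(prot.without_stop().residues[self.start - 1:self.end], prot.id)


@dataclass(frozen=True)
class RegionReport:
    region: ProteinRegion
    swi: float
    p_sol: float
    gravy: float
    mean_flexibility: float


def _residue_mean(seq: str, values: dict[str, float], what: str) -> float:
    total = 0.0
    for aa in seq:
        try:
            total += values[aa]
        except KeyError:
            raise SequenceError(f"residue {aa!r} has no {what} value") from None
    return total / len(seq)


def swi(prot: ProtSeq, model: SolubilityModel = DEFAULT_SOLUBILITY_MODEL) -> float:
    """Solubility-weighted index: mean per-residue solubility weight."""
    seq = prot.without_stop().residues
    if not seq:
        raise SequenceError("empty protein")
    return _residue_mean(seq, model.swi_weights, "SWI weight")


def p_sol(prot: ProtSeq, model: SolubilityModel = DEFAULT_SOLUBILITY_MODEL) -> float:
    """Probability of solubility: logistic(a * SWI + b)."""
    return p_sol_from_swi(swi(prot, model), model)


def p_sol_from_swi(swi_value: float,
                   model: SolubilityModel = DEFAULT_SOLUBILITY_MODEL) -> float:
    return float(expit(model.logistic_a * swi_value + model.logistic_b))


def gravy(prot: ProtSeq, scale: ResidueScale = GRAVY_SCALE) -> float:
    """Grand average of hydropathicity (mean Kyte-Doolittle by default)."""
    return _residue_mean(prot.without_stop().residues, scale.values, scale.name)


def flexibility_profile(prot: ProtSeq, scale: ResidueScale = FLEX_SCALE,
                        window: int = 9) -> np.ndarray:
    """Unweighted sliding-window mean of the flexibility scale.

    Returns L - window + 1 values; point k covers residues k..k+window-1
    (0-based).
    """
    seq = prot.without_stop().residues
    if len(seq) < window:
        raise SequenceError(
            f"protein of length {len(seq)} shorter than window {window}; "
            f"use a smaller window"
        )
    vals = np.array([scale[aa] for aa in seq])
    kernel = np.ones(window) / window
    return np.convolve(vals, kernel, mode="valid")


def region_report(prot: ProtSeq, region: ProteinRegion,
                  model: SolubilityModel = DEFAULT_SOLUBILITY_MODEL) -> RegionReport:
    sub = region.slice(prot)
    s = swi(sub, model)
    flex = (flexibility_profile(sub).mean() if len(sub) >= 9
            else _residue_mean(sub.residues, FLEXIBILITY_SCALE, "flexibility"))
    return RegionReport(region=region, swi=s, p_sol=p_sol_from_swi(s, model),
                        gravy=gravy(sub), mean_flexibility=float(flex))


# ---------------------------------------------------------------------------
# Region-extension search
# ---------------------------------------------------------------------------

#: exhaustive enumeration is used when the superset space is at most this
#: many candidates; annealing takes over on larger proteins
_EXHAUSTIVE_LIMIT = 20000

_BOUNDARY_MOVES = [(d, 0) for d in range(-5, 6) if d] + \
                  [(0, d) for d in range(-5, 6) if d]


def extend_region_search(prot: ProtSeq, region: ProteinRegion,
                         model: SolubilityModel = DEFAULT_SOLUBILITY_MODEL,
                         seed: int = 0, max_results: int = 10,
                         iterations: int = 3000, restarts: int = 4
                         ) -> list[RegionReport]:
    """Regions strictly containing ``region`` with strictly higher p_sol.

    Searches the space of boundary extensions (left boundary moved left,
    right boundary moved right).  Small spaces are enumerated exactly;
    larger ones are explored by seeded simulated annealing over ±1..±5
    boundary moves.  Results are sorted by p_sol descending; the empty
    list means no superset improves on the input region.
    """
    L = len(prot.without_stop())
    if region.end > L:
        raise SequenceError(f"region {region} outside protein of length {L}")
    base_p = region_report(prot, region, model).p_sol

    prefix = np.concatenate([[0.0], np.cumsum(
        [model.swi_weights[aa] for aa in prot.without_stop().residues])])

    def swi_of(l: int, r: int) -> float:  # 1-based inclusive
        return (prefix[r] - prefix[l - 1]) / (r - l + 1)

    def p_of(l: int, r: int) -> float:
        return p_sol_from_swi(swi_of(l, r), model)

    n_candidates = region.start * (L - region.end + 1) - 1
    found: dict[tuple[int, int], float] = {}

    if n_candidates <= _EXHAUSTIVE_LIMIT:
        for l in range(1, region.start + 1):
            for r in range(region.end, L + 1):
                if (l, r) != (region.start, region.end):
                    found[(l, r)] = p_of(l, r)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            l, r = region.start, region.end
            cur = p_of(l, r)
            temp = 0.05
            for _ in range(iterations):
                dl, dr = _BOUNDARY_MOVES[int(rng.integers(len(_BOUNDARY_MOVES)))]
                nl = min(max(1, l + dl), region.start)
                nr = max(min(L, r + dr), region.end)
                if (nl, nr) == (l, r):
                    continue
                cand = p_of(nl, nr)
                if (nl, nr) != (region.start, region.end):
                    found[(nl, nr)] = cand
                if cand >= cur or rng.random() < math.exp((cand - cur) / temp):
                    l, r, cur = nl, nr, cand
                temp *= 0.999

    improved = [(l, r) for (l, r), p in found.items() if p > base_p]
    improved.sort(key=lambda lr: (-found[lr], lr[1] - lr[0], lr[0]))
    return [region_report(prot, ProteinRegion(l, r), model)
            for l, r in improved[:max_results]]


# ---------------------------------------------------------------------------
# Fusion tags
# ---------------------------------------------------------------------------

def load_tag_library(path: str | Path | None = None) -> dict[str, ProtSeq]:
    """Bundled (synthetic stand-in) or user-supplied fusion-tag sequences."""
    if path is None:
        ref = resources.files("exprkit").joinpath("data/tags_synthetic.fasta")
        with resources.as_file(ref) as p:
            seqs = read_fasta(p, kind="prot")
    else:
        seqs = read_fasta(path, kind="prot")
    return {s.id: s for s in seqs}


def compare_tags(prot_region: ProtSeq, tags: dict[str, ProtSeq] | None = None,
                 model: SolubilityModel = DEFAULT_SOLUBILITY_MODEL,
                 extra_fusions: dict[str, ProtSeq] | None = None
                 ) -> dict[str, float]:
    """P(soluble) of each tag + region fusion, plus the untagged baseline."""
    if tags is None:
        tags = load_tag_library()
    seq = prot_region.without_stop()
    out = {"untagged": p_sol(seq, model)}
    for name, tag in tags.items():
        fusion = ProtSeq(tag.without_stop().residues + seq.residues, name)
        out[name] = p_sol(fusion, model)
    for name, fusion in (extra_fusions or {}).items():
        out[name] = p_sol(fusion.without_stop(), model)
    return out


# ---------------------------------------------------------------------------
# Precomputed domain annotations
# ---------------------------------------------------------------------------

def load_domain_table(path: str | Path, protein_length: int | None = None
                      ) -> list[tuple[str, int, int, str]]:
    """Read a precomputed domain-annotation table.

    Whitespace-separated rows: name, start, end (1-based inclusive),
    optional free-text description.  Overlapping domains are allowed;
    coordinates outside the protein (when its length is given) error.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(None, 3)
            if len(fields) < 3:
                raise SequenceError(f"{path}: line {lineno}: expected name start end")
            name, s, e = fields[0], fields[1], fields[2]
            desc = fields[3] if len(fields) > 3 else ""
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise SequenceError(
                    f"{path}: line {lineno}: non-integer coordinates {s!r} {e!r}"
                ) from None
            if end < start or start < 1:
                raise SequenceError(
                    f"{path}: line {lineno}: invalid interval {start}..{end}"
                )
            if protein_length is not None and end > protein_length:
                raise SequenceError(
                    f"{path}: line {lineno}: domain {name} ends at {end}, beyond "
                    f"protein length {protein_length}"
                )
            out.append((name, start, end, desc))
    return out
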