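"""Synonymous-codon optimisation of translation-initiation accessibility.

Protein output in heterologous expression correlates with how easily
ribosomes can access the translation-initiation region of the mRNA.
This module searches the synonymous-codon space of a CDS by simulated
annealing, moving the opening energy of a host-specific region around
the start codon toward a target expression score, while rejecting any
candidate that introduces a forbidden restriction site (AarI, BsaI and
BsmBI by default) on either strand.  Accepted candidates are screened
for rho-independent-terminator-like elements and ranked.

The expression score maps opening energy onto a 0–100 scale through a
logistic curve, 100·logistic(β0 + β1·OE) with β1 < 0, calibrated for
the E. coli T7 lac promoter system.  The bundled coefficients are
re-derived from this package's synthetic expression fixtures and are
configuration, not a published fit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .accessibility import (DEFAULT_ENERGY_MODEL, EnergyModel,
                            opening_energy_from_indices)
from .sequence_core import (NucSeq, Region, SequenceError, STANDARD_TABLE,
                            CodonTable, count_nt_changes, region_to_indices,
                            reverse_complement, synonymous_codons, translate)

logger = logging.getLogger("exprkit")

#: host-specific initiation regions (signed, relative to the start codon)
HOST_REGIONS: dict[str, Region] = {
    "e_coli": Region(-24, 24),
    "s_cerevisiae": Region(-7, 89),
    "m_musculus": Region(-8, 11),
    "other": Region(-24, 89),
}

#: recognition sites of the Golden-Gate-era type IIS enzymes screened by
#: default (sourced from standard restriction-enzyme references)
DEFAULT_FORBIDDEN_MOTIFS: dict[str, str] = {
    "AarI": "CACCTGC",
    "BsaI": "GGTCTC",
    "BsmBI": "CGTCTC",
}

#: T7-promoter-derived leader used as the default 5'UTR (the pET-vector
#: lac-operator leader commonly paired with the T7 lac system); 71 nt
DEFAULT_UTR = NucSeq(
    "GGGGAATTGTGAGCGGATAACAATTCCCCTCTAGAAATAATTTTGTTTAACTTTAAGAAGGAGATATACAT",
    "T7_leader",
)

# (iterations per restart, number of restarts)
SAMPLING_MODES = {"quick": (1000, 1), "deep": (5000, 8)}


@dataclass(frozen=True)
class ExpressionScoreModel:
    """Logistic map from opening energy (kcal/mol) to a 0-100 score.

    score = 100 * logistic(beta0 + beta1 * OE), beta1 < 0 so lower
    opening energy (more accessible) scores higher.  Defaults are
    re-derived from synthetic success/failure opening-energy
    distributions generated by the fixtures module; they are
    configuration values, not the published regression.
    """

    beta0: float = 35.4593
    beta1: float = -0.7277

    def __post_init__(self) -> None:
        if self.beta1 >= 0:
            raise ValueError("beta1 must be negative (lower OE -> higher score)")

    def score(self, oe: float) -> float:
        return 100.0 * float(expit(self.beta0 + self.beta1 * oe))

    @property
    def midpoint_oe(self) -> float:
        """Opening energy at which the score is exactly 50."""
        return -self.beta0 / self.beta1


DEFAULT_SCORE_MODEL = ExpressionScoreModel()


def host_default_region(host: str) -> Region:
    try:
        return HOST_REGIONS[host]
    except KeyError:
        raise ValueError(
            f"unknown host {host!r}; expected one of {sorted(HOST_REGIONS)}"
        ) from None


def expression_score(oe: float, model: ExpressionScoreModel = DEFAULT_SCORE_MODEL
                     ) -> float:
    """0-100 expression score for an opening energy (kcal/mol)."""
    if not math.isfinite(oe):
        raise ValueError("opening energy must be finite")
    return model.score(oe)


# ---------------------------------------------------------------------------
# Motif and terminator screening
# ---------------------------------------------------------------------------

def find_forbidden_motifs(seq: NucSeq, motifs: dict[str, str] | None = None
                          ) -> list[tuple[str, str, int]]:
    """All occurrences of the motifs on either strand.

    Returns (motif_name, strand, position) triples with positions
    0-based on the forward strand; a '-' hit at position p means the
    reverse complement of the motif occurs at forward position p.
    """
    if motifs is None:
        motifs = DEFAULT_FORBIDDEN_MOTIFS
    hits = []
    s = seq.residues
    for name, motif in motifs.items():
        if not motif:
            raise ValueError(f"empty motif for {name!r}")
        fwd = NucSeq(motif).residues
        rev = reverse_complement(NucSeq(fwd)).residues
        start = s.find(fwd)
        while start != -1:
            hits.append((name, "+", start))
            start = s.find(fwd, start + 1)
        if rev != fwd:  # palindromes reported once
            start = s.find(rev)
            while start != -1:
                hits.append((name, "-", start))
                start = s.find(rev, start + 1)
    return sorted(hits, key=lambda h: (h[2], h[0], h[1]))


@dataclass(frozen=True)
class TerminatorHit:
    hairpin_start: int
    hairpin_end: int  # exclusive; end of the right stem arm
    stem_len: int
    u_tract_start: int


def detect_terminator(seq: NucSeq, min_stem: int = 6, min_loop: int = 3,
                      max_loop: int = 10,
                      external_hits: list[TerminatorHit] | None = None
                      ) -> list[TerminatorHit]:
    """Screen for rho-independent-terminator-like elements.

    Heuristic: a perfect hairpin stem of >= ``min_stem`` pairs (GC/AT/GT
    allowed) with a loop of ``min_loop``..``max_loop`` nt, immediately
    followed by a 6-nt window containing >= 5 T — the hairpin + U-tract
    architecture of intrinsic terminators.  When a table of externally
    computed hits is supplied (e.g. from a covariance-model search) it
    is returned verbatim and the heuristic is skipped.
    """
    if external_hits is not None:
        return list(external_hits)
    pairs = {"GC", "CG", "AT", "TA", "GT", "TG"}
    s = seq.residues
    n = len(s)
    candidates: list[TerminatorHit] = []
    for a in range(1, n):  # a = first loop position
        for loop in range(min_loop, max_loop + 1):
            max_stem = (54 - loop) // 2  # keep hairpin within a 60-nt window
            stem = 0
            while (stem < max_stem and a - 1 - stem >= 0 and a + loop + stem < n
                   and s[a - 1 - stem] + s[a + loop + stem] in pairs):
                stem += 1
            if stem < min_stem:
                continue
            end = a + loop + stem
            tract = s[end:end + 6]
            if len(tract) == 6 and tract.count("T") >= 5:
                candidates.append(TerminatorHit(a - stem, end, stem, end))
    # keep one hit per locus: earliest start, longest stem, skip overlaps
    candidates.sort(key=lambda h: (h.hairpin_start, -h.stem_len))
    hits: list[TerminatorHit] = []
    claimed_until = -1
    for h in candidates:
        if h.hairpin_start > claimed_until:
            hits.append(h)
            claimed_until = h.hairpin_end
    return hits


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OptimizationConfig:
    """Settings for an optimisation run."""

    host: str = "e_coli"
    promoter: str = "T7 lac"
    target_score: float | str = "maximise"  # 0-100, "maximise" or "minimise"
    region_override: Region | None = None
    scope: str = "initiation_region"  # or "full_cds"
    forbidden_motifs: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FORBIDDEN_MOTIFS)
    )
    extra_motifs: dict[str, str] = field(default_factory=dict)
    replace_default_motifs: bool = False
    terminator_check: bool = True
    seed: int = 0
    mode: str = "quick"
    utr: NucSeq = DEFAULT_UTR
    max_results: int = 10

    def __post_init__(self) -> None:
        if isinstance(self.target_score, (int, float)):
            if not 0 <= self.target_score <= 100:
                raise ValueError("numeric target_score must be in [0, 100]")
        elif self.target_score not in ("maximise", "minimise"):
            raise ValueError("target_score must be numeric, 'maximise' or 'minimise'")
        if self.mode not in SAMPLING_MODES:
            raise ValueError(f"mode must be one of {sorted(SAMPLING_MODES)}")
        if self.scope not in ("initiation_region", "full_cds"):
            raise ValueError("scope must be 'initiation_region' or 'full_cds'")

    @property
    def motifs(self) -> dict[str, str]:
        if self.replace_default_motifs:
            return dict(self.extra_motifs)
        return {**self.forbidden_motifs, **self.extra_motifs}

    @property
    def is_default_system(self) -> bool:
        """E. coli + a T7 promoter: the system the 0-100 score applies to."""
        return self.host == "e_coli" and "T7" in self.promoter


@dataclass(frozen=True)
class OptimizationResult:
    sequence: NucSeq  # optimised CDS
    oe_before: float
    oe_after: float
    score_before: float | None
    score_after: float | None
    n_changes: int
    motif_hits: list
    terminator_hits: list


def _objective(oe: float, config: OptimizationConfig,
               score_model: ExpressionScoreModel) -> float:
    """Quantity minimised by the annealer."""
    if config.target_score == "maximise":
        return oe  # maximise score == minimise opening energy
    if config.target_score == "minimise":
        return -oe
    return abs(expression_score(oe, score_model) - float(config.target_score))


def _mutable_codons(cds: NucSeq, utr_len: int, lo: int, hi: int, scope: str,
                    table: CodonTable) -> list[tuple[int, tuple[str, ...]]]:
    """Codon indices with >1 synonymous option inside the optimisation scope."""
    out = []
    n_codons = len(cds) // 3
    for ci in range(n_codons):
        codon = cds.residues[3 * ci:3 * ci + 3]
        if codon in table.stop_codons:
            continue
        if scope == "initiation_region":
            c_lo, c_hi = utr_len + 3 * ci, utr_len + 3 * ci + 3
            if c_hi <= lo or c_lo >= hi:
                continue
        syn = sorted(synonymous_codons(codon, table))
        if len(syn) > 1:
            out.append((ci, tuple(syn)))
    return out


def anneal(cds: NucSeq, config: OptimizationConfig = OptimizationConfig(),
           model: EnergyModel = DEFAULT_ENERGY_MODEL,
           score_model: ExpressionScoreModel = DEFAULT_SCORE_MODEL,
           table: CodonTable = STANDARD_TABLE) -> list[OptimizationResult]:
    """Optimise a CDS by simulated annealing over synonymous codons.

    Returns ranked, deduplicated solutions; every returned sequence
    translates identically to the input and is free of the configured
    forbidden motifs on both strands.  Deterministic for a fixed
    (input, config, seed).
    """
    translate(cds, table)  # validates the CDS (length, internal stops)
    utr = config.utr
    region = config.region_override or host_default_region(config.host)
    lo, hi = region_to_indices(region, len(utr), len(cds))
    motifs = config.motifs

    def full_seq(cds_str: str) -> NucSeq:
        return NucSeq(utr.residues + cds_str, cds.id)

    def oe_of(cds_str: str) -> float:
        return opening_energy_from_indices(full_seq(cds_str), lo, hi, model)

    oe_before = oe_of(cds.residues)
    score_before = (expression_score(oe_before, score_model)
                    if config.is_default_system else None)

    mutable = _mutable_codons(cds, len(utr), lo, hi, config.scope, table)
    input_result = OptimizationResult(
        sequence=cds, oe_before=oe_before, oe_after=oe_before,
        score_before=score_before, score_after=score_before,
        n_changes=0, motif_hits=find_forbidden_motifs(full_seq(cds.residues), motifs),
        terminator_hits=(detect_terminator(full_seq(cds.residues))
                         if config.terminator_check else []),
    )
    if not mutable:
        logger.warning(
            "no synonymous degrees of freedom in scope for %s; returning input",
            cds.id or "<unnamed>",
        )
        return [input_result]

    iters, restarts = SAMPLING_MODES[config.mode]
    rng = np.random.default_rng(config.seed)
    codon_starts = [3 * ci for ci, _ in mutable]
    options = [syn for _, syn in mutable]

    base = list(cds.residues)

    def assemble(state: tuple[str, ...]) -> str:
        out = base[:]
        for pos, codon in zip(codon_starts, state):
            out[pos:pos + 3] = codon
        return "".join(out)

    oe_cache: dict[tuple[str, ...], float] = {}

    def evaluate(state: tuple[str, ...]) -> float | None:
        """Objective of a state; None when it violates the motif constraint."""
        if state in oe_cache:
            return _objective(oe_cache[state], config, score_model)
        if find_forbidden_motifs(full_seq(assemble(state)), motifs):
            return None
        oe = oe_of(assemble(state))
        oe_cache[state] = oe
        return _objective(oe, config, score_model)

    init_state = tuple(cds.residues[p:p + 3] for p in codon_starts)
    init_obj = evaluate(init_state)
    if init_obj is None:  # input itself carries a forbidden motif
        init_obj = _objective(oe_before, config, score_model)
        oe_cache[init_state] = oe_before

    def propose(state: tuple[str, ...]) -> tuple[str, ...]:
        k = int(rng.integers(len(mutable)))
        syn = options[k]
        new = syn[int(rng.integers(len(syn)))]
        while len(syn) > 1 and new == state[k]:
            new = syn[int(rng.integers(len(syn)))]
        lst = list(state)
        lst[k] = new
        return tuple(lst)

    # initial temperature: calibrate so ~50% of uphill moves accept
    deltas = []
    probe = init_state
    for _ in range(30):
        cand = propose(probe)
        obj = evaluate(cand)
        if obj is not None:
            deltas.append(abs(obj - init_obj))
    t0 = max(np.mean(deltas) / math.log(2.0), 1e-3) if deltas else 1.0

    cooling_every = max(1, iters // 100)
    for _ in range(restarts):
        state, obj = init_state, init_obj
        temp = t0
        for it in range(iters):
            cand = propose(state)
            cand_obj = evaluate(cand)
            if cand_obj is None:
                continue  # forbidden motif: reject outright
            delta = cand_obj - obj
            if delta <= 0 or rng.random() < math.exp(-delta / temp):
                state, obj = cand, cand_obj
            if (it + 1) % cooling_every == 0:
                temp *= 0.95

    # rebuild results from every feasible state visited
    results = []
    for state, oe in oe_cache.items():
        seq_str = assemble(state)
        out_seq = NucSeq(seq_str, cds.id)
        full = full_seq(seq_str)
        results.append(OptimizationResult(
            sequence=out_seq,
            oe_before=oe_before,
            oe_after=oe,
            score_before=score_before,
            score_after=(expression_score(oe, score_model)
                         if config.is_default_system else None),
            n_changes=count_nt_changes(cds, out_seq),
            motif_hits=find_forbidden_motifs(full, motifs),
            terminator_hits=[],
        ))
    results = [r for r in results if not r.motif_hits]
    if not results:
        # the motif lies outside the mutable codons (e.g. in the UTR):
        # no synonymous variant can clear it, so report the input as-is
        logger.warning(
            "no motif-free synonymous variant reachable for %s; forbidden "
            "site lies outside the optimisable codons", cds.id or "<unnamed>",
        )
        return [input_result]
    ranked = rank_results(results, config)[:config.max_results]
    if config.terminator_check:
        final = []
        for r in ranked:
            t_hits = detect_terminator(full_seq(r.sequence.residues))
            if t_hits:
                logger.warning(
                    "terminator-like element in optimised %s; consider "
                    "--scope full_cds", cds.id or "<unnamed>",
                )
            final.append(replace(r, terminator_hits=t_hits))
        ranked = final
    return ranked


def rank_results(results: list[OptimizationResult],
                 config: OptimizationConfig) -> list[OptimizationResult]:
    """Order solutions by the host-appropriate rule.

    Default system (E. coli, T7 promoter): closest expression score to
    the target first; ties broken by fewer nucleotide changes, then
    lexicographic sequence.  Other hosts/promoters: fewest nucleotide
    changes first among objective-improving results, same tie-breaks.
    """
    if not results:
        raise ValueError("no results to rank")

    if config.is_default_system:
        if config.target_score == "maximise":
            target = 100.0
        elif config.target_score == "minimise":
            target = 0.0
        else:
            target = float(config.target_score)
        return sorted(
            results,
            key=lambda r: (abs((r.score_after or 0.0) - target), r.n_changes,
                           r.sequence.residues),
        )

    sign = -1.0 if config.target_score == "minimise" else 1.0
    baseline = results[0].oe_before
    satisfying = [r for r in results if sign * r.oe_after <= sign * baseline]
    pool = satisfying or results
    return sorted(pool, key=lambda r: (r.n_changes, sign * r.oe_after,
                                       r.sequence.residues))
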