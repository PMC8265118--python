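"""Ensemble signal-peptide detection with cleavage-site annotation.

A secretory signal peptide (SP) is an N-terminal extension with a
three-part architecture: a short positively charged n-region, a
hydrophobic h-region and a polar c-region whose cleavage site typically
follows an A-X-A motif.  Detection here combines:

* five probabilistic sequence-level classifiers (random forests by
  default) over N-terminal physicochemical features — the S-scores;
* a position-specific log-odds weight matrix over the cleavage-site
  context (−15..+2), whose sliding scores feed five further classifiers
  producing per-position cleavage scores — the C-scores;
* per model, Y = sqrt(S · max C); the final score is the median of the
  five Y-scores, and the cleavage site is taken from the model whose
  max C-score is the median of the five maxima (ties: lowest model
  index).

Detected SPs are optionally passed through secondary five-model tiers
(toxin-origin and fungal-origin), each reporting a median score and a
star count — the number of models agreeing above the threshold.

The ensembles are trained locally (`train_ensemble`) on labelled
sequences; nothing here depends on externally shipped model weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .sequence_core import NucSeq, ProtSeq, SequenceError, translate
from .solubility import FLEXIBILITY_SCALE, KYTE_DOOLITTLE

FORMAT_VERSION = "1"

N_MODELS = 5
PAD = "X"  # neutral padding token for short sequences

HYDROPHOBIC = set("AILMFVWC")
POLAR = set("STNQGY")
POSITIVE = set("KRH")
NEGATIVE = set("DE")

#: cleavage-context window: 15 residues upstream (−15..−1) and 2 downstream
#: (+1..+2) of the scissile bond
WM_UPSTREAM = 15
WM_DOWNSTREAM = 2
WM_WIDTH = WM_UPSTREAM + WM_DOWNSTREAM

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: candidate cleavage positions considered (cleavage after residue p,
#: 1-based); spans the N-terminal window plus cleavage-site context
CANDIDATE_MIN = 6
CANDIDATE_MAX = 35

FEATURE_WINDOW = 30  # N-terminal residues examined for sequence-level features


def _nterm(prot: ProtSeq, n: int = FEATURE_WINDOW) -> str:
    seq = prot.without_stop().residues
    if len(seq) < n:
        return seq + PAD * (n - len(seq))
    return seq[:n]


def extract_features(prot: ProtSeq) -> np.ndarray:
    """Fixed-order physicochemical feature vector of the N-terminal 30.

    Features: fractions of hydrophobic / polar / positive / negative /
    proline residues; max sliding-7-mer mean hydropathy; net charge of
    the first 5 residues (K,R = +1, D,E = −1); longest hydrophobic run
    (scaled by 30); mean flexibility.  Sequences shorter than 30 are
    padded with a neutral token.
    """
    if not prot.residues:
        raise SequenceError("empty protein")
    s = _nterm(prot)
    n = len(s)
    comp = [
        sum(c in HYDROPHOBIC for c in s) / n,
        sum(c in POLAR for c in s) / n,
        sum(c in POSITIVE for c in s) / n,
        sum(c in NEGATIVE for c in s) / n,
        s.count("P") / n,
    ]
    hyd = np.array([KYTE_DOOLITTLE.get(c, 0.0) for c in s])
    win7 = np.convolve(hyd, np.ones(7) / 7, mode="valid")
    max_hyd7 = float(win7.max())
    charge5 = float(sum((c in "KR") - (c in "DE") for c in s[:5]))
    run = best = 0
    for c in s:
        run = run + 1 if c in HYDROPHOBIC else 0
        best = max(best, run)
    flex = float(np.mean([FLEXIBILITY_SCALE.get(c, 1.0) for c in s]))
    return np.array(comp + [max_hyd7, charge5, best / n, flex])


@dataclass
class WeightMatrix:
    """Position-specific log-odds over the −15..+2 cleavage context."""

    log_odds: np.ndarray  # (20, WM_WIDTH)
    background: np.ndarray  # (20,)

    def __post_init__(self) -> None:
        if self.log_odds.shape != (20, WM_WIDTH):
            raise ValueError(f"weight matrix must be 20x{WM_WIDTH}")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("weight matrix entries must be finite")

    def context(self, seq: str, p: int) -> str:
        """The −15..+2 residue context of cleavage after residue p (1-based)."""
        left = seq[max(0, p - WM_UPSTREAM):p]
        left = PAD * (WM_UPSTREAM - len(left)) + left
        right = seq[p:p + WM_DOWNSTREAM]
        right = right + PAD * (WM_DOWNSTREAM - len(right))
        return left + right

    def score(self, seq: str, p: int) -> float:
        """Summed log-odds of the context; padding contributes 0."""
        total = 0.0
        for col, aa in enumerate(self.context(seq, p)):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                total += self.log_odds[idx, col]
        return total

    @classmethod
    def from_sites(cls, seqs_and_sites: list[tuple[str, int]],
                   background_seqs: list[str]) -> "WeightMatrix":
        """Estimate log-odds from labelled cleavage sites (+1 pseudocounts)."""
        counts = np.ones((20, WM_WIDTH))  # +1 pseudocount
        dummy = cls(np.zeros((20, WM_WIDTH)), np.full(20, 0.05))
        for seq, p in seqs_and_sites:
            for col, aa in enumerate(dummy.context(seq, p)):
                idx = _AA_INDEX.get(aa)
                if idx is not None:
                    counts[idx, col] += 1
        freqs = counts / counts.sum(axis=0, keepdims=True)
        bg_counts = np.ones(20)
        for seq in background_seqs:
            for aa in seq:
                idx = _AA_INDEX.get(aa)
                if idx is not None:
                    bg_counts[idx] += 1
        bg = bg_counts / bg_counts.sum()
        return cls(np.log(freqs / bg[:, None]), bg)


def candidate_positions(length: int) -> np.ndarray:
    """Candidate cleavage positions for a protein of the given length."""
    hi = min(CANDIDATE_MAX, length - WM_DOWNSTREAM)
    if hi < CANDIDATE_MIN:
        raise SequenceError(
            f"protein of length {length} too short for cleavage scanning"
        )
    return np.arange(CANDIDATE_MIN, hi + 1)


def _cleavage_features(seq: str, p: int, wm: WeightMatrix) -> np.ndarray:
    """Per-candidate features: scaled PWM score, position, context composition."""
    ctx = wm.context(seq, p)
    n = len(ctx)
    comp = [
        sum(c in HYDROPHOBIC for c in ctx) / n,
        sum(c in POLAR for c in ctx) / n,
        sum(c in POSITIVE for c in ctx) / n,
        sum(c in NEGATIVE for c in ctx) / n,
    ]
    h_reg = seq[max(0, p - 13):max(0, p - 4)]
    h_frac = (sum(c in HYDROPHOBIC for c in h_reg) / len(h_reg)) if h_reg else 0.0
    return np.array([wm.score(seq, p) / WM_WIDTH, p / 30.0, h_frac] + comp)


@dataclass
class SPModelEnsemble:
    """Five sequence-level + five cleavage-site classifiers and the PWM."""

    s_models: list
    c_models: list
    weight_matrix: WeightMatrix
    theta: float = 0.5
    tier: str = "eukaryote"

    def __post_init__(self) -> None:
        if len(self.s_models) != N_MODELS or len(self.c_models) != N_MODELS:
            raise ValueError(f"ensemble requires exactly {N_MODELS} models per role")


@dataclass
class SPScoreSet:
    """Full score breakdown for one sequence."""

    s_scores: np.ndarray            # (5,)
    c_scores: np.ndarray            # (5, P) clipped to [0, 1]
    positions: np.ndarray           # (P,) candidate cleavage positions
    y_scores: np.ndarray            # (5,)
    final_score: float
    theta: float
    sp_detected: bool               # any model's Y >= theta
    cleavage_pos: int | None
    toxin_score: float | None = None
    fungal_score: float | None = None
    stars: dict = field(default_factory=dict)


def combine_scores(s_scores: np.ndarray, c_scores: np.ndarray
                   ) -> tuple[np.ndarray, float]:
    """Y-scores (geometric mean of S and max C per model) and their median."""
    s = np.asarray(s_scores, dtype=float)
    c = np.asarray(c_scores, dtype=float)
    if s.shape[0] != N_MODELS or c.shape[0] != N_MODELS:
        raise ValueError(f"expected {N_MODELS} models")
    y = np.sqrt(s * c.max(axis=1))
    return y, float(np.median(y))


def cleavage_site(scoreset: SPScoreSet) -> int:
    """Cleavage position from the model with the median max-C-score.

    The median of the five per-model maxima is attained by one of the
    models; ties go to the lowest model index, and within the chosen
    model's series the lowest-index argmax wins.
    """
    if scoreset.final_score < scoreset.theta:
        raise SequenceError("cleavage_site requires a detected signal peptide")
    maxima = scoreset.c_scores.max(axis=1)
    med = np.median(maxima)
    model_i = int(np.argmin(np.abs(maxima - med)))  # exact hit; lowest index on ties
    return int(scoreset.positions[int(np.argmax(scoreset.c_scores[model_i]))])


def secondary_tier(prot: ProtSeq, ensemble: SPModelEnsemble,
                   primary_fired: bool = True) -> tuple[float, int]:
    """Median probability and star count from a toxin/fungal tier."""
    if not primary_fired:
        raise SequenceError("secondary tier requires a primary SP detection")
    x = extract_features(prot).reshape(1, -1)
    probs = np.array([m.predict_proba(x)[0, 1] for m in ensemble.s_models])
    return float(np.median(probs)), int(np.sum(probs >= ensemble.theta))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_ensemble(labeled: list[tuple[ProtSeq, int, int | None]],
                   tier: str = "eukaryote", seed: int = 0,
                   n_estimators: int = 60, theta: float = 0.5
                   ) -> SPModelEnsemble:
    """Train the five-model ensemble on (sequence, label, cleavage) triples.

    Sequences are split into five seeded folds; model i trains on the
    four folds other than i, so the five models see overlapping but
    distinct data.  The weight matrix is the +1-pseudocount log-odds of
    residue frequencies at −15..+2 around the labelled cleavage sites
    against the background composition.  Deterministic for a fixed seed.
    """
    n_pos = sum(1 for _, y, _ in labeled if y == 1)
    n_neg = len(labeled) - n_pos
    if n_pos < 100 or n_neg < 100:
        raise ValueError(f"need >= 100 of each class (got {n_pos}+/{n_neg}-)")
    if max(n_pos, n_neg) > 50 * min(n_pos, n_neg):
        raise ValueError(f"class imbalance beyond 1:50 ({n_pos}+/{n_neg}-)")

    rng = np.random.default_rng(seed)
    seqs = [p.without_stop().residues for p, _, _ in labeled]
    labels = np.array([y for _, y, _ in labeled])

    wm = WeightMatrix.from_sites(
        [(s, cp) for s, (_, y, cp) in zip(seqs, labeled) if y == 1 and cp],
        [s[:FEATURE_WINDOW + 10] for s in seqs],
    )

    X = np.vstack([extract_features(p) for p, _, _ in labeled])

    # per-sequence cleavage-site training examples
    c_X, c_y, c_owner = [], [], []
    for si, (s, (_, y, cp)) in enumerate(zip(seqs, labeled)):
        cands = candidate_positions(len(s)) if len(s) >= CANDIDATE_MIN + WM_DOWNSTREAM else []
        if y == 1 and cp:
            c_X.append(_cleavage_features(s, cp, wm))
            c_y.append(1)
            c_owner.append(si)
            wrong = [p for p in cands if abs(p - cp) > 2]
            for p in rng.choice(wrong, size=min(3, len(wrong)), replace=False):
                c_X.append(_cleavage_features(s, int(p), wm))
                c_y.append(0)
                c_owner.append(si)
        elif len(cands):
            p = int(rng.choice(cands))
            c_X.append(_cleavage_features(s, p, wm))
            c_y.append(0)
            c_owner.append(si)
    c_X = np.vstack(c_X)
    c_y = np.array(c_y)
    c_owner = np.array(c_owner)

    folds = rng.permutation(len(labeled)) % N_MODELS
    child_seeds = rng.integers(0, 2**31 - 1, size=2 * N_MODELS)

    s_models, c_models = [], []
    for i in range(N_MODELS):
        keep = folds != i
        m = RandomForestClassifier(n_estimators=n_estimators,
                                   random_state=int(child_seeds[i]))
        m.fit(X[keep], labels[keep])
        s_models.append(m)
        ckeep = keep[c_owner]
        cm = RandomForestClassifier(n_estimators=n_estimators,
                                    random_state=int(child_seeds[N_MODELS + i]))
        cm.fit(c_X[ckeep], c_y[ckeep])
        c_models.append(cm)

    return SPModelEnsemble(s_models, c_models, wm, theta=theta, tier=tier)


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def c_score_series(prot: ProtSeq, ensemble: SPModelEnsemble
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(positions, 5xP matrix) of per-position cleavage scores in [0, 1]."""
    seq = prot.without_stop().residues
    pos = candidate_positions(len(seq))
    feats = np.vstack([_cleavage_features(seq, int(p), ensemble.weight_matrix)
                       for p in pos])
    series = np.vstack([m.predict_proba(feats)[:, 1] for m in ensemble.c_models])
    return pos, np.clip(series, 0.0, 1.0)


def predict(seq: ProtSeq | NucSeq,
            primary: SPModelEnsemble,
            toxin: SPModelEnsemble | None = None,
            fungal: SPModelEnsemble | None = None) -> SPScoreSet:
    """Score a sequence for a signal peptide; nucleotide input is translated.

    Toxin/fungal tiers are evaluated only when at least one primary
    model fires (Y >= theta).
    """
    prot = translate(seq) if isinstance(seq, NucSeq) else seq
    if len(prot.without_stop()) < 15:
        raise SequenceError("sequence too short for signal-peptide analysis (< 15 aa)")

    x = extract_features(prot).reshape(1, -1)
    s_scores = np.array([m.predict_proba(x)[0, 1] for m in primary.s_models])
    positions, c_scores = c_score_series(prot, primary)
    y_scores, final = combine_scores(s_scores, c_scores)

    detected = bool(np.any(y_scores >= primary.theta))
    stars = {"primary": int(np.sum(y_scores >= primary.theta))}
    result = SPScoreSet(
        s_scores=s_scores, c_scores=c_scores, positions=positions,
        y_scores=y_scores, final_score=final, theta=primary.theta,
        sp_detected=detected, cleavage_pos=None, stars=stars,
    )
    if final >= primary.theta:
        result.cleavage_pos = cleavage_site(result)
    if detected:
        if toxin is not None:
            result.toxin_score, s = secondary_tier(prot, toxin)
            stars["toxin"] = s
        if fungal is not None:
            result.fungal_score, s = secondary_tier(prot, fungal)
            stars["fungal"] = s
    return result


# ---------------------------------------------------------------------------
# Model persistence (versioned manifest + joblib payloads)
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: SPModelEnsemble, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "tier": ensemble.tier,
        "theta": ensemble.theta,
        "n_models": N_MODELS,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    joblib.dump(
        {
            "s_models": ensemble.s_models,
            "c_models": ensemble.c_models,
            "log_odds": ensemble.weight_matrix.log_odds,
            "background": ensemble.weight_matrix.background,
        },
        d / "models.joblib",
    )


def load_ensemble(directory: str | Path) -> SPModelEnsemble:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported model-bundle version {manifest.get('format_version')!r}"
        )
    payload = joblib.load(d / "models.joblib")
    wm = WeightMatrix(payload["log_odds"], payload["background"])
    return SPModelEnsemble(payload["s_models"], payload["c_models"], wm,
                           theta=manifest["theta"], tier=manifest["tier"])
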