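"""Scoring schemes and Karlin-Altschul statistics for local similarity search.

The screen's decisions rest on E-values ``E = K * m * n * exp(-lambda * S)``.
``lambda`` is the unique positive root of ``sum_ij p_i p_j exp(lambda*s_ij)=1``
and ``K`` is computed with the classical ungapped lattice formula
(convolution series for sigma, then ``K = delta*lambda*exp(-2*sigma) /
(H*(1-exp(-lambda*delta)))``).  Gapped alignments reuse the ungapped
parameters: a documented approximation that preserves E-value comparisons,
which is all the screen's thresholds require.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from math import gcd

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

DNA_LETTERS = "ACGTN"
PROTEIN_LETTERS = "ACDEFGHIKLMNPQRSTVWYX"

# Robinson & Robinson (1991) amino-acid background frequencies.
ROBINSON_FREQS = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}


class CalibrationError(ValueError):
    """Raised when Karlin-Altschul statistics are undefined for a scheme."""


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus (after calibration) lambda and K.

    ``kind`` is 'nucleotide' (match/mismatch scores) or 'protein'
    (named substitution matrix).  Gap costs follow the BLAST convention:
    a gap of length g costs ``gap_open + g * gap_extend``.
    """

    kind: str
    match: int = 2
    mismatch: int = -3
    matrix_name: str = "BLOSUM62"
    gap_open: int = 5
    gap_extend: int = 2
    lam: float | None = None
    K: float | None = None
    calibration_method: str | None = None

    def __post_init__(self):
        if self.kind not in {"nucleotide", "protein"}:
            raise ValueError(f"bad scheme kind {self.kind!r}")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")

    @property
    def letters(self) -> str:
        return DNA_LETTERS if self.kind == "nucleotide" else PROTEIN_LETTERS

    @property
    def calibrated(self) -> bool:
        return self.lam is not None and self.K is not None

    def matrix(self) -> np.ndarray:
        """Integer substitution matrix over :attr:`letters` (N/X = worst mismatch)."""
        if self.kind == "nucleotide":
            m = np.full((5, 5), self.mismatch, dtype=np.int32)
            np.fill_diagonal(m, self.match)
            m[4, :] = self.mismatch  # N matches nothing, including itself
            m[:, 4] = self.mismatch
            return m
        blosum = substitution_matrices.load(self.matrix_name)
        worst = int(min(blosum.values()))
        n = len(PROTEIN_LETTERS)
        m = np.full((n, n), worst, dtype=np.int32)
        for i, a in enumerate(PROTEIN_LETTERS[:-1]):
            for j, b in enumerate(PROTEIN_LETTERS[:-1]):
                m[i, j] = int(blosum[a][b])
        return m

    def background(self) -> np.ndarray:
        """Residue background frequencies over the canonical letters (no N/X)."""
        if self.kind == "nucleotide":
            return np.full(4, 0.25)
        return np.array([ROBINSON_FREQS[a] for a in PROTEIN_LETTERS[:-1]])

    def encode(self, seq: str) -> np.ndarray:
        lut = np.full(128, -1, dtype=np.int8)
        for i, ch in enumerate(self.letters):
            lut[ord(ch)] = i
        enc = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        if (enc < 0).any():
            bad = seq[int(np.argmax(enc < 0))]
            raise ValueError(f"character {bad!r} outside scheme alphabet")
        return enc.astype(np.int16)


def nucleotide_default() -> "ScoringScheme":
    return calibrate_scoring(ScoringScheme(kind="nucleotide", match=2, mismatch=-3,
                                           gap_open=5, gap_extend=2))


def protein_default() -> "ScoringScheme":
    return calibrate_scoring(ScoringScheme(kind="protein", matrix_name="BLOSUM62",
                                           gap_open=11, gap_extend=1))


def _score_distribution(scheme: ScoringScheme, background: np.ndarray):
    """Probability of each integer score under independent background residues."""
    mat = scheme.matrix()
    k = len(background)
    sub = mat[:k, :k]
    probs: dict[int, float] = {}
    outer = np.outer(background, background)
    for s, p in zip(sub.ravel(), outer.ravel()):
        probs[int(s)] = probs.get(int(s), 0.0) + float(p)
    scores = np.array(sorted(probs))
    p = np.array([probs[int(s)] for s in scores])
    return scores, p


def _karlin_k(scores: np.ndarray, p: np.ndarray, lam: float) -> float:
    """K by the ungapped lattice formula (convolution series for sigma)."""
    delta = 0
    for s in scores[p > 0]:
        delta = gcd(delta, int(abs(s)))
    delta = max(delta, 1)
    H = lam * float(np.sum(scores * p * np.exp(lam * scores)))
    low, high = int(scores.min()), int(scores.max())
    # dense single-step distribution over [low, high]
    base = np.zeros(high - low + 1)
    for s, q in zip(scores, p):
        base[int(s) - low] = q
    sigma = 0.0
    conv = None
    for k in range(1, 61):
        conv = base if conv is None else np.convolve(conv, base)
        offset = k * low  # conv[i] = P(S_k = offset + i)
        vals = offset + np.arange(conv.size)
        neg = vals < 0
        term = float(np.sum(conv[neg] * np.exp(lam * vals[neg])) + np.sum(conv[~neg]))
        sigma += term / k
        if term / k < 1e-8 and k > 10:
            break
    return delta * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * delta)))


def calibrate_scoring(scheme: ScoringScheme,
                      background: np.ndarray | None = None) -> ScoringScheme:
    """Attach lambda and K to a scheme; raises CalibrationError if E[score] >= 0."""
    bg = scheme.background() if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    scores, p = _score_distribution(scheme, bg)
    expected = float(np.sum(scores * p))
    if expected >= 0:
        raise CalibrationError(
            f"expected score {expected:.4f} >= 0: Karlin-Altschul statistics undefined"
        )

    def f(lam):
        return float(np.sum(p * np.exp(lam * scores))) - 1.0

    hi = 0.5
    while f(hi) <= 0:
        hi *= 2.0
        if hi > 1e4:
            raise CalibrationError("no positive root for lambda")
    lam = brentq(f, 1e-12, hi, xtol=1e-15, rtol=8.9e-16)
    # polish to the documented residual tolerance
    for _ in range(50):
        if abs(f(lam)) < 1e-10:
            break
        fp = float(np.sum(p * scores * np.exp(lam * scores)))
        lam -= f(lam) / fp
    K = _karlin_k(scores, p, lam)
    return replace(scheme, lam=lam, K=K,
                   calibration_method="karlin-altschul-1990-ungapped")
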