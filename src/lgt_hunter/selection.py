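"""Pairwise dN/dS estimation.

Two routes are provided: the Nei-Gojobori (1986) counting method with
Jukes-Cantor correction, and maximum likelihood under a Goldman-Yang-style
codon model (61 sense codons, universal code) with transition/transversion
ratio ``kappa``, nonsynonymous/synonymous ratio ``omega`` and F3x4
equilibrium codon frequencies built from the pair's positional nucleotide
frequencies.  The generator is scaled so branch length ``t`` is measured in
expected substitutions per codon; dN and dS are derived from ``t`` and the
model's synonymous/nonsynonymous flux proportions (the codeml convention,
so that the derived dN/dS equals ``omega``).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .datamodel import CODON_TABLE, SENSE_CODONS, STOP_CODONS, translate
from .scoring import ScoringScheme, protein_default

NUCS = "TCAG"
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_STATES = len(SENSE_CODONS)  # 61


def _is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


# single-nucleotide-difference structure of the 61-state space:
# for each ordered pair (i, j): position changed, transition?, synonymous?
_PAIRS_I, _PAIRS_J, _PAIRS_TS, _PAIRS_SYN = [], [], [], []
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [p for p in range(3) if _ci[p] != _cj[p]]
        if len(diffs) != 1:
            continue
        _p = diffs[0]
        _PAIRS_I.append(_i)
        _PAIRS_J.append(_j)
        _PAIRS_TS.append(_is_transition(_ci[_p], _cj[_p]))
        _PAIRS_SYN.append(CODON_TABLE[_ci] == CODON_TABLE[_cj])
_PAIRS_I = np.array(_PAIRS_I)
_PAIRS_J = np.array(_PAIRS_J)
_PAIRS_TS = np.array(_PAIRS_TS)
_PAIRS_SYN = np.array(_PAIRS_SYN)


@dataclass
class CodonAlignmentPair:
    """In-frame aligned codon columns for two CDS; gaps are '---' triplets."""

    id_a: str
    id_b: str
    columns: list[tuple[str, str]]

    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in self.columns if "-" not in a and "-" not in b]

    def positional_base_freqs(self) -> np.ndarray:
        """3x4 matrix of nucleotide frequencies per codon position (T,C,A,G),
        pooled over both sequences' non-gap codons."""
        counts = np.zeros((3, 4))
        for a, b in self.ungapped_columns():
            for codon in (a, b):
                for p, nt in enumerate(codon):
                    counts[p, NUCS.index(nt)] += 1
        # floor to keep F3x4 frequencies strictly positive
        counts = np.maximum(counts, 1e-4)
        return counts / counts.sum(axis=1, keepdims=True)


@dataclass
class DnDsResult:
    dN: float
    dS: float
    omega: float
    kappa: float
    t: float
    logL: float
    method: str
    n_codons: int = 0


def _validate_cds(cds: str, name: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    if cds[-3:] in STOP_CODONS:
        cds = cds[:-3]
    aa = translate(cds)
    if "*" in aa:
        raise ValueError(f"{name}: internal stop codon at codon {aa.index('*') + 1}")
    return cds


def build_codon_alignment(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b",
                          scheme: ScoringScheme | None = None) -> CodonAlignmentPair:
    """Protein-guided codon alignment: align the translations globally, then
    back-translate each aligned residue to its source codon."""
    from .homology import global_align_protein

    cds_a = _validate_cds(cds_a, id_a)
    cds_b = _validate_cds(cds_b, id_b)
    scheme = scheme or protein_default()
    aln_a, aln_b = global_align_protein(translate(cds_a), translate(cds_b), scheme)
    cols = []
    ia = ib = 0
    for ra, rb in zip(aln_a, aln_b):
        if ra != "-":
            ca = cds_a[3 * ia:3 * ia + 3]
            ia += 1
        else:
            ca = "---"
        if rb != "-":
            cb = cds_b[3 * ib:3 * ib + 3]
            ib += 1
        else:
            cb = "---"
        cols.append((ca, cb))
    return CodonAlignmentPair(id_a=id_a, id_b=id_b, columns=cols)


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------

def _syn_site_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (changes to stops count as
    nonsynonymous); in [0, 3]."""
    aa = CODON_TABLE[codon]
    syn = 0.0
    for p in range(3):
        for nt in NUCS:
            if nt == codon[p]:
                continue
            alt = codon[:p] + nt + codon[p + 1:]
            if CODON_TABLE[alt] == aa:  # stop codons translate to '*', never equal
                syn += 1.0
    return syn / 3.0


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average (syn, nonsyn) substitution counts over all minimal pathways
    between two codons; pathways through stop codons are discarded."""
    diffs = [p for p in range(3) if codon_a[p] != codon_b[p]]
    if not diffs:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diffs):
        cur = codon_a
        sd = nd = 0
        blocked = False
        for p in order:
            nxt = cur[:p] + codon_b[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            totals.append((sd, nd))
    if not totals:  # every pathway crosses a stop: count all steps nonsynonymous
        return 0.0, float(len(diffs))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p:.3f} >= 3/4: Jukes-Cantor correction undefined")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86(pair: CodonAlignmentPair) -> DnDsResult:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction."""
    cols = pair.ungapped_columns()
    if not cols:
        raise ValueError("no comparable (non-gap) codon columns")
    S = sum((_syn_site_fraction(a) + _syn_site_fraction(b)) / 2.0 for a, b in cols)
    N = 3.0 * len(cols) - S
    Sd = Nd = 0.0
    for a, b in cols:
        sd, nd = _pathway_counts(a, b)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    omega = dN / dS if dS > 0 else float("nan")
    return DnDsResult(dN=dN, dS=dS, omega=omega, kappa=float("nan"), t=float("nan"),
                      logL=float("nan"), method="NG86", n_codons=len(cols))


# ---------------------------------------------------------------------------
# GY94 maximum likelihood
# ---------------------------------------------------------------------------

def f3x4_codon_freqs(pos_freqs: np.ndarray) -> np.ndarray:
    """Sense-codon equilibrium frequencies from 3x4 positional nucleotide
    frequencies, renormalized after removing stop codons."""
    pi = np.empty(N_STATES)
    for i, codon in enumerate(SENSE_CODONS):
        pi[i] = (pos_freqs[0, NUCS.index(codon[0])]
                 * pos_freqs[1, NUCS.index(codon[1])]
                 * pos_freqs[2, NUCS.index(codon[2])])
    return pi / pi.sum()


def gy94_rate_matrix(pi: np.ndarray, kappa: float, omega: float) -> np.ndarray:
    """Scaled GY94 generator: single-nucleotide changes only, rate
    pi_j * kappa^[transition] * omega^[nonsynonymous]; scaled so the expected
    substitution rate at stationarity is 1 per codon."""
    Q = np.zeros((N_STATES, N_STATES))
    rates = np.where(_PAIRS_TS, kappa, 1.0) * np.where(_PAIRS_SYN, 1.0, omega)
    Q[_PAIRS_I, _PAIRS_J] = rates * pi[_PAIRS_J]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(pi, np.diag(Q)))
    return Q / mu


def flux_proportions(pi: np.ndarray, kappa: float, omega: float) -> tuple[float, float]:
    """(synonymous, nonsynonymous) shares of the substitution flux."""
    Q = gy94_rate_matrix(pi, kappa, omega)
    flux = pi[_PAIRS_I] * Q[_PAIRS_I, _PAIRS_J]
    syn = float(flux[_PAIRS_SYN].sum())
    total = float(flux.sum())
    return syn / total, 1.0 - syn / total


def _transition_probs(Q: np.ndarray, pi: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt) via eigendecomposition of the pi-symmetrized generator."""
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]  # D^1/2 Q D^-1/2, symmetric by reversibility
    B = 0.5 * (B + B.T)  # clean up round-off
    w, V = np.linalg.eigh(B)
    P = (V * np.exp(w * t)) @ V.T
    P = P / sq[:, None] * sq[None, :]
    return np.maximum(P, 1e-300)


def _pair_counts(pair: CodonAlignmentPair):
    counts: dict[tuple[int, int], int] = {}
    for a, b in pair.ungapped_columns():
        key = (CODON_INDEX[a], CODON_INDEX[b])
        counts[key] = counts.get(key, 0) + 1
    ij = np.array(list(counts), dtype=int)
    n = np.array(list(counts.values()), dtype=float)
    return ij[:, 0], ij[:, 1], n


def _log_likelihood(i_idx, j_idx, n, pi, kappa, omega, t) -> float:
    Q = gy94_rate_matrix(pi, kappa, omega)
    P = _transition_probs(Q, pi, t)
    return float(np.sum(n * np.log(pi[i_idx] * P[i_idx, j_idx])))


_ML_STARTS = [(0.5, 2.0, 0.5), (0.1, 1.0, 0.1), (1.5, 4.0, 1.0)]


def ml_pairwise_dnds(pair: CodonAlignmentPair) -> DnDsResult:
    """Maximum-likelihood (t, kappa, omega) under GY94/F3x4 for one pair."""
    cols = pair.ungapped_columns()
    if len(cols) < 10:
        raise ValueError(f"only {len(cols)} comparable codons; need >= 10")
    pi = f3x4_codon_freqs(pair.positional_base_freqs())
    i_idx, j_idx, n = _pair_counts(pair)
    n_diff = int(n[i_idx != j_idx].sum())
    if n_diff == 0:
        warnings.warn("identical sequences: t at the zero boundary", stacklevel=2)
        logL = float(np.sum(n * np.log(pi[i_idx])))
        return DnDsResult(dN=0.0, dS=0.0, omega=float("nan"), kappa=float("nan"),
                          t=0.0, logL=logL, method="ML", n_codons=len(cols))

    def neg_loglik(x):
        t, kappa, omega = np.exp(x)
        if t > 50 or kappa > 500 or omega > 500:
            return 1e12
        return -_log_likelihood(i_idx, j_idx, n, pi, kappa, omega, t)

    best = None
    for start in _ML_STARTS:
        res = minimize(neg_loglik, np.log(start), method="Nelder-Mead",
                       options={"fatol": 1e-8, "xatol": 1e-6, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"ML optimization failed to converge: {best}")
    t, kappa, omega = np.exp(best.x)
    rho_s, rho_n = flux_proportions(pi, kappa, omega)
    rho_s1, rho_n1 = flux_proportions(pi, kappa, 1.0)
    dS = t * rho_s / (3.0 * rho_s1)
    dN = t * rho_n / (3.0 * rho_n1)
    return DnDsResult(dN=float(dN), dS=float(dS), omega=float(omega),
                      kappa=float(kappa), t=float(t), logL=float(-best.fun),
                      method="ML", n_codons=len(cols))
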