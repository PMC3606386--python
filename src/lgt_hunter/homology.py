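"""Self-contained seed-and-extend local similarity search with E-values.

The engine follows the classical word-seeded design: exact word seeding
(DNA, both strands) or neighborhood word seeding (protein, word score
threshold), ungapped X-drop extension along the diagonal, then a banded
affine-gap local extension around promising HSPs.  E-values come from the
Karlin-Altschul formula with the ungapped parameters of the calibrated
:class:`~lgt_hunter.scoring.ScoringScheme` and raw ``m * n`` search space
(no effective-length correction; recorded in output metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datamodel import ProteinRecord, Scaffold, reverse_complement
from .scoring import ScoringScheme

LN2 = math.log(2.0)


@dataclass(frozen=True)
class Hsp:
    """A high-scoring segment pair; intervals 0-based half-open on + strands.

    For strand '-', the query interval refers to the forward query
    coordinates whose reverse complement aligns to the subject interval.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    raw_score: int
    bitscore: float
    evalue: float
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int


@dataclass
class SearchParams:
    """Knobs of the search; defaults mirror common megablast/blastp settings."""

    word_size: int | None = None          # 11 DNA, 3 protein when None
    x_drop: int = 0                       # raw-score drop-off (40 DNA, 20 protein when 0)
    evalue_cutoff: float = 10.0
    neighborhood_threshold: int = 11      # protein seed word score threshold
    band: int = 16                        # half-width of the gapped band
    gap_trigger_bits: float = 22.0        # ungapped bitscore needed to try gapped extension

    def resolved(self, kind: str) -> "SearchParams":
        p = SearchParams(**self.__dict__)
        if p.word_size is None:
            p.word_size = 11 if kind == "nucleotide" else 3
        if p.x_drop == 0:
            p.x_drop = 40 if kind == "nucleotide" else 20
        return p


def evalue_of(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul expectation E = K*m*n*exp(-lambda*S)."""
    if not scheme.calibrated:
        raise ValueError("scheme is not calibrated; run calibrate_scoring first")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def bitscore_of(score: int, scheme: ScoringScheme) -> float:
    if not scheme.calibrated:
        raise ValueError("scheme is not calibrated; run calibrate_scoring first")
    return (scheme.lam * score - math.log(scheme.K)) / LN2


def _ungapped_extend(q: np.ndarray, s: np.ndarray, qpos: int, spos: int,
                     w: int, mat: np.ndarray, x_drop: int):
    """Extend a seed of length w on its diagonal with X-drop; returns
    (q_start, q_end, score) in query coordinates (subject offset fixed)."""
    score = 0
    for k in range(w):
        score += mat[q[qpos + k], s[spos + k]]
    # right
    best, best_right = score, qpos + w
    i, j = qpos + w, spos + w
    cur = score
    while i < len(q) and j < len(s):
        cur += mat[q[i], s[j]]
        if cur > best:
            best, best_right = cur, i + 1
        if best - cur > x_drop:
            break
        i += 1
        j += 1
    # left
    score_l = best
    best, best_left = score_l, qpos
    i, j = qpos - 1, spos - 1
    cur = score_l
    while i >= 0 and j >= 0:
        cur += mat[q[i], s[j]]
        if cur > best:
            best, best_left = cur, i
        if best - cur > x_drop:
            break
        i -= 1
        j -= 1
    return best_left, best_right, int(best)


def _banded_affine_local(q: np.ndarray, s: np.ndarray, mat: np.ndarray,
                         gap_open: int, gap_extend: int, d0: int, band: int):
    """Banded Smith-Waterman with affine gaps around diagonal d0 (= j - i).

    Returns (score, q_start, q_end, s_start, s_end, matches, aln_len,
    gap_opens) or None if no positive-scoring cell exists in the band.
    """
    n, m = len(q), len(s)
    width = 2 * band + 1
    NEG = -(10 ** 9)
    go = -(gap_open + gap_extend)
    ge = -gap_extend
    H_prev = [0] * width
    X_prev = [NEG] * width   # gap in subject (vertical move)
    ptr_rows = []            # per row: 0 stop, 1 diag, 2 up(from H), 3 up(from X), 4 left(from H), 5 left(from Y)
    best = 0
    best_pos = None
    for i in range(n):
        H_cur = [0] * width
        X_cur = [NEG] * width
        Y = NEG  # gap in query (horizontal), scans left-to-right within row
        ptr = bytearray(3 * width)  # ptrH, ptrX, ptrY interleaved
        qi = q[i]
        base_j = i + d0 - band
        row_mat = mat[qi]
        for k in range(width):
            j = base_j + k
            if j < 0 or j >= m:
                H_cur[k] = NEG
                X_cur[k] = NEG
                Y = NEG
                continue
            # X: gap in subject (come from row i-1, same k? j fixed, i-1 => k+1)
            up_h = H_prev[k + 1] if k + 1 < width else NEG
            up_x = X_prev[k + 1] if k + 1 < width else NEG
            x_open = up_h + go
            x_ext = up_x + ge
            if x_open >= x_ext:
                X_cur[k] = x_open
                ptr[3 * k + 1] = 2
            else:
                X_cur[k] = x_ext
                ptr[3 * k + 1] = 3
            # Y: gap in query (same row, j-1 => k-1)
            left_h = H_cur[k - 1] if k >= 1 else NEG
            y_open = left_h + go
            y_ext = Y + ge
            if y_open >= y_ext:
                Y = y_open
                ptr[3 * k + 2] = 4
            else:
                Y = y_ext
                ptr[3 * k + 2] = 5
            # H
            diag = H_prev[k] + row_mat[s[j]] if H_prev[k] > NEG // 2 else NEG
            h = 0
            p = 0
            if diag > h:
                h, p = diag, 1
            if X_cur[k] > h:
                h, p = X_cur[k], 2
            if Y > h:
                h, p = Y, 3
            H_cur[k] = h
            ptr[3 * k] = p
            if h > best:
                best = h
                best_pos = (i, k)
        ptr_rows.append(ptr)
        H_prev, X_prev = H_cur, X_cur
    if best_pos is None or best <= 0:
        return None
    # traceback
    i, k = best_pos
    state = 0  # 0=H, 1=X, 2=Y
    matches = aln_len = gap_opens = 0
    q_end = i + 1
    s_end = i + d0 - band + k + 1
    while i >= 0:
        ptr = ptr_rows[i]
        if state == 0:
            p = ptr[3 * k]
            if p == 0:
                break
            if p == 1:
                j = i + d0 - band + k
                aln_len += 1
                if q[i] == s[j]:
                    matches += 1
                i -= 1
                continue
            state = 1 if p == 2 else 2
        elif state == 1:  # gap in subject: consumed q[i]
            p = ptr[3 * k + 1]
            aln_len += 1
            if p == 2:
                gap_opens += 1
                state = 0
            i -= 1
            k += 1
            continue
        else:  # gap in query: consumed s[j]
            p = ptr[3 * k + 2]
            aln_len += 1
            if p == 4:
                gap_opens += 1
                state = 0
            k -= 1
            continue
    q_start = i + 1
    s_start = i + d0 - band + k + 1
    return best, q_start, q_end, s_start, s_end, matches, aln_len, gap_opens


def _protein_word_neighbors(q_enc: np.ndarray, word_size: int, mat: np.ndarray,
                            threshold: int, subject_words: dict):
    """Yield (qpos, spos) seeds where the subject word scores >= threshold
    against the query word under the substitution matrix."""
    sw_keys = list(subject_words)
    if not sw_keys:
        return
    sw_arr = np.array(sw_keys, dtype=np.int64)  # packed base-32 words
    digits = [(sw_arr >> (5 * t)) & 31 for t in range(word_size)]
    cache: dict[int, np.ndarray] = {}
    for qpos in range(len(q_enc) - word_size + 1):
        qword = 0
        for t in range(word_size):
            qword |= int(q_enc[qpos + t]) << (5 * t)
        hits = cache.get(qword)
        if hits is None:
            scores = np.zeros(len(sw_arr), dtype=np.int64)
            for t in range(word_size):
                scores += mat[int(q_enc[qpos + t]), digits[t]]
            hits = np.nonzero(scores >= threshold)[0]
            cache[qword] = hits
        for h in hits:
            for spos in subject_words[sw_keys[int(h)]]:
                yield qpos, spos


def _index_words(enc: np.ndarray, word_size: int, n_letters: int) -> dict:
    """Map packed word -> positions; words containing N/X are skipped."""
    idx: dict[int, list[int]] = {}
    wild = n_letters - 1
    for pos in range(len(enc) - word_size + 1):
        word = 0
        ok = True
        for t in range(word_size):
            c = int(enc[pos + t])
            if c == wild:
                ok = False
                break
            word |= c << (5 * t)
        if ok:
            idx.setdefault(word, []).append(pos)
    return idx


def _search_one_strand(q_enc, query_id, query_len, subject, s_enc, scheme, mat,
                       params, strand, total_db_len, word_index):
    hsps = []
    w = params.word_size
    if w > len(q_enc) or w > len(s_enc):
        return hsps
    if scheme.kind == "nucleotide":
        q_index_iter = []
        for qpos in range(len(q_enc) - w + 1):
            word = 0
            ok = True
            for t in range(w):
                c = int(q_enc[qpos + t])
                if c == 4:
                    ok = False
                    break
                word |= c << (5 * t)
            if ok and word in word_index:
                for spos in word_index[word]:
                    q_index_iter.append((qpos, spos))
        seeds = q_index_iter
    else:
        seeds = _protein_word_neighbors(q_enc, w, mat, params.neighborhood_threshold,
                                        word_index)
    hwm: dict[int, int] = {}  # diagonal -> query end already extended through
    gap_trigger = math.ceil((params.gap_trigger_bits * LN2 + math.log(scheme.K)) / scheme.lam)
    for qpos, spos in seeds:
        diag = qpos - spos
        if hwm.get(diag, -1) >= qpos + w:
            continue
        qs, qe, score = _ungapped_extend(q_enc, s_enc, qpos, spos, w, mat, params.x_drop)
        hwm[diag] = qe
        ss, se = qs - diag, qe - diag
        matches = int(np.sum(q_enc[qs:qe] == s_enc[ss:se]))
        aln_len = qe - qs
        mismatches = aln_len - matches
        gap_opens = 0
        if score >= gap_trigger:
            # banded gapped extension in a window around the ungapped HSP;
            # the window grows while the optimum presses against its edge
            pad = params.band + 112
            while True:
                q0, q1 = max(0, qs - pad), min(len(q_enc), qe + pad)
                s0, s1 = max(0, ss - pad), min(len(s_enc), se + pad)
                sub_d0 = (ss - s0) - (qs - q0)
                res = _banded_affine_local(q_enc[q0:q1], s_enc[s0:s1], mat,
                                           scheme.gap_open, scheme.gap_extend,
                                           sub_d0, params.band)
                if res is None or pad >= 4096:
                    break
                wqs, wqe, wss, wse = res[1:5]
                at_edge = ((wqs < 8 and q0 > 0) or (wss < 8 and s0 > 0)
                           or (q1 - q0 - wqe < 8 and q1 < len(q_enc))
                           or (s1 - s0 - wse < 8 and s1 < len(s_enc)))
                if not at_edge:
                    break
                pad *= 2
            if res is not None and res[0] >= score:
                score, wqs, wqe, wss, wse, matches, aln_len, gap_opens = res
                qs, qe, ss, se = q0 + wqs, q0 + wqe, s0 + wss, s0 + wse
                mismatches = (qe - qs) + (se - ss) - aln_len - matches
        ev = evalue_of(score, query_len, total_db_len, scheme)
        if ev > params.evalue_cutoff:
            continue
        if strand == "-":
            h = Hsp(query_id=query_id, subject_id=subject.id,
                    q_start=query_len - qe, q_end=query_len - qs,
                    s_start=ss, s_end=se, strand="-", raw_score=int(score),
                    bitscore=bitscore_of(score, scheme), evalue=ev,
                    pct_identity=100.0 * matches / aln_len, aln_len=aln_len,
                    mismatches=mismatches, gap_opens=gap_opens)
        else:
            h = Hsp(query_id=query_id, subject_id=subject.id, q_start=qs, q_end=qe,
                    s_start=ss, s_end=se, strand="+", raw_score=int(score),
                    bitscore=bitscore_of(score, scheme), evalue=ev,
                    pct_identity=100.0 * matches / aln_len, aln_len=aln_len,
                    mismatches=mismatches, gap_opens=gap_opens)
        hsps.append(h)
    return hsps


def _dedupe(hsps: list[Hsp]) -> list[Hsp]:
    """Merge overlapping same-diagonal HSPs on a subject, keeping the best."""
    kept: list[Hsp] = []
    for h in sorted(hsps, key=lambda x: (-x.raw_score, x.evalue)):
        redundant = False
        for k in kept:
            if k.subject_id != h.subject_id or k.strand != h.strand:
                continue
            same_diag = (k.q_start - k.s_start == h.q_start - h.s_start
                         and k.gap_opens == 0 and h.gap_opens == 0
                         and h.q_start < k.q_end and k.q_start < h.q_end)
            contained = (k.q_start <= h.q_start and h.q_end <= k.q_end
                         and k.s_start <= h.s_start and h.s_end <= k.s_end)
            if same_diag or contained:
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def find_hsps(query: Scaffold | ProteinRecord, db, scheme: ScoringScheme,
              params: SearchParams | None = None) -> list[Hsp]:
    """Search ``query`` against every record in ``db``; returns HSPs with
    E <= cutoff sorted by ascending E then descending score."""
    if not scheme.calibrated:
        raise ValueError("scheme is not calibrated; run calibrate_scoring first")
    params = (params or SearchParams()).resolved(scheme.kind)
    db = list(db)
    if not db:
        return []
    total_db_len = sum(len(r.seq) for r in db)
    mat = scheme.matrix()
    q_enc = scheme.encode(query.seq)
    hsps: list[Hsp] = []
    n_letters = len(scheme.letters)
    strands = ["+"] if scheme.kind == "protein" else ["+", "-"]
    q_rc_enc = scheme.encode(reverse_complement(query.seq)) if "-" in strands else None
    for subject in db:
        s_enc = scheme.encode(subject.seq)
        if params.word_size > len(s_enc):
            continue
        word_index = _index_words(s_enc, params.word_size, n_letters)
        for strand in strands:
            qe = q_enc if strand == "+" else q_rc_enc
            hsps.extend(_search_one_strand(qe, query.id, len(query.seq), subject,
                                           s_enc, scheme, mat, params, strand,
                                           total_db_len, word_index))
    hsps = _dedupe(hsps)
    hsps.sort(key=lambda h: (h.evalue, -h.raw_score, h.subject_id))
    return hsps


def best_hit(query, db, scheme: ScoringScheme,
             params: SearchParams | None = None) -> Hsp | None:
    """Minimum-E HSP; ties broken by raw score, then lexicographic subject id."""
    hits = find_hsps(query, db, scheme, params)
    return hits[0] if hits else None


def global_align_protein(seq_a: str, seq_b: str, scheme: ScoringScheme):
    """Global (Needleman-Wunsch) protein alignment with the scheme's matrix
    and affine gap costs; returns the two gapped strings."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    aln = aligner.align(seq_a.replace("X", "A"), seq_b.replace("X", "A"))[0]
    a_gapped, b_gapped = str(aln[0]), str(aln[1])
    # restore any X residues masked for matrix lookup
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(a_gapped, b_gapped):
        if ca != "-":
            out_a.append(seq_a[ia])
            ia += 1
        else:
            out_a.append("-")
        if cb != "-":
            out_b.append(seq_b[ib])
            ib += 1
        else:
            out_b.append("-")
    return "".join(out_a), "".join(out_b)


OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                   "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def hsp_to_outfmt6(h: Hsp) -> list:
    """BLAST outfmt-6-style row; coordinates 1-based inclusive, minus-strand
    subject coordinates reversed as BLAST does."""
    if h.strand == "-":
        sstart, send = h.s_end, h.s_start + 1
    else:
        sstart, send = h.s_start + 1, h.s_end
    return [h.query_id, h.subject_id, f"{h.pct_identity:.2f}", h.aln_len,
            h.mismatches, h.gap_opens, h.q_start + 1, h.q_end, sstart, send,
            f"{h.evalue:.3g}", f"{h.bitscore:.1f}"]
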