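"""Degenerate primer design over conserved alignment blocks and in-silico PCR.

Primers are IUPAC consensus strings over gap-free alignment windows whose
total degeneracy (product of per-position code cardinalities) stays within a
budget, mirroring how a survey primer pair is designed from an alignment of
two homologs.  The in-silico PCR scan is degeneracy-aware (a template base
matches a code if it belongs to the code's base set), tolerates a bounded
number of mismatches outside an exactly matching 3' anchor, and reports all
forward/reverse site pairings up to a product-size limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

from .datamodel import Scaffold

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC.items()}
_IUPAC_COMPLEMENT = {code: _SET_TO_CODE[frozenset({"ACGT"["TGCA".index(b)] for b in bases})]
                     for code, bases in IUPAC.items()}


def iupac_consensus(bases) -> str:
    """Smallest IUPAC code covering all observed bases."""
    return _SET_TO_CODE[frozenset().union(*(IUPAC[b] for b in bases))]


def reverse_complement_iupac(seq: str) -> str:
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(seq))


def degeneracy_of(iupac_seq: str) -> int:
    d = 1
    for c in iupac_seq:
        d *= len(IUPAC[c])
    return d


def expand(iupac_seq: str) -> list[str]:
    """All non-degenerate variants (use only for small degeneracy)."""
    return ["".join(p) for p in iter_product(*(sorted(IUPAC[c]) for c in iupac_seq))]


@dataclass(frozen=True)
class DegeneratePrimer:
    name: str
    iupac_seq: str
    alignment_span: tuple[int, int] = (0, 0)  # column interval of origin

    def __post_init__(self):
        for c in self.iupac_seq:
            if c not in IUPAC:
                raise ValueError(f"primer {self.name!r}: bad IUPAC code {c!r}")

    @property
    def degeneracy(self) -> int:
        return degeneracy_of(self.iupac_seq)


@dataclass(frozen=True)
class Amplicon:
    template_id: str
    fwd_site: tuple[int, int]  # 0-based half-open on the + strand
    rev_site: tuple[int, int]
    product_length: int
    fwd_mismatches: int
    rev_mismatches: int


def find_conserved_blocks(dna_alignment, min_len: int = 18,
                          max_degeneracy: int = 512) -> list[tuple[int, int]]:
    """Maximal gap-free column windows whose per-column consensus keeps the
    window degeneracy within budget; sorted by ascending degeneracy then
    descending length."""
    seqs = [rec.seq if hasattr(rec, "seq") else rec[1] for rec in dna_alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned sequences")
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("aligned sequences must have equal lengths")
    length = len(seqs[0])
    card = []
    for col in range(length):
        bases = {s[col] for s in seqs}
        card.append(0 if "-" in bases else len(IUPAC[iupac_consensus(bases)]))
    blocks = []
    start = None
    for col in range(length + 1):
        gap_or_end = col == length or card[col] == 0
        if start is None:
            if not gap_or_end:
                start = col
            continue
        if gap_or_end:
            blocks.extend(_split_block(card, start, col, min_len, max_degeneracy))
            start = None

    def block_deg(b):
        d = 1
        for c in range(b[0], b[1]):
            d *= card[c]
        return d

    blocks.sort(key=lambda b: (block_deg(b), -(b[1] - b[0]), b[0]))
    return blocks


def _split_block(card, start, end, min_len, max_degeneracy):
    """Maximal sub-windows of [start, end) within the degeneracy budget
    (two-pointer sweep over the running product)."""
    out = []
    lo = start
    prod = 1
    last_emitted = None
    for hi in range(start, end):
        prod *= card[hi]
        while prod > max_degeneracy:
            prod //= card[lo]
            lo += 1
        if hi + 1 - lo >= min_len:
            window = (lo, hi + 1)
            if last_emitted and last_emitted[0] == lo:
                out[-1] = window  # extend the maximal window with the same start
            else:
                out.append(window)
            last_emitted = window
    # keep only maximal windows (drop any contained in a neighbor)
    maximal = [w for w in out
               if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in out)]
    return maximal


def make_primer(block: tuple[int, int], dna_alignment, orientation: str = "forward",
                name: str = "primer") -> DegeneratePrimer:
    """IUPAC consensus over the block columns; reverse orientation returns the
    reverse complement (for priming the minus strand)."""
    seqs = [rec.seq if hasattr(rec, "seq") else rec[1] for rec in dna_alignment]
    consensus = "".join(iupac_consensus({s[c] for s in seqs})
                        for c in range(block[0], block[1]))
    if orientation == "reverse":
        consensus = reverse_complement_iupac(consensus)
    elif orientation != "forward":
        raise ValueError(f"bad orientation {orientation!r}")
    return DegeneratePrimer(name=name, iupac_seq=consensus, alignment_span=block)


def _match_sites(primer_seq: str, template: str, max_mismatch: int, anchor_3prime: int):
    """(start, mismatches) for every template position where the primer binds
    reading 5'->3' along the template; the 3'-terminal anchor must match
    exactly (degeneracy-aware)."""
    plen = len(primer_seq)
    sets = [IUPAC[c] for c in primer_seq]
    sites = []
    for start in range(len(template) - plen + 1):
        mism = 0
        ok = True
        for k in range(plen):
            if template[start + k] in sets[k]:
                continue
            if k >= plen - anchor_3prime:
                ok = False
                break
            mism += 1
            if mism > max_mismatch:
                ok = False
                break
        if ok:
            sites.append((start, mism))
    return sites


def insilico_pcr(fwd: DegeneratePrimer, rev: DegeneratePrimer, template: Scaffold,
                 max_mismatch: int = 1, anchor_3prime: int = 3,
                 max_product: int = 5000) -> list[Amplicon]:
    """All products where the forward primer binds the + strand upstream of a
    - strand binding site of the reverse primer; sorted by product length."""
    fwd_sites = _match_sites(fwd.iupac_seq, template.seq, max_mismatch, anchor_3prime)
    # a - strand site of rev corresponds to + strand match of its reverse complement,
    # with the primer's 3' end at the left (template) edge of the site
    rev_rc = reverse_complement_iupac(rev.iupac_seq)
    rev_rc_sets = [IUPAC[c] for c in rev_rc]
    rlen = len(rev_rc)
    rev_sites = []
    for start in range(len(template.seq) - rlen + 1):
        mism = 0
        ok = True
        for k in range(rlen):
            if template.seq[start + k] in rev_rc_sets[k]:
                continue
            if k < anchor_3prime:  # 3' end of the reverse primer sits leftmost
                ok = False
                break
            mism += 1
            if mism > max_mismatch:
                ok = False
                break
        if ok:
            rev_sites.append((start, mism))
    products = []
    for fstart, fm in fwd_sites:
        for rstart, rm in rev_sites:
            length = rstart + rlen - fstart
            if 0 < length <= max_product and rstart >= fstart + len(fwd.iupac_seq):
                products.append(Amplicon(template_id=template.id,
                                         fwd_site=(fstart, fstart + len(fwd.iupac_seq)),
                                         rev_site=(rstart, rstart + rlen),
                                         product_length=length,
                                         fwd_mismatches=fm, rev_mismatches=rm))
    products.sort(key=lambda a: (a.product_length, a.fwd_site))
    return products
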