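"""Reciprocal-best-hit orthology, identity Z-scores and microsynteny.

A 1:1 ortholog pair requires each protein to be the other's unique best hit.
The identity Z-score situates a focal pair's percent identity within the
distribution of identities over all background ortholog pairs - a transferred
gene that arrived before two hosts diverged should look no more and no less
diverged than any vertically inherited gene, which is the corroboration this
statistic formalizes.  Microsynteny checks that the genes flanking the focal
locus are themselves 1:1 orthologs in conserved order across assemblies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .datamodel import Assembly, GeneModel
from .homology import SearchParams, best_hit
from .scoring import ScoringScheme


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    pct_identity: float  # over the best HSP's aligned columns
    evalue_ab: float
    evalue_ba: float


@dataclass
class SyntenyReport:
    focal_pair: OrthologPair
    window: int
    shared_flank_fraction: float
    order_conserved: bool
    neighbor_gap_bp: int | None = None


def reciprocal_best_hits(proteome_a, proteome_b, scheme: ScoringScheme,
                         params: SearchParams | None = None) -> list[OrthologPair]:
    """All (a, b) with b the unique best hit of a in B and vice versa."""
    if not proteome_a or not proteome_b:
        raise ValueError("proteomes must be non-empty")
    params = params or SearchParams(evalue_cutoff=1e-3)
    fwd = {}
    for rec in proteome_a:
        h = best_hit(rec, proteome_b, scheme, params)
        if h is not None:
            fwd[rec.id] = h
    rev = {}
    for rec in proteome_b:
        h = best_hit(rec, proteome_a, scheme, params)
        if h is not None:
            rev[rec.id] = h
    pairs = []
    for a_id, h_ab in fwd.items():
        b_id = h_ab.subject_id
        h_ba = rev.get(b_id)
        if h_ba is not None and h_ba.subject_id == a_id:
            pairs.append(OrthologPair(gene_a=a_id, gene_b=b_id,
                                      pct_identity=h_ab.pct_identity,
                                      evalue_ab=h_ab.evalue, evalue_ba=h_ba.evalue))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def identity_zscore(focal_pair: OrthologPair, background: list[OrthologPair]):
    """(z, mean, sd) of the focal identity against the background identities
    (focal excluded from the background; sd uses the n-1 denominator)."""
    values = [p.pct_identity for p in background
              if not (p.gene_a == focal_pair.gene_a and p.gene_b == focal_pair.gene_b)]
    if len(values) < 2:
        raise ValueError("background must contain at least 2 other pairs")
    mean = sum(values) / len(values)
    var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
    sd = math.sqrt(var)
    if sd == 0:
        raise ValueError("degenerate background: zero standard deviation")
    return (focal_pair.pct_identity - mean) / sd, mean, sd


def _flank(assembly: Assembly, gene: GeneModel, window: int):
    """(upstream, downstream) gene-id lists within `window` genes of the focal."""
    genes = assembly.genes[gene.scaffold_id]
    idx = next(i for i, g in enumerate(genes) if g.gene_id == gene.gene_id)
    up = [g.gene_id for g in genes[max(0, idx - window):idx]]
    down = [g.gene_id for g in genes[idx + 1:idx + 1 + window]]
    return up, down


def microsynteny(focal_pair: OrthologPair, assembly_a: Assembly, assembly_b: Assembly,
                 ortholog_map: dict, window: int = 4) -> SyntenyReport:
    """Fraction of focal-flank genes whose 1:1 orthologs land inside the
    partner's flank, and whether their relative order is conserved
    (whole-window reversal allowed)."""
    try:
        gene_a = assembly_a.gene(focal_pair.gene_a)
    except KeyError:
        raise ValueError(f"focal gene {focal_pair.gene_a!r} absent from assembly A")
    try:
        gene_b = assembly_b.gene(focal_pair.gene_b)
    except KeyError:
        raise ValueError(f"focal gene {focal_pair.gene_b!r} absent from assembly B")
    up_a, down_a = _flank(assembly_a, gene_a, window)
    up_b, down_b = _flank(assembly_b, gene_b, window)
    flank_a = up_a + down_a
    flank_b = up_b + down_b
    denominator = min(len(flank_a), 2 * window)
    if denominator == 0:
        return SyntenyReport(focal_pair=focal_pair, window=window,
                             shared_flank_fraction=0.0, order_conserved=False)
    partner_pos = {gid: i for i, gid in enumerate(flank_b)}
    shared = [(i, partner_pos[ortholog_map[gid]])
              for i, gid in enumerate(flank_a)
              if gid in ortholog_map and ortholog_map[gid] in partner_pos]
    fraction = len(shared) / denominator
    if len(shared) >= 2:
        b_order = [b for _, b in sorted(shared)]
        order_ok = (b_order == sorted(b_order) or b_order == sorted(b_order, reverse=True))
    else:
        order_ok = len(shared) == 1
    return SyntenyReport(focal_pair=focal_pair, window=window,
                         shared_flank_fraction=fraction, order_conserved=order_ok)


def neighbor_distance(focal_gene: GeneModel, assembly: Assembly):
    """(neighbor_id, gap_bp) of the nearest other gene on the scaffold by
    end-to-start gap (0 if overlapping); ties go to the downstream gene.
    Returns None on a single-gene scaffold."""
    genes = assembly.genes[focal_gene.scaffold_id]
    if len(genes) < 2:
        return None
    best = None
    for g in genes:
        if g.gene_id == focal_gene.gene_id:
            continue
        if g.start >= focal_gene.end:
            gap = g.start - focal_gene.end
            downstream = True
        elif focal_gene.start >= g.end:
            gap = focal_gene.start - g.end
            downstream = False
        else:
            gap = 0
            downstream = g.start >= focal_gene.start
        key = (gap, 0 if downstream else 1, g.gene_id)
        if best is None or key < best[0]:
            best = (key, g.gene_id, gap)
    return best[1], best[2]


def bridging_interval(focal_gene: GeneModel, assembly: Assembly):
    """Genomic interval spanning the focal gene's 3'-most boundary with its
    nearest neighbor - the region a chimera-excluding bridging PCR targets."""
    nb = neighbor_distance(focal_gene, assembly)
    if nb is None:
        return None
    neighbor = assembly.gene(nb[0])
    lo = min(focal_gene.start, neighbor.start)
    hi = max(focal_gene.end, neighbor.end)
    return focal_gene.scaffold_id, lo, hi
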