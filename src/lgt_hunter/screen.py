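"""The differential-homology LGT screen.

Scaffold regions with strong nucleotide-level bacterial similarity
(E below cutoff) are candidate transfers; a candidate is discarded when the
same region matches an animal panel even better (a conserved eukaryotic
gene, not a transfer) or when it sits on a sub-threshold scaffold (short
scaffolds are enriched for environmental contamination rather than genuine
host sequence).  Every candidate is reported with an ordered audit trail of
the filters applied, so exclusions are inspectable rather than silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .datamodel import Assembly, Scaffold
from .homology import Hsp, SearchParams, best_hit, find_hsps
from .scoring import ScoringScheme

RETAINED = "retained"
EXCLUDED_ANIMAL = "excluded_animal"
EXCLUDED_SCAFFOLD_LENGTH = "excluded_scaffold_length"


@dataclass
class ScreenParams:
    bacterial_evalue_cutoff: float = 1e-5
    min_scaffold_length: int = 5000
    hsp_merge_gap: int = 1000

    def __post_init__(self):
        if self.bacterial_evalue_cutoff <= 0:
            raise ValueError("bacterial_evalue_cutoff must be > 0")
        if self.min_scaffold_length < 0:
            raise ValueError("min_scaffold_length must be >= 0")


@dataclass
class LgtCandidate:
    scaffold_id: str
    region: tuple[int, int]  # 0-based half-open
    bacterial_best: Hsp
    animal_best_evalue: float | None = None
    status: str = RETAINED
    audit: list[str] = field(default_factory=list)


def find_bacterial_regions(assembly: Assembly, bacterial_db, scheme: ScoringScheme,
                           params: ScreenParams) -> list[LgtCandidate]:
    """Merge all sub-cutoff bacterial HSPs per scaffold into candidate regions
    (HSPs closer than hsp_merge_gap coalesce); each region carries its
    minimum-E HSP."""
    candidates = []
    search = SearchParams(evalue_cutoff=params.bacterial_evalue_cutoff)
    for sid, scaffold in assembly.scaffolds.items():
        hsps = find_hsps(scaffold, bacterial_db, scheme, search)
        if not hsps:
            continue
        intervals = sorted((h.q_start, h.q_end, h) for h in hsps)
        merged: list[list] = []
        for qs, qe, h in intervals:
            if merged and qs - merged[-1][1] <= params.hsp_merge_gap:
                merged[-1][1] = max(merged[-1][1], qe)
                merged[-1][2].append(h)
            else:
                merged.append([qs, qe, [h]])
        for qs, qe, hs in merged:
            best = min(hs, key=lambda h: (h.evalue, -h.raw_score))
            candidates.append(LgtCandidate(
                scaffold_id=sid, region=(qs, qe), bacterial_best=best,
                audit=[f"bacterial_region:E={best.evalue:.3g}<"
                       f"{params.bacterial_evalue_cutoff:g}"]))
    return candidates


def animal_filter(candidate: LgtCandidate, animal_db, scheme: ScoringScheme,
                  params: ScreenParams, assembly: Assembly) -> LgtCandidate:
    """Search the extracted candidate region against the animal panel; exclude
    iff the animal E-value is strictly smaller than the bacterial one."""
    qs, qe = candidate.region
    region_seq = assembly.scaffolds[candidate.scaffold_id].seq[qs:qe]
    region = Scaffold(id=f"{candidate.scaffold_id}:{qs}-{qe}", seq=region_seq)
    hit = best_hit(region, list(animal_db), scheme, SearchParams()) if animal_db else None
    animal_e = hit.evalue if hit is not None else None
    status = candidate.status
    if animal_e is not None and animal_e < candidate.bacterial_best.evalue:
        status = EXCLUDED_ANIMAL
    note = "none" if animal_e is None else f"{animal_e:.3g}"
    return replace(candidate, animal_best_evalue=animal_e, status=status,
                   audit=candidate.audit + [f"animal_filter:animal_E={note}"])


def scaffold_length_filter(candidate: LgtCandidate, assembly: Assembly,
                           params: ScreenParams) -> LgtCandidate:
    """Exclude candidates on scaffolds strictly shorter than the threshold."""
    scaffold = assembly.scaffolds.get(candidate.scaffold_id)
    if scaffold is None:
        raise ValueError(f"unknown scaffold {candidate.scaffold_id!r}")
    status = candidate.status
    if scaffold.length < params.min_scaffold_length and status == RETAINED:
        status = EXCLUDED_SCAFFOLD_LENGTH
    return replace(candidate, status=status,
                   audit=candidate.audit + [f"scaffold_length_filter:{scaffold.length}bp"])


def screen(assembly: Assembly, bacterial_db, animal_db, scheme: ScoringScheme,
           params: ScreenParams | None = None) -> list[LgtCandidate]:
    """Full filter chain: bacterial regions -> animal filter -> length filter.
    Returns every candidate (retained first, ascending bacterial E) with its
    complete audit trail."""
    params = params or ScreenParams()
    candidates = find_bacterial_regions(assembly, bacterial_db, scheme, params)
    candidates = [animal_filter(c, animal_db, scheme, params, assembly)
                  for c in candidates]
    candidates = [scaffold_length_filter(c, assembly, params) for c in candidates]
    candidates.sort(key=lambda c: (c.status != RETAINED, c.bacterial_best.evalue))
    return candidates


def candidate_rows(candidates: list[LgtCandidate]) -> list[list]:
    """TSV rows (1-based inclusive region coordinates) for reporting."""
    rows = []
    for c in candidates:
        rows.append([c.scaffold_id, c.region[0] + 1, c.region[1],
                     c.bacterial_best.subject_id, f"{c.bacterial_best.evalue:.3g}",
                     "none" if c.animal_best_evalue is None else f"{c.animal_best_evalue:.3g}",
                     c.status, ";".join(c.audit)])
    return rows


CANDIDATE_COLUMNS = ["scaffold_id", "region_start", "region_end", "best_subject",
                     "bacterial_evalue", "animal_evalue", "status", "audit"]
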