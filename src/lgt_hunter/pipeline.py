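"""End-to-end characterization: screen, then corroborate each retained
candidate with orthology/synteny context, dN/dS, phylogenetic placement and
survey primers, collected into one report per candidate.

Optional stages degrade gracefully: a stage whose inputs are missing (or
which fails) is marked skipped with a reason rather than aborting the run;
the screen itself is required.  Reports embed the full configuration so
every threshold used is visible in the output.
"""

from __future__ import annotations

import os
import sys
import time
from dataclasses import dataclass, field

from . import __version__
from .datamodel import Assembly
from .io import read_fasta, read_gene_table, write_tsv
from .orthology import neighbor_distance
from .placement import bootstrap_supports, classify_origin
from .primer import find_conserved_blocks, insilico_pcr, make_primer
from .screen import (CANDIDATE_COLUMNS, RETAINED, ScreenParams, candidate_rows,
                     screen)
from .scoring import nucleotide_default
from .selection import build_codon_alignment, ml_pairwise_dnds, ng86

REQUIRED_KEYS = ("genome", "genes", "bacteria", "animal")


@dataclass
class Section:
    status: str = "skipped"  # ok | skipped | failed
    reason: str = ""
    data: object = None


@dataclass
class CandidateReport:
    candidate: object
    gene_id: str | None
    orthology: Section = field(default_factory=Section)
    selection: Section = field(default_factory=Section)
    placement: Section = field(default_factory=Section)
    primers: Section = field(default_factory=Section)
    provenance: dict = field(default_factory=dict)


def read_config(path) -> dict:
    """Plain key = value config file; '#' lines are comments."""
    cfg = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {line!r}")
            key, value = line.split("=", 1)
            cfg[key.strip()] = value.strip()
    return cfg


def validate_config(cfg: dict) -> dict:
    for key in REQUIRED_KEYS:
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
        if not os.path.exists(cfg[key]):
            raise ValueError(f"config path for {key!r} does not exist: {cfg[key]}")
    for key in ("evalue",):
        if key in cfg and float(cfg[key]) <= 0:
            raise ValueError(f"{key} must be positive")
    return cfg


def _log(quiet: bool, msg: str) -> None:
    if not quiet:
        print(msg, file=sys.stderr)


def _candidate_gene(assembly: Assembly, cand):
    """Gene model overlapping the candidate region, if any."""
    for g in assembly.genes.get(cand.scaffold_id, []):
        if g.start < cand.region[1] and cand.region[0] < g.end:
            return g
    return None


def run_pipeline(config, quiet: bool = False) -> list[CandidateReport]:
    """Execute screen -> per-candidate corroboration; returns one report per
    retained candidate (excluded candidates appear in the screen TSV only)."""
    cfg = read_config(config) if not isinstance(config, dict) else dict(config)
    validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    t0 = time.time()

    assembly = Assembly()
    for scf in read_fasta(cfg["genome"], "dna"):
        assembly.add_scaffold(scf)
    read_gene_table(cfg["genes"], assembly)
    bacterial_db = read_fasta(cfg["bacteria"], "dna")
    animal_db = read_fasta(cfg["animal"], "dna")
    scheme = nucleotide_default()
    params = ScreenParams(
        bacterial_evalue_cutoff=float(cfg.get("evalue", 1e-5)),
        min_scaffold_length=int(cfg.get("min_scaffold", 5000)),
        hsp_merge_gap=int(cfg.get("merge_gap", 1000)))
    _log(quiet, f"[screen] {len(assembly.scaffolds)} scaffolds vs "
                f"{len(bacterial_db)} bacterial records")
    candidates = screen(assembly, bacterial_db, animal_db, scheme, params)
    _log(quiet, f"[screen] {sum(c.status == RETAINED for c in candidates)} retained "
                f"of {len(candidates)} candidates ({time.time() - t0:.1f}s)")

    provenance = {"config": dict(cfg), "version": __version__, "seed": seed,
                  "scheme": f"{scheme.kind} match={scheme.match} mismatch={scheme.mismatch} "
                            f"gap={scheme.gap_open}/{scheme.gap_extend} "
                            f"lambda={scheme.lam:.4f} K={scheme.K:.4f}"}
    reports = []
    for cand in candidates:
        if cand.status != RETAINED:
            continue
        gene = _candidate_gene(assembly, cand)
        report = CandidateReport(candidate=cand,
                                 gene_id=gene.gene_id if gene else None,
                                 provenance=provenance)
        report.orthology = _orthology_stage(assembly, gene)
        report.selection = _selection_stage(cfg, gene)
        report.placement = _placement_stage(cfg, gene, seed, quiet)
        report.primers = _primer_stage(cfg, gene, assembly, cand)
        reports.append(report)
    # writers also need the excluded candidates for the audit TSV
    run_pipeline.last_candidates = candidates  # type: ignore[attr-defined]
    return reports


def _orthology_stage(assembly, gene) -> Section:
    if gene is None:
        return Section(status="skipped", reason="candidate overlaps no gene model")
    nb = neighbor_distance(gene, assembly)
    if nb is None:
        return Section(status="skipped", reason="single-gene scaffold")
    return Section(status="ok", data={"neighbor_id": nb[0], "neighbor_gap_bp": nb[1]})


def _selection_stage(cfg, gene) -> Section:
    if gene is None or not gene.cds_seq:
        return Section(status="skipped", reason="no CDS for candidate")
    if "partner_cds" not in cfg:
        return Section(status="skipped", reason="no partner_cds configured")
    try:
        partners = read_fasta(cfg["partner_cds"], "dna")
        results = []
        for partner in partners:
            pair = build_codon_alignment(gene.cds_seq, partner.seq,
                                         id_a=gene.gene_id, id_b=partner.id)
            results.append(ng86(pair))
            results.append(ml_pairwise_dnds(pair))
        return Section(status="ok", data=results)
    except Exception as exc:  # optional stage: failure is reported, not fatal
        return Section(status="failed", reason=str(exc))


def _placement_stage(cfg, gene, seed, quiet) -> Section:
    if "panel_alignment" not in cfg or "panel_labels" not in cfg:
        return Section(status="skipped", reason="no placement panel configured")
    focal = cfg.get("focal_panel_id", gene.gene_id if gene else "")
    try:
        panel = read_fasta(cfg["panel_alignment"], "protein")
        labels = {}
        with open(cfg["panel_labels"]) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("id\t"):
                    continue
                rec_id, kingdom = line.split()[:2]
                labels[rec_id] = kingdom
        reps = int(cfg.get("bootstrap_reps", 100))
        tree = bootstrap_supports([(r.id, r.seq) for r in panel], reps, seed=seed)
        call, side = classify_origin(tree, focal, labels,
                                     support_threshold=float(cfg.get("support", 0.8)))
        return Section(status="ok", data={"call": call, "tree": tree,
                                          "newick": tree.newick(),
                                          "clade": sorted(side) if side else None})
    except Exception as exc:
        return Section(status="failed", reason=str(exc))


def _primer_stage(cfg, gene, assembly, cand) -> Section:
    if gene is None or not gene.cds_seq or "partner_cds" not in cfg:
        return Section(status="skipped", reason="needs candidate CDS and partner_cds")
    try:
        partner = read_fasta(cfg["partner_cds"], "dna")[0]
        pair = build_codon_alignment(gene.cds_seq, partner.seq,
                                     id_a=gene.gene_id, id_b=partner.id)
        aln = [(pair.id_a, "".join(a for a, _ in pair.columns)),
               (pair.id_b, "".join(b for _, b in pair.columns))]
        blocks = find_conserved_blocks(aln, min_len=18,
                                       max_degeneracy=int(cfg.get("max_degeneracy", 512)))
        if len(blocks) < 2:
            return Section(status="skipped", reason="fewer than 2 conserved blocks")
        blocks_by_pos = sorted(blocks)
        fwd = make_primer(blocks_by_pos[0], aln, "forward", name="survey_fwd")
        rev = make_primer(blocks_by_pos[-1], aln, "reverse", name="survey_rev")
        templates = [assembly.scaffolds[cand.scaffold_id]]
        if "survey_templates" in cfg:
            templates += read_fasta(cfg["survey_templates"], "dna")
        amplicons = {t.id: insilico_pcr(fwd, rev, t) for t in templates}
        return Section(status="ok", data={"fwd": fwd, "rev": rev,
                                          "amplicons": amplicons})
    except Exception as exc:
        return Section(status="failed", reason=str(exc))


def characterize_ortholog_cds(path) -> dict:
    """Recompute the printed evidence for a real ortholog CDS set: peptide
    lengths, pairwise amino-acid identity (global alignment) and ML dN/dS
    for every record pair in the FASTA file.

    This is the entry point for reproducing the published numbers from the
    MonarchBase / SilkDB / DBM gene sets once the user has downloaded them;
    no reference sequences are bundled with the package.
    """
    from .datamodel import translate
    from .homology import global_align_protein
    from .scoring import protein_default

    records = read_fasta(path, "dna")
    scheme = protein_default()
    out = {"peptide_lengths": {}, "pairs": {}}
    proteins = {}
    for rec in records:
        cds = rec.seq[:-3] if rec.seq[-3:] in {"TAA", "TAG", "TGA"} else rec.seq
        proteins[rec.id] = translate(cds)
        out["peptide_lengths"][rec.id] = len(proteins[rec.id])
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            ga, gb = global_align_protein(proteins[a.id], proteins[b.id], scheme)
            both = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
            ident = 100.0 * sum(x == y for x, y in both) / len(both)
            pair = build_codon_alignment(a.seq, b.seq, id_a=a.id, id_b=b.id)
            ml = ml_pairwise_dnds(pair)
            out["pairs"][(a.id, b.id)] = {"pct_identity": ident,
                                          "omega": ml.omega, "dN": ml.dN,
                                          "dS": ml.dS, "n_codons": ml.n_codons}
    return out


def write_reports(reports, candidates, out_dir, quiet: bool = False) -> None:
    """TSV set plus one human-readable summary per retained candidate."""
    os.makedirs(out_dir, exist_ok=True)
    meta = ["coordinates in this report are 1-based inclusive",
            "raw m*n search space; ungapped Karlin-Altschul parameters"]
    write_tsv(os.path.join(out_dir, "candidates.tsv"), CANDIDATE_COLUMNS,
              candidate_rows(candidates), metadata=meta)
    for i, rep in enumerate(reports, 1):
        lines = [f"candidate {i}: scaffold {rep.candidate.scaffold_id} "
                 f"region {rep.candidate.region[0] + 1}-{rep.candidate.region[1]} "
                 f"({rep.gene_id or 'no gene model'})",
                 f"bacterial best: {rep.candidate.bacterial_best.subject_id} "
                 f"E={rep.candidate.bacterial_best.evalue:.3g}"]
        for name in ("orthology", "selection", "placement", "primers"):
            sec = getattr(rep, name)
            if sec.status != "ok":
                lines.append(f"{name}: {sec.status} ({sec.reason})")
            elif name == "selection":
                for r in sec.data:
                    lines.append(f"selection[{r.method}]: dN={r.dN:.4f} dS={r.dS:.4f} "
                                 f"omega={r.omega:.4f} n_codons={r.n_codons}")
            elif name == "placement":
                lines.append(f"placement: {sec.data['call']}")
            elif name == "primers":
                d = sec.data
                lines.append(f"primers: fwd {d['fwd'].iupac_seq} "
                             f"(deg {d['fwd'].degeneracy}) / rev {d['rev'].iupac_seq} "
                             f"(deg {d['rev'].degeneracy})")
                for tid, amps in d["amplicons"].items():
                    sizes = ",".join(str(a.product_length) for a in amps) or "none"
                    lines.append(f"  amplicons on {tid}: {sizes}")
            else:
                lines.append(f"{name}: {sec.data}")
        lines.append("provenance: " + "; ".join(f"{k}={v}" for k, v in
                                                rep.provenance["config"].items()))
        with open(os.path.join(out_dir, f"candidate_{i}_summary.txt"), "w") as fh:
            fh.write("\n".join(lines) + "\n")
    _log(quiet, f"[report] wrote {len(reports)} report(s) to {out_dir}")
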