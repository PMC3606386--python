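"""Synthetic genomes, reference panels and evolved sequence pairs with
recorded ground truth.

Every generator is a pure function of a :class:`SimulationRecipe` (or an
explicit seed), so identical recipes give byte-identical outputs.  The
standard "acceptance assembly" combines, in one synthetic genome, the three
fates the screen must distinguish: a genuinely implanted bacterial gene on a
long scaffold, a conserved host gene that also matches bacteria (the decoy
the animal filter exists to remove), and a short pure-bacterial contaminant
scaffold caught by the scaffold-length rule.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import (Assembly, GeneModel, ProteinRecord, Scaffold,
                        SENSE_CODONS, STOP_CODONS, reverse_complement)
from .placement import DistanceMatrix, PhyloTree, TreeNode
from .selection import CodonAlignmentPair, f3x4_codon_freqs, gy94_rate_matrix

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationRecipe:
    """Knobs of the synthetic study; defaults are the standard conditions
    exercised by the test suite."""

    seed: int = 7
    host_gc: float = 0.35
    donor_gc: float = 0.40
    n_scaffolds: int = 3
    scaffold_length_bp: int = 50_000
    genes_per_scaffold: int = 10
    gene_length_codons: int = 300
    implant_divergence: float = 0.20
    decoy_animal_divergence: float = 0.05
    decoy_bacterial_divergence: float = 0.25
    contaminant_length_bp: int = 3_000
    omega: float = 0.062
    kappa: float = 2.0
    t: float = 0.8

    def __post_init__(self):
        for name in ("implant_divergence", "decoy_animal_divergence",
                     "decoy_bacterial_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.75:
                raise ValueError(f"{name} = {v} outside [0, 0.75]")

    def rng(self, stream: str) -> np.random.Generator:
        # crc32 is stable across processes (str hash is salted)
        return np.random.default_rng([self.seed, zlib.crc32(stream.encode())])


@dataclass
class GroundTruth:
    implanted_regions: list = field(default_factory=list)  # (scaffold_id, (start, end), donor_id)
    decoy_gene_ids: list = field(default_factory=list)
    contaminant_scaffold_ids: list = field(default_factory=list)
    true_ortholog_pairs: list = field(default_factory=list)
    true_tree: str | None = None  # newick
    true_omega: float | None = None


def random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Intronless CDS: ATG + random sense codons weighted by GC + stop."""
    w = np.array([np.prod([gc / 2 if b in "GC" else (1 - gc) / 2 for b in c])
                  for c in SENSE_CODONS])
    w /= w.sum()
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 1, p=w)
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + "TAA"


def mutate_dna(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Uniform substitutions at per-site probability `divergence` (no indels)."""
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < divergence
    for i in np.nonzero(hit)[0]:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def mutate_cds(rng: np.random.Generator, cds: str, divergence: float) -> str:
    """Uniform substitutions like :func:`mutate_dna`, but a substitution that
    would create an internal stop codon is redrawn, keeping the sequence a
    translatable CDS (the implanted gene is a functional gene, not junk)."""
    arr = list(cds)
    hit = np.nonzero(rng.random(len(arr)) < divergence)[0]
    for i in hit:
        codon_start = 3 * (i // 3)
        alternatives = [b for b in "ACGT" if b != arr[i]]
        rng.shuffle(alternatives)
        for b in alternatives:
            trial = arr[codon_start:codon_start + 3]
            trial[i - codon_start] = b
            if "".join(trial) not in STOP_CODONS or codon_start == len(cds) - 3:
                arr[i] = b
                break
    return "".join(arr)


def evolve_cds(cds: str, omega: float, kappa: float, t: float, seed: int) -> str:
    """Evolve a CDS for time t (expected substitutions/codon) under the GY94
    model with uniform-ish F3x4 frequencies; the terminal stop is kept."""
    rng = np.random.default_rng(seed)
    stop = cds[-3:] if cds[-3:] in STOP_CODONS else ""
    body = cds[:-3] if stop else cds
    pi = f3x4_codon_freqs(_DEFAULT_POS_FREQS)
    Q = gy94_rate_matrix(pi, kappa, omega)
    out = []
    codon_index = {c: i for i, c in enumerate(SENSE_CODONS)}
    for k in range(0, len(body), 3):
        i = codon_index[body[k:k + 3]]
        out.append(SENSE_CODONS[_evolve_codon(rng, Q, i, t)])
    return "".join(out) + stop


def mutate_protein(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    arr = list(seq)
    for _ in range(n_subs):
        i = int(rng.integers(len(arr)))
        arr[i] = AA20[int(rng.integers(20))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# host assembly, implant, decoy, contaminant
# ---------------------------------------------------------------------------

def simulate_host_assembly(recipe: SimulationRecipe):
    """Random multi-scaffold assembly with non-overlapping intronless genes."""
    rng = recipe.rng("host")
    gene_len = 3 * recipe.gene_length_codons + 3  # incl. stop
    if recipe.genes_per_scaffold > 0:
        slot = recipe.scaffold_length_bp // recipe.genes_per_scaffold
        if gene_len + 10 > slot:
            raise ValueError("genes do not fit the scaffold at this density")
    assembly = Assembly()
    truth = GroundTruth()
    for s in range(recipe.n_scaffolds):
        sid = f"scaffold{s + 1}"
        seq = list(random_dna(rng, recipe.scaffold_length_bp, recipe.host_gc))
        genes = []
        for g in range(recipe.genes_per_scaffold):
            start = slot * g + int(rng.integers(0, slot - gene_len))
            cds = random_cds(rng, recipe.gene_length_codons + 1, recipe.host_gc)
            strand = "+" if rng.random() < 0.5 else "-"
            insert = cds if strand == "+" else reverse_complement(cds)
            seq[start:start + len(insert)] = list(insert)
            genes.append((f"{sid}_g{g + 1}", start, start + len(insert), strand, cds))
        assembly.add_scaffold(Scaffold(id=sid, seq="".join(seq)))
        for gid, start, end, strand, cds in genes:
            assembly.add_gene(GeneModel(gene_id=gid, scaffold_id=sid, start=start,
                                        end=end, strand=strand, cds_seq=cds))
    return assembly, truth


def _rebuild_scaffold(assembly: Assembly, sid: str, new_seq: str) -> None:
    assembly.scaffolds[sid] = Scaffold(id=sid, seq=new_seq)


def implant_lgt(assembly: Assembly, donor_gene: GeneModel, divergence: float,
                recipe: SimulationRecipe, truth: GroundTruth,
                scaffold_id: str | None = None) -> GroundTruth:
    """Mutate the donor CDS and write it into an intergenic interval."""
    rng = recipe.rng("implant")
    sid = scaffold_id or next(iter(assembly.scaffolds))
    scaffold = assembly.scaffolds[sid]
    genes = assembly.genes.get(sid, [])
    need = len(donor_gene.cds_seq) + 200
    # find the widest intergenic gap
    bounds = [0] + [x for g in genes for x in (g.start, g.end)] + [scaffold.length]
    gaps = [(bounds[i + 1] - bounds[i], bounds[i], bounds[i + 1])
            for i in range(0, len(bounds), 2)]
    gaps = [g for g in gaps if g[0] >= need]
    if not gaps:
        raise ValueError("no intergenic room for the implant")
    _, lo, hi = max(gaps)
    start = lo + 100
    mutated = mutate_cds(rng, donor_gene.cds_seq, divergence)
    seq = scaffold.seq[:start] + mutated + scaffold.seq[start + len(mutated):]
    _rebuild_scaffold(assembly, sid, seq)
    assembly.add_gene(GeneModel(gene_id="lgt_implant", scaffold_id=sid,
                                start=start, end=start + len(mutated),
                                strand="+", cds_seq=mutated))
    truth.implanted_regions.append((sid, (start, start + len(mutated)),
                                    donor_gene.gene_id))
    return truth


def make_decoy_conserved_gene(assembly: Assembly, bacterial_db: list, animal_db: list,
                              recipe: SimulationRecipe, truth: GroundTruth) -> GroundTruth:
    """Copy one host gene into the bacterial panel at high divergence and into
    the animal panel at low divergence, so its animal E-value wins."""
    rng = recipe.rng("decoy")
    sid = list(assembly.scaffolds)[-1]
    gene = assembly.genes[sid][0]
    region = assembly.scaffolds[sid].seq[gene.start:gene.end]
    bacterial_db.append(Scaffold(
        id="bact_decoy_homolog",
        seq=mutate_dna(rng, region, recipe.decoy_bacterial_divergence)))
    animal_db.append(Scaffold(
        id="animal_decoy_homolog",
        seq=mutate_dna(rng, region, recipe.decoy_animal_divergence)))
    truth.decoy_gene_ids.append(gene.gene_id)
    return truth


def make_acceptance_assembly(seed: int = 7, recipe: SimulationRecipe | None = None):
    """The standard screening fixture: one implant (retained), one decoy
    (excluded_animal), one short contaminant scaffold
    (excluded_scaffold_length).  Returns (assembly, bacterial_db, animal_db,
    truth, recipe)."""
    recipe = replace(recipe, seed=seed) if recipe else SimulationRecipe(seed=seed)
    assembly, truth = simulate_host_assembly(recipe)
    rng = recipe.rng("panels")

    # bacterial panel: one donor genome carrying the donor gene, plus noise genomes
    donor_cds = random_cds(rng, 667, recipe.donor_gc)  # ~2 kb donor gene
    donor_flank_l = random_dna(rng, 3000, recipe.donor_gc)
    donor_flank_r = random_dna(rng, 3000, recipe.donor_gc)
    donor_genome = Scaffold(id="donor_genome", seq=donor_flank_l + donor_cds + donor_flank_r)
    bacterial_db = [donor_genome,
                    Scaffold(id="bact_noise1", seq=random_dna(rng, 8000, 0.45)),
                    Scaffold(id="bact_noise2", seq=random_dna(rng, 8000, 0.55))]
    animal_db = [Scaffold(id="animal_noise1", seq=random_dna(rng, 8000, 0.40)),
                 Scaffold(id="animal_noise2", seq=random_dna(rng, 8000, 0.42))]

    donor_gene = GeneModel(gene_id="donor_gh", scaffold_id="donor_genome",
                           start=3000, end=3000 + len(donor_cds), strand="+",
                           cds_seq=donor_cds)
    implant_lgt(assembly, donor_gene, recipe.implant_divergence, recipe, truth)
    make_decoy_conserved_gene(assembly, bacterial_db, animal_db, recipe, truth)

    # short contaminant scaffold: verbatim bacterial sequence
    contaminant = Scaffold(id="contaminant_scf",
                           seq=donor_genome.seq[100:100 + recipe.contaminant_length_bp])
    assembly.add_scaffold(contaminant)
    truth.contaminant_scaffold_ids.append(contaminant.id)
    return assembly, bacterial_db, animal_db, truth, recipe


# ---------------------------------------------------------------------------
# codon-level simulation under GY94
# ---------------------------------------------------------------------------

_DEFAULT_POS_FREQS = np.array([
    [0.20, 0.30, 0.25, 0.25],   # position 1: T C A G
    [0.25, 0.20, 0.30, 0.25],
    [0.30, 0.25, 0.20, 0.25],
])


def _evolve_codon(rng, Q, start_idx: int, time_left: float) -> int:
    """Exact CTMC simulation of one codon site for a given duration."""
    i = start_idx
    while True:
        rate = -Q[i, i]
        if rate <= 0:
            return i
        wait = rng.exponential(1.0 / rate)
        if wait >= time_left:
            return i
        time_left -= wait
        probs = Q[i].copy()
        probs[i] = 0.0
        probs /= probs.sum()
        i = int(rng.choice(len(probs), p=probs))


def simulate_codon_pair(omega: float, kappa: float, t: float, n_codons: int,
                        seed: int, pos_freqs: np.ndarray | None = None):
    """Two CDS diverged for total time t (t/2 per lineage) under GY94/F3x4;
    returns (CodonAlignmentPair, truth dict)."""
    rng = np.random.default_rng(seed)
    pf = _DEFAULT_POS_FREQS if pos_freqs is None else pos_freqs
    pi = f3x4_codon_freqs(pf)
    Q = gy94_rate_matrix(pi, kappa, omega)
    ancestors = rng.choice(len(pi), size=n_codons, p=pi)
    cols = []
    for anc in ancestors:
        ia = _evolve_codon(rng, Q, int(anc), t / 2.0)
        ib = _evolve_codon(rng, Q, int(anc), t / 2.0)
        cols.append((SENSE_CODONS[ia], SENSE_CODONS[ib]))
    pair = CodonAlignmentPair(id_a="sim_a", id_b="sim_b", columns=cols)
    return pair, {"omega": omega, "kappa": kappa, "t": t, "n_codons": n_codons}


# ---------------------------------------------------------------------------
# ortholog panels, species trees, placement fixtures
# ---------------------------------------------------------------------------

def _random_binary_tree(rng, labels: list[str], depth: float) -> TreeNode:
    """Random topology by repeated joining; branch lengths scaled to `depth`."""
    nodes = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 3 if len(labels) > 3 else len(nodes) > len(labels):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        bi = depth * rng.uniform(0.3, 1.0)
        bj = depth * rng.uniform(0.3, 1.0)
        new = TreeNode(children=[(nodes[i], bi), (nodes[j], bj)])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    root = TreeNode(children=[(n, depth * rng.uniform(0.3, 1.0)) for n in nodes])
    return root


def tree_distances(root: TreeNode) -> DistanceMatrix:
    """Additive path-length distances between the leaves of a tree."""
    dists: dict[str, dict[str, float]] = {}

    def walk(node):
        # returns {leaf: distance to this node}
        if not node.children:
            return {node.name: 0.0}
        below = []
        for child, blen in node.children:
            d = walk(child)
            below.append({k: v + blen for k, v in d.items()})
        for x in range(len(below)):
            for y in range(x + 1, len(below)):
                for la, da in below[x].items():
                    for lb, db in below[y].items():
                        dists.setdefault(la, {})[lb] = da + db
                        dists.setdefault(lb, {})[la] = da + db
        merged = {}
        for d in below:
            merged.update(d)
        return merged

    walk(root)
    labels = sorted(dists)
    n = len(labels)
    d = np.zeros((n, n))
    for i, la in enumerate(labels):
        for j, lb in enumerate(labels):
            if i != j:
                d[i, j] = dists[la][lb]
    return DistanceMatrix(labels=labels, d=d)


def random_additive_matrix(n_taxa: int, seed: int):
    """(DistanceMatrix, true bipartitions) from a random binary tree with
    strictly positive branch lengths."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    root = _random_binary_tree(rng, labels, depth=1.0)
    tree = PhyloTree(root=root)
    return tree_distances(root), tree.bipartitions()


def _evolve_protein_on_tree(rng, root: TreeNode, ancestral: str, rate: float):
    """{leaf: sequence} with Poisson(branch_length * rate * L) substitutions."""
    out = {}

    def walk(node, seq):
        if not node.children:
            out[node.name] = seq
            return
        for child, blen in node.children:
            n_subs = rng.poisson(blen * rate * len(seq))
            walk(child, mutate_protein(rng, seq, int(n_subs)))

    walk(root, ancestral)
    return out


def simulate_ortholog_panel(n_species: int = 2, tree_depth: float = 0.15,
                            n_genes: int = 30, gene_length: int = 150,
                            seed: int = 11, n_paralogs: int = 0,
                            shuffle_species: str | None = None):
    """Proteomes + gene-order assemblies for several species evolved along a
    random species tree, with recorded true ortholog pairs and tree.

    Optional paralog confounders (extra diverged copies in the last species)
    and an optional per-species gene-order shuffle for synteny negatives.
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1}" for i in range(n_species)]
    root = _random_binary_tree(rng, species, tree_depth)
    truth = GroundTruth(true_tree=PhyloTree(root=root).newick())
    proteomes = {sp: [] for sp in species}
    for g in range(n_genes):
        ancestral = "".join(AA20[int(x)] for x in rng.integers(0, 20, size=gene_length))
        leaf_seqs = _evolve_protein_on_tree(rng, root, ancestral, rate=1.0)
        for sp in species:
            proteomes[sp].append(ProteinRecord(id=f"{sp}_g{g + 1}",
                                               seq=leaf_seqs[sp], source_taxon=sp))
        for x in range(len(species) - 1):
            truth.true_ortholog_pairs.append(
                (f"{species[x]}_g{g + 1}", f"{species[x + 1]}_g{g + 1}"))
    for p in range(n_paralogs):
        sp = species[-1]
        src = proteomes[sp][int(rng.integers(n_genes))]
        proteomes[sp].append(ProteinRecord(
            id=f"{sp}_paralog{p + 1}",
            seq=mutate_protein(rng, src.seq, int(0.5 * gene_length)),
            source_taxon=sp))
    # gene order: shared layout, one scaffold per species
    assemblies = {}
    gene_span = 450
    spacing = 550
    for sp in species:
        order = list(range(n_genes))
        if sp == shuffle_species:
            rng.shuffle(order)
        length = n_genes * (gene_span + spacing) + spacing
        asm = Assembly()
        asm.add_scaffold(Scaffold(id=f"{sp}_scf1", seq=random_dna(rng, length, 0.4)))
        for pos, g in enumerate(order):
            start = spacing + pos * (gene_span + spacing)
            asm.add_gene(GeneModel(gene_id=f"{sp}_g{g + 1}", scaffold_id=f"{sp}_scf1",
                                   start=start, end=start + gene_span, strand="+"))
        assemblies[sp] = asm
    return proteomes, assemblies, truth


def write_acceptance_bundle(out_dir, seed: int = 7):
    """Write the full file-based study bundle for a pipeline run: synthetic
    genome + gene table, bacterial/animal panels, a partner-species ortholog
    CDS for the implant (evolved under the recipe's omega), an aligned
    placement panel with the implant grafted into the bacterial clade, and a
    ground-truth table.  Returns the config dict for ``run_pipeline``."""
    import os

    from .io import write_fasta, write_gene_table, write_tsv

    os.makedirs(out_dir, exist_ok=True)
    assembly, bacterial_db, animal_db, truth, recipe = make_acceptance_assembly(seed)
    implant = assembly.gene("lgt_implant")
    partner = Scaffold(id="partner_ortholog_cds",
                       seq=evolve_cds(implant.cds_seq, recipe.omega, recipe.kappa,
                                      recipe.t, seed=recipe.seed + 101))
    panel, labels, focal = grafted_hgt_panel(seed=recipe.seed + 202)
    panel = [ProteinRecord(id="lgt_implant" if r.id == focal else r.id, seq=r.seq,
                           kingdom_label=r.kingdom_label) for r in panel]
    labels = {("lgt_implant" if k == focal else k): v for k, v in labels.items()}

    paths = {k: os.path.join(out_dir, v) for k, v in {
        "genome": "genome.fna", "genes": "genes.tsv", "bacteria": "bacteria.fna",
        "animal": "animal.fna", "partner_cds": "partner_cds.fna",
        "panel_alignment": "panel_alignment.faa", "panel_labels": "panel_labels.tsv",
        "ground_truth": "ground_truth.tsv"}.items()}
    write_fasta(paths["genome"], list(assembly.scaffolds.values()))
    write_gene_table(paths["genes"], assembly, metadata=[f"seed={seed}"])
    write_fasta(paths["bacteria"], bacterial_db)
    write_fasta(paths["animal"], animal_db)
    write_fasta(paths["partner_cds"], [partner])
    write_fasta(paths["panel_alignment"], panel)
    write_tsv(paths["panel_labels"], ["id", "kingdom"],
              [[k, v] for k, v in labels.items() if v != "focal"],
              metadata=[f"seed={seed}"])
    rows = ([["implant", sid, f"{iv[0]}-{iv[1]}", donor]
             for sid, iv, donor in truth.implanted_regions]
            + [["decoy_gene", "-", "-", g] for g in truth.decoy_gene_ids]
            + [["contaminant", s, "-", "-"] for s in truth.contaminant_scaffold_ids])
    write_tsv(paths["ground_truth"], ["kind", "scaffold", "interval", "id"], rows,
              metadata=[f"seed={seed}"])
    config = {"genome": paths["genome"], "genes": paths["genes"],
              "bacteria": paths["bacteria"], "animal": paths["animal"],
              "partner_cds": paths["partner_cds"],
              "panel_alignment": paths["panel_alignment"],
              "panel_labels": paths["panel_labels"],
              "focal_panel_id": "lgt_implant", "seed": str(seed)}
    return config


def grafted_hgt_panel(seed: int, n_bacterial: int = 6, n_eukaryotic: int = 6,
                      length: int = 200, within: float = 0.08, between: float = 0.6):
    """Protein alignment of a bacterial clade, a eukaryotic clade, and a focal
    sequence grafted inside the bacterial clade (the synthetic transferred
    gene).  Returns (alignment records, kingdom label map, focal id)."""
    rng = np.random.default_rng(seed)
    ancestral = "".join(AA20[int(x)] for x in rng.integers(0, 20, size=length))
    bact_anc = mutate_protein(rng, ancestral, int(rng.poisson(between * length / 2)))
    euk_anc = mutate_protein(rng, ancestral, int(rng.poisson(between * length / 2)))
    records = []
    labels = {}
    for i in range(n_bacterial):
        seq = mutate_protein(rng, bact_anc, int(rng.poisson(within * length)))
        rid = f"bact{i + 1}"
        records.append(ProteinRecord(id=rid, seq=seq, kingdom_label="bacterial"))
        labels[rid] = "bacterial"
    for i in range(n_eukaryotic):
        seq = mutate_protein(rng, euk_anc, int(rng.poisson(within * length)))
        rid = f"euk{i + 1}"
        records.append(ProteinRecord(id=rid, seq=seq, kingdom_label="animal"))
        labels[rid] = "eukaryotic"
    focal_parent = records[0].seq  # sister to the first bacterial leaf
    focal_seq = mutate_protein(rng, focal_parent, int(rng.poisson(within * length / 2)))
    records.append(ProteinRecord(id="focal_lgt", seq=focal_seq, kingdom_label="focal"))
    labels["focal_lgt"] = "focal"
    return records, labels, "focal_lgt"
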