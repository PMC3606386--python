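# Methods

This note records the models implemented, the defaults chosen where the
underlying workflow left them open, and what the synthetic-data harness
does and does not establish.

## Local similarity search and its statistics

The search engine is a classical word-seeded local aligner:

1. **Seeding.** Exact 11-mer matches for DNA (both strands; minus-strand
   hits are reported against forward-query coordinates with strand `-`).
   For proteins, 3-mer neighborhood seeding: a database word seeds when its
   substitution score against the query word reaches 11 (BLOSUM62).
2. **Ungapped extension.** X-drop extension along the seed diagonal
   (drop-off 40 raw score units for DNA, 20 for protein). A per-diagonal
   high-water mark suppresses redundant seeds inside an already extended
   region.
3. **Gapped extension.** HSPs whose ungapped bitscore reaches 22 bits are
   re-aligned by banded affine-gap Smith–Waterman (band half-width 16)
   in a window around the ungapped HSP; the window grows (up to a 4 kb
   pad) while the optimum presses against its edge. Overlapping
   same-diagonal gapless HSPs, and HSPs fully contained in a better one,
   are merged keeping the higher score.

Scoring defaults are BLASTN-like for DNA (match +2, mismatch −3, gap open
5, extend 2) and BLOSUM62 with gap open 11 / extend 1 for protein. `N` and
`X` score as the worst-case mismatch. These follow common defaults because
the original screen used stock BLAST settings without naming parameters.

**E-values.** λ solves Σ pᵢpⱼ e^(λ sᵢⱼ) = 1 (Brent bracketing plus Newton
polish to |f(λ)| < 10⁻¹⁰); K uses the ungapped lattice convolution formula
(σ-series over k-fold convolutions of the score distribution, then
K = δλe^(−2σ)/(H(1−e^(−λδ)))). Background frequencies are uniform for DNA
and Robinson–Robinson for protein. Two documented approximations: gapped
alignments reuse the ungapped (λ, K), and the search space is raw m·n with
no effective-length correction. Both shift all E-values in the same
direction, so E-value *comparisons* — which are all the screen's decisions
use — are preserved; the acceptance suite additionally checks that the
resulting E-values are conservative (P(E ≤ e) ≤ 2e at e = 0.01, 0.1 over
500 random pairs).

## The differential-homology screen

Regions with bacterial E below the cutoff (default 10⁻⁵) are merged per
scaffold when closer than `hsp_merge_gap` = 1000 bp (the workflow never
defines "region"; 1 kb is gene-scale and is recorded in output metadata).
The *extracted region sequence* — not the whole scaffold — is then searched
against the animal panel, and the candidate is excluded iff the animal
E-value is strictly smaller than the bacterial one; exact ties retain.
Finally candidates on scaffolds strictly shorter than 5000 bp are excluded.
Filters always run in this order and each appends to the candidate's audit
trail; a candidate keeps the status of the first filter that rejected it.
Exclusions are reported alongside retained candidates rather than dropped,
so every decision can be inspected.

## Orthology, identity Z-score, microsynteny

RBH orthology uses the engine's best-hit rule (minimum E, then higher
score, then lexicographic subject id); a pair is emitted only when each
side is the other's best hit, so each gene appears in at most one pair.
Pair identity is the percent identity over the best HSP's aligned columns
(the choice of identity definition was open; BLAST-local identity is used
and recorded). The identity Z-score is (focal − mean)/sd over the
background pair identities, focal pair excluded, sd with the n−1
denominator (the estimator was unstated; n−1 is the conventional sample
choice), and the background size is reported alongside the mean so the
average is auditable.

Microsynteny takes the `window` (default 4) genes on each side of the
focal gene in each assembly, computes the fraction of flank genes whose
1:1 ortholog lands in the partner flank (denominator 2·window, clipped at
scaffold ends to the available gene count), and calls order conserved when
the shared orthologs appear in the same relative order, whole-window
reversal allowed (assemblies may differ in scaffold orientation).
Neighbor distance is the end-to-start gap to the nearest other gene
(0 when overlapping; ties broken toward the downstream gene) and feeds the
bridging interval used for chimera-excluding PCR design.

## dN/dS

**Codon alignment.** CDS pairs are validated (length ≡ 0 mod 3, trailing
stop stripped, internal stops rejected with position), translated, globally
aligned at the protein level (Needleman–Wunsch, BLOSUM62, affine gaps) and
back-translated, so gaps come in whole codons. Gap columns are dropped
pairwise before estimation.

**NG86.** Synonymous site fractions per codon count the 9 single-base
changes, with changes to stop codons counted as nonsynonymous; sites are
averaged over the two sequences. Multi-difference codons average the
synonymous/nonsynonymous steps over all minimal substitution pathways,
discarding pathways through stops (if every pathway is blocked, all steps
count as nonsynonymous — a rare, documented fallback). Proportions are
corrected with Jukes–Cantor d = −¾ ln(1 − 4p/3); p ≥ ¾ raises a
saturation error rather than returning a number.

**Maximum likelihood.** The 61-state codon generator has
q
ᵢⱼ = 0 for multi-base changes and πⱼ·κ^[transition]·ω^[nonsynonymous]
otherwise, with π from F3x4 (positional nucleotide frequencies of the
pair, floored at 10⁻⁴ so no sense codon has zero frequency). Q is scaled
to unit substitution flux, so t is expected substitutions per codon.
Reversibility collapses the two-branch pairwise likelihood to
Σ columns ln(πᵢ P(t)ᵢⱼ); P(t) comes from eigendecomposition of the
π-symmetrized generator. (ln t, ln κ, ln ω) is maximized by Nelder–Mead
from 3 fixed starts (tolerance 10⁻⁸ in log-likelihood); identical
sequences return the t = 0 boundary with a warning instead of an error,
and fewer than 10 comparable codons are rejected. dN and dS derive from t
and the synonymous/nonsynonymous flux proportions at the fitted and at
ω = 1 parameters, which makes the derived dN/dS equal the fitted ω
exactly. The acceptance suite checks recovery of ω ∈ {0.062, 0.5, 1.0}
within 15% relative bias at 2000 codons × 20 replicates; observed bias in
development runs was ≤ 3%.

## Placement

Distances are Poisson-corrected mismatch fractions, −ln(1−p), with
pairwise deletion of gap columns so ragged domain trims are tolerated.
Neighbor joining follows Saitou–Nei with the Q criterion; ties break by
the lexicographically smallest pair of cluster representative labels, and
negative branch lengths are clamped to zero with the deficit moved to the
sister branch. Bootstrap resamples alignment columns with replacement and
tallies each full-tree bipartition across replicate trees. The origin call
examines the smallest bipartition with support ≥ 0.8 (mirroring the >80%
corroboration threshold) that groups the focal leaf with at least one
other; if every such companion is bacterial the call is `bacterial_nested`,
all-eukaryotic gives `eukaryotic_nested`, anything else — including no
supported grouping — is `ambiguous`. Distance-based placement was chosen
over Bayesian MCMC deliberately: the decision-relevant output is clade
nesting, which this preserves at a cost of seconds, deterministically.

## Primer design and in-silico PCR

Conserved blocks are maximal gap-free alignment windows whose per-column
minimal covering IUPAC codes keep the window degeneracy within budget
(default 512) at length ≥ the primer floor; consensus is unweighted
because the original primers were designed from a two-sequence alignment.
Reverse primers are IUPAC reverse complements. The PCR scan is
degeneracy-aware (a template base matches a code containing it), requires
the 3′-terminal 3 bases to match exactly, allows 1 mismatch elsewhere, and
reports all forward-before-reverse pairings up to 5 kb — PCR-realistic
defaults, chosen because none were stated. For degeneracy ≤ 256 the scan
is verified against brute-force expansion of every primer variant.

## Synthetic data: what it does and does not show

Generators are pure functions of a `SimulationRecipe` (seeded numpy
generators keyed by a stable stream hash), so outputs are byte-identical
across runs. The standard study conditions: 3 scaffolds × 50 kb at GC
0.35, 10 intronless 300-codon genes per scaffold, a ~2 kb donor gene at
GC 0.40 implanted at 20% divergence, a decoy host gene copied into the
bacterial panel at 25% and the animal panel at 5% divergence, and a 3 kb
verbatim-bacterial contaminant scaffold. Codon pairs default to
ω = 0.062, κ = 2, t = 0.8 — the purifying-selection regime of the
motivating transfer. DNA fixtures mutate by uniform substitution without
indels (ground-truth intervals stay exact; E-value decisions do not need
indels); implant substitutions that would create an internal stop are
redrawn so the implanted gene remains a translatable CDS, as a genuine
transferred gene would be.

What passing tests show: the screen's decision logic, the estimators and
their statistics behave correctly on data satisfying their model
assumptions, with known ground truth. What they do not show: robustness to
repeats, assembly gaps, sequencing error, indel-rich divergence,
composition bias, or horizontal transfer from donors absent from the
bacterial panel — real-data screens should treat the audit trail, not the
binary status, as the primary output. The real-sequence reproduction test
(peptide lengths 1076/923 aa, 58.5% identity, dN/dS 0.062/0.107/0.108)
runs only when the user supplies the downloadable gene sets; it is not
replaced by a synthetic stand-in.

## Numerical and problem-size choices

The test suite and the acceptance script size their simulations to desk
scale as the package's own study design: 10 replicates × 1000 codons per ω
in the script (20 × 2000 in the acceptance suite), 500 random pairs for
calibration, 50 additive matrices, 20 placement panels at 100 bootstrap
replicates. Coordinates are 0-based half-open internally and 1-based
inclusive in every human-readable report. All thresholds appearing in a
report's provenance are the values actually used in that run.
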