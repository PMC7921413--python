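# Methods

## Model

A sample's clonal history is a rooted mutation tree: nodes are somatic
variants, the root is the unmutated state, and the genotype of a node is the
set of variants on its root path. Each cell belongs to exactly one node; its
model genotype `M_cg ∈ {0,1}` over variants `g` is determined by that
attachment. Observed calls `N_cg ∈ {0,1,NA}` come from the ternary call
matrix. The likelihood of one (cell, variant) entry is

- `α_g` when `M=1, N=0` — allelic dropout of a truly mutant site,
- `β` when `M=0, N=1` — false-positive mutant call,
- `1` when `N = NA` — an uncovered site carries no information,
- `(1−α_g)(1−β)` otherwise — both concordant cases share one factor.

No renormalization is applied: the four cases do not sum to one, which is a
deliberate property of this model family and is kept exactly. One
consequence documented here because it matters for the robustness procedure:
when `α_g > (1−α_g)(1−β)` (at `β = 0.03`, `α_g ≳ 0.492`), a reference
observation is *better* explained as mutant-with-dropout than as reference,
so placing variant `g` ancestral to every cell increases the likelihood
regardless of the data. Dropout rates that large are outside the model's
useful regime; perturbation draws that cross the threshold flip the inferred
tree in a data-independent way (see Robustness below).

Cells attach to their maximum-likelihood node (ties: smaller genotype, then
lexicographic label), and the tree score is the sum of per-cell maxima. A
maximum over attachments — rather than a sum — matches the assumption that
each cell has a single true genotype.

## Parameters

| parameter | default | meaning |
|---|---|---|
| min_reads / min_cells | 5 / 20 | site usable when ≥5 reads in ≥20 cells |
| min_cell_vaf | 0.10 | minor-allele fraction calling a cell mutant in the cohort filter |
| min_fraction_in_patient | 0.01 | minimum fraction of an individual's cells mutant |
| max_cells_other | 10 | maximum mutant cells tolerated in any other individual |
| min_covered_fraction | 0.20 | variant kept when covered in ≥20% of cells |
| vaf_cutoff | 0.05 | call-matrix mutant threshold (strictly above) |
| α | 0.10 | allelic dropout rate; per-variant when estimated |
| β | 0.03 | false-positive rate, global |
| concentration | 10 | Beta concentration of the robustness perturbation |
| n_runs | 80 | Latin-hypercube robustness runs |
| swap threshold | 1.0 | per-cell log-likelihood cost below which adjacent nodes merge |
| min_confidence | 0.8 | posterior required to keep a cell in quantitative analyses |
| min_mean_reads | 20 | expression filter for de novo candidate sites (strictly above) |

Boundary conventions: "at least" thresholds are inclusive (a VAF of exactly
0.10 calls a cell mutant in the cohort filter; coverage in exactly 20% of
cells keeps a variant), while the 5% call cutoff and the 20-reads expression
filter are strict ("above 5%", "mean > 20"). The VAF denominator is total
coverage over all five alleles (A/C/G/T/deletion), not ref+alt. The 1%-of-
cells denominator is all cells of the individual, not only covered cells —
the conservative reading. Blacklist identity is (site, alt), not site alone.
Missing means strictly zero coverage; a `min_coverage_for_call` knob exists
for stricter calling but defaults to 1 read.

## Search

For k ≤ 7 variants every rooted mutation tree is enumerated via Prüfer
sequences — (k+1)^(k−1) topologies — and scored; the global optimum is
returned with deterministic tie-breaking (canonical parent-map order). For
larger k, steepest-ascent hill-climbing over subtree-regraft moves
(reassigning a node's parent to any non-descendant) runs from seeded random
restarts (default 20); the result is deterministic given the seed and never
scores below its initialization. The trees this package targets have ≤ ~8
variants, so the exhaustive path is the usual one.

## Dropout estimation and robustness

Per-variant dropout `α_g` is estimated as the fraction of cells with a
missing call at `g`, clamped to (0.01, 0.99). The robustness procedure
draws, for each variant and run, `α` from Beta(m·c, (1−m)·c) — mean `m`,
concentration `c = 10` — with Latin-hypercube stratification: the unit
interval is cut into `n_runs` equal bins, each visited exactly once per
variant in permuted order, then mapped through the Beta quantile function.
The tree is re-inferred per draw and compared at *clone level*: topologies
count as equal when they induce the same clone partition and the same
parent relation between clones, since node order within a clone is by
construction unsupported by the data.

Stratification guarantees one draw per variant from the top 1/`n_runs`
quantile bin. At mean 0.10 that bin reaches α ≈ 0.39–1, and with
probability ≈ 0.18 per variant the draw crosses the α ≳ 0.492 degeneracy
described above, flipping that run's tree irrespective of the number of
cells. On the bundled three-clone fixture this produces 78–80 agreeing runs
out of 80 depending on the master seed — near-unanimity, with the modal
topology always the planted one; exact unanimity in every seed would
require dropout means safely below the degeneracy's reach (roughly ≤ 0.05
at these settings).

## Clone grouping and assignment

The tree is split into maximal linear branches (branch points and leaves
delimit). Within a branch, the cost of exchanging two nodes is
`(logL(original) − logL(swapped)) / n_cells` with cells re-attached
optimally under the swapped topology — non-negative when the original is
the ML tree, and exactly zero for variants with identical call columns.
Nodes merge greedily root-to-leaf while the average pairwise cost within
the growing clone stays below 1 per cell. The threshold is an
interpretability cutoff, not a test: at α = 0.10, β = 0.03 a discordant
cell costs ≈ 2.3 log units, so a split requires roughly ≥ 43% of cells to
distinguish the order.

Assignment evaluates each cell's likelihood at every clone genotype (a
wildtype clone is always included) under a uniform prior; the posterior row
is summarized by its argmax probability (the 0.8 filter) and by the KL
information `Σ_k p_k log2(p_k |C|) ∈ [0, log2 |C|]` bits. The KL sum is
taken over clones within a cell — the reading under which "bits of
information" is a per-cell confidence; a cohort-level summary is simply the
per-cell column aggregated.

## De novo scan

Per-cell alternative read counts at a candidate site are beta-binomial with
mean `μ` and overdispersion `ρ` (shapes `μ(1−ρ)/ρ`, `(1−μ)(1−ρ)/ρ`; `ρ→0`
is binomial). H0 fits one (μ, ρ) over all confidently assigned cells
(k = 2); H1 fits per-clone μ with shared ρ (k = |C|+1). Fitting is bounded
L-BFGS-B from a fixed multistart grid (μ ∈ {0.01, 0.1, 0.5} × ρ ∈
{0.01, 0.1}) plus the empirical means, and the H1 optimization additionally
starts from the H0 optimum so the nesting inequality logL(H1) ≥ logL(H0)
holds numerically. Models are compared by AIC only; no p-value is derived,
and sites are ranked by `delta_aic`. Sharing ρ across clones keeps the
comparison about means; a per-clone-ρ variant would add |C|−1 parameters
and is not the default.

## Synthetic data

The generator plants a mutation tree, assigns cells to attachment nodes by
fixed proportions, and emits allele count tables: per (cell, site) coverage
is negative-binomial (default mean 50, dispersion 2 — overdispersed like
expression data), zeroed with the per-variant dropout probability (the NB
draw itself is floored at one read so dropout is the only source of
missingness, making the missing fraction converge exactly to the dropout
rate); alternative reads are binomial at the cell's true VAF — mutant_vaf
(default 0.9, a high-heteroplasmy variant) for carriers, error_vaf (default
0.005) otherwise, with error reads spread uniformly over the three
non-reference bases. Editing-like sites are planted at identical positions
and level (default VAF 0.5) in every individual; somatic variants occupy
individual-private positions. An optional mode ties dropout to coverage
mean, mimicking expression-dependent dropout.

What the generator does *not* emulate: amplification chimeras, strand bias,
UMI structure, doublets, contamination, site-specific error spectra, and
copy-number change. Passing tests therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every artefact
of real libraries.

Fixtures: `threeclones` (1 individual, 200 cells, founder → two branches,
one branch carrying two variants with no intermediate cells — 3 clones from
4 variants); `cohort4` (4 individuals × 120 cells, private 2-variant chains
plus 3 shared editing sites); `h0site`/`h1site` (single-site count draws
for scan calibration: homogeneous VAF 0.02 vs one clone at VAF 0.45 among
100 cells at coverage ~30). Problem sizes were chosen so the full test
suite and the acceptance script run in minutes on one core: 200 cells and
4 variants keep exhaustive tree enumeration (125 topologies) instantaneous
while leaving each clone tens of cells of support.

## Numerical choices and degenerate inputs

- Likelihood work is vectorized as `base + Δ·Gᵀ` (per-cell log-factors for
  the all-reference genotype plus per-variant flip increments), so missing
  entries contribute exactly 0 by construction.
- Ties in attachment go to the node nearest the root, then lexicographic;
  ties in topology score to the canonical sorted parent map — all results
  are exactly reproducible.
- A variant missing in every cell estimates α at the 0.99 clamp and logs a
  warning (it should have been filtered); α estimates are clamped away from
  {0,1} to keep logs finite.
- Beta draws for robustness are clipped to [1e−6, 1−1e−6].
- Posteriors are computed via log-sum-exp; a posterior off normal by >1e−6
  raises rather than silently renormalizing.
- Empty candidate lists, all-missing cells (uniform posterior, unassigned)
  and single-individual cohorts (empty blacklist, warning) are handled
  explicitly.

## Known limitations

- The unnormalized likelihood's large-α degeneracy (above) bounds the
  useful dropout range; the robustness report should be read together with
  the drawn α values.
- Hill-climbing is a local search; for k > 7 global optimality is not
  guaranteed (restarts mitigate).
- No doublet, mutation-loss or copy-number modelling; deletions are
  genotyped as an allele but insertions are not counted.
- The de novo scan assumes clone assignments are correct and conditions on
  them; uncertainty in assignment does not propagate into `delta_aic`.
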