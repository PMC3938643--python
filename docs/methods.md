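# Methods

## The gene-content model

A lineage's elongation-factor repertoire is a subset of
{eEF1A, eEF1Bα, EFL}, encoded as a 3-bit state. Translation requires a
functional delivery system, so a state is **viable** iff it contains EFL, or
both eEF1A and eEF1Bα; 5 of the 8 subsets are viable. Evolution is a
continuous-time Markov chain on the viable states:

* each gene carried is lost at rate λ (`loss_rate`, optionally per-gene),
* EFL — and only EFL — is gained by horizontal transfer at rate *h*
  (`hgt_rate`) while absent,
* there is **no** gain channel for eEF1A or eEF1Bα. This encodes the model
  assumption that re-acquiring a lost partner before its counterpart
  diverges beyond functional interaction is effectively impossible; it is an
  assumption, not an observed fact.

Rates are per unit branch length — the tree defines the clock; no absolute
time unit is implied, and the defaults (λ = 0.1, h = 0) are placeholders
that carry no empirical content.

**Lethality as rejection.** By default loss events whose target state is
inviable simply do not occur (`lethal_policy="reject"`): purifying selection
removes such mutations before fixation, and every observed lineage is one
that never passed through a lethal state. The embedded generator therefore
has zero flux into inviable states, rows summing to zero over the 5 viable
states. An `extinct` policy that lets the event occur and kills the lineage
is available for exploration; it is excluded from the matrix machinery
because the killed process is not a Markov chain on the viable states.

**Two-step divergence.** Optionally each gene decays through an intermediate
DIVERGENT level (intact → divergent at rate `divergence_rate`, divergent →
absent at `loss_rate`), with only intact copies counting toward viability.
This reproduces survey tables in which degrading sequences are still
detectable. The matrix, simulation and likelihood machinery all operate on
the expanded viable space in this mode; published-style analyses use the
one-step model.

**The ratchet.** From the ancestral state {eEF1A, eEF1Bα}, the only
permitted move is +EFL (losing either gene alone is lethal). Once EFL is
present, loss of eEF1A or eEF1Bα is permitted and — having no gain channel —
irreversible: the pawl. With h = 0 the process is a pure lineage-sorting
mechanism degrading {all three} into EFL-only or eEF1A+eEF1Bα tips; with
h > 0 it is processive, re-arming in eEF1A+eEF1Bα lineages and enriching
EFL-containing tips (verified as a Monte-Carlo monotonicity check).

## Simulation, master equation, likelihood

Simulation is exact Gillespie sampling along each branch: exponential
waiting times in the current state's total outgoing rate, children
inheriting parental end states. Each branch draws from an independent RNG
stream keyed by (seed, CRC32 of the clade's sorted tip labels), so
realizations are reproducible and unaffected by edits elsewhere in the tree.
Event logs record (branch, absolute time, kind, gene, from-state, to-state);
replaying a log from the root reproduces the tip states exactly (tested).

`propagate` solves the master equation dP/dt = PQ with SciPy's
scaling-and-squaring matrix exponential; output distributions sum to 1
within 1e-10. `tip_likelihood` is Felsenstein pruning with one matrix
exponential per distinct branch length, per-node rescaling to avoid
underflow, and the root fixed at the model's root state (default: all three
genes, the inferred ancestral condition). Partially observed tips (per-gene
present/divergent/absent/unknown tokens) are summed over compatible states;
a `divergent_as` switch controls whether divergent observations count as
present or absent in the one-step model. Pruning is verified against
brute-force marginalization over all internal-node states on every ≤ 4-tip
topology shape.

`fit_rates` maximizes the pruning likelihood over (λ, h) with a log-spaced
grid (default 6×6 over [1e-3, 10]²) followed by Nelder-Mead refinement in
log-parameter space; the procedure is deterministic. A flat surface (e.g.
all-unknown observations) returns a degenerate-fit warning with the grid.

**Rate-recovery study design.** The recovery benchmark simulates at
(λ = 0.2, h = 0.5) on 200 tips arranged as **20 independent 10-tip Yule
clades of height 5**, fitting jointly across clades. Two deliberate choices:
tree height 5 makes λ·height = 1 expected loss per gene per root-to-tip
path, the natural scale at which both loss and regain events occur often
enough to be informative; and independent clades are essential because a
single tree is a single draw of the deep gain/loss history — on one 200-tip
tree the HGT rate is weakly identified (whole-tree outcomes such as "no
eEF1A+eEF1Bα tips survive" swing ĥ by orders of magnitude), whereas
replicate clades average over that history. Success is both estimates
within a factor of 2 of truth; the suite requires ≥ 90 % of 20 replicate
fits to succeed.

## Consensus and site classification

Per family, each column's conservation fraction uses **all family rows as
denominator, gaps included** — a column that is half gaps can never reach a
70 % residue consensus; this matches the gap-dominated consensus rendering
around family-specific insertions. `X` counts toward the denominator but
can never be the consensus letter. Tiers: uppercase when the top residue's
fraction ≥ `threshold_high` (default 0.70), lowercase when the plurality
residue reaches `threshold_low` (default 0.50) but not the high tier, `.`
otherwise, `-` when the gap fraction ≥ `threshold_high`. Plurality ties
break alphabetically, making the call deterministic; the lowercase tier is
a declared convention of this package (published consensus strings mix
cases without defining them), so lowercase/`.` calls may differ from other
tools at the same threshold.

Comparing two profiles, each column gets exactly one category:
INDEL when exactly one profile is `-`; STRONG_DIFFERENTIAL when both are
uppercase and different; IDENTICALLY_CONSERVED when both uppercase and
equal; CONSERVED_A_ONLY / CONSERVED_B_ONLY when one side is uppercase and
the other neither uppercase nor gap; else UNCONSERVED. Strongly
differential pairs are additionally flagged when the residues cross a fixed
7-group chemical partition — {AVLIMC} {FWYH} {STNQ} {KR} {DE} {G} {P} —
stated explicitly because "chemically different" has no universal
definition; glycine and proline sit alone for their backbone behaviour.

Indel runs are maximal same-direction stretches of INDEL columns, flagged
conserved when ≥ 50 % of the run carries a consensus letter in the non-gap
family. Coordinates are 1-based inclusive in all user-facing output
(half-open internally). `map_column` converts an alignment column to a
residue position by prefix-counting non-gaps; `cterm_extension` averages,
over family-A sequences, the residues beyond the last non-gap column of the
family-B consensus.

## The exact association test

Fisher's exact test is implemented directly from the hypergeometric mass
function rather than called from a statistics library, so that independent
verification by enumeration is meaningful: two-sided p is the sum of point
probabilities, over all tables with the observed margins, not exceeding the
observed table's (relative tie tolerance 1e-12); masses are computed in log
space, keeping tables with n > 170 finite. The odds ratio is ad/bc with ∞
when bc = 0 and a, d > 0. Any zero margin yields p = 1 with a degenerate
flag. The implementation is checked against exact-rational enumeration for
every table with n ≤ 30 and against an independent library routine.

The survey analysis reports all three tabulations (EFL vs eEF1A, vs eEF1Bα,
vs both-present) under both divergent conventions — six results — because
the published claim does not fix the tabulation; EFL-vs-both is treated as
primary. Taxa are treated as independent observations, as in the original
analysis; `collapse_by_lineage` offers a majority-state pseudo-taxon
reduction for readers worried about phylogenetic non-independence.

The bundled survey table is a **synthetic reconstruction**: the original
supplementary table is not redistributed here, so the file encodes every
exceptional taxon documented in prose (five eEF1A/EFL co-maintainers
lacking eEF1Bα, seven species with degrading eEF1A beside EFL, two with
degrading eEF1Bα, one divergent-EFL case, the EFL-only choanoflagellate
used as an experimental query) and fills the bulk mutually-exclusive
pattern with placeholder taxa at proportions consistent with the published
dataset dimensions (~70 EFL-carrying, ~70 eEF1A+eEF1Bα taxa). Association
conclusions are robust to the placeholder counts at these magnitudes.

## Synthetic data

`make_alignment` plants a category per column: conserved positions are
emitted at frequency 1 (before noise), unconserved columns cycle a shuffled
residue alphabet so no residue can exceed ⌈n/20⌉/n ≈ 5–10 % — far from both
thresholds, so noiseless recovery is exact by construction and no
margin-of-threshold columns occur. Insertions are gap blocks in the
non-carrier family; the C-terminal tail is a trailing family-A-only block.
Noise substitutes each residue cell independently with probability ε by a
uniform draw over the other 19 residues — the simplest model that stresses
the threshold logic. **Not emulated:** phylogenetic autocorrelation within
families, indel polymorphism within a family, alignment error, or realistic
substitution matrices; closed-loop recovery results therefore bound
threshold-logic correctness, not performance on real alignments.

`make_table` draws tip states from a ratchet history on a Yule tree
(re-labelling losses in the most recent `divergent_fraction` of tree height
as DIVERGENT, mimicking ongoing decay) or from independent Bernoulli coins
(the null for calibration). `make_tree` grows a pure-birth tree at unit
rate with an exponential hold after the last split (so all pendant edges
are positive) and rescales to a chosen height; trees are binary, ultrametric
and fully seeded.

## Problem sizes and numerical choices

The test suite and acceptance script use: exhaustive exact-test enumeration
to n = 30; 300-column, 20+20-sequence alignments (noise 0 and 0.05); 10⁴
8-tip histories for irreversibility; 10⁵ single-branch replicates × 5
random parameter draws against the master equation (3 binomial SE per
state); 20 replicate recovery fits of the 20×10-clade design; and 10⁴
40-taxon null tables for type-I calibration (the exact test is
conservative, empirically ~3 % at nominal 5 %). Tolerances: pruning vs
brute force 1e-10 relative; probability conservation 1e-10; exact-test ties
1e-12 relative.

## Known limitations

* Rates are identifiable only relative to branch lengths; nothing here
  dates events or estimates absolute HGT frequency.
* The ratchet model ignores selective differences between EFL- and
  eEF1A-driven translation, multifunctional ("moonlighting") constraints
  that may retain eEF1A, and any GEF hijacking — its point is that drift
  plus a viability constraint suffices for the observed pattern.
* The association test treats taxa as exchangeable; the lineage-collapse
  option is a coarse, not a model-based, correction.
* Consensus case (upper vs lower) at tier boundaries is convention-bound;
  only the letter identity is comparable across tools.
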