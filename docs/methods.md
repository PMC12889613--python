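# Methods

## Model

A Potts (pairwise maximum-entropy) model over an alignment of kinase
catalytic domains assigns each sequence S of length L the statistical energy
H(S) = Σ_{i<j} J_ij(S_i, S_j) + Σ_i h_i(S_i), with P(S) ∝ exp(−H(S)).  Lower
energy means more probable.  The partition function is never computed; for a
kinome-scale model (L = 259, q = 21) it is intractable, and every quantity
the package reports depends only on energy differences.

The alphabet has 21 states: the 20 amino acids plus the alignment gap,
which is an ordinary Potts state so that gapped columns thread like any
other.  In A2M input, lowercase letters and `.` are insertions and are
dropped; `-` is a gap in a match column and is kept.

### Gauge

The Potts parameterization is redundant: per-pair row/column shifts of J can
be absorbed into h without changing any probability.  The canonical form
here is the **zero-sum gauge** (couplings sum to zero over either state
index), which makes per-pair coupling magnitudes comparable.  The gauge
transform also tracks a scalar energy offset so absolute energies — not just
differences — are preserved to rounding (checked at 1e−9).

### Threading score

ΔT(S) = −Σ_{i<j} J_ij(S_i, S_j) · Δc_ij, with Δc = c_out − c_in the
contact-frequency difference between the classical DFG-out and active DFG-in
ensembles of the kinase's class.  ΔT is a *sequence-specific reorganization
penalty*: positive contributions come from couplings favored by S on
contacts lost during reorganization.  ΔT is not gauge-invariant in general,
so it is always evaluated in the zero-sum gauge; `threading_score` fixes the
gauge internally if needed, which is why raw and gauge-fixed models give
identical scores.

Classification defaults follow the blind-test convention: ΔT > 6 predicts
selective, ΔT < 2 promiscuous, in between indeterminate.  A large gatekeeper
residue sterically restricts the type II pocket; this is folded in as a
configurable additive offset (default +1.0 score units) on the adjusted
score, so a large gatekeeper can veto a borderline promiscuous call.  The
functional form of the gatekeeper signal is a design choice of this package
(no canonical form exists); setting the offset to 0 gives the pure-ΔT
ablation.  Conserved activation-loop anchor residues are sometimes used as a
further selectivity cue; the package carries no scoring weight for them —
annotations of that kind can be joined onto the output table by the caller.

## Contact ensembles

Binary contacts: residues i, j are in contact when their minimum heavy-atom
distance is strictly below 6 Å (configurable).  The atom set is a design
choice recorded in output metadata; Cβ–Cβ variants can be configured via the
cutoff.  Pairs closer than 3 alignment columns are excluded by default
(`min_separation`): backbone-adjacent contacts are conformation-independent
and only add noise to Δc.

Frequency maps are 1/u-weighted means, u = occurrences of the same kinase
(by gene-level id) in the ensemble pair under consideration.  By default u
is counted over the union of the active and inactive ensembles
(`u_mode="union"`); counting within each ensemble separately is a switch.
Unresolved positions are excluded from both numerator and denominator of the
affected entries (per-entry effective weights) rather than treated as
non-contacts, so flexible loops do not bias frequencies toward zero; pairs
never resolved anywhere are NaN in the frequency map and contribute Δc = 0
(no evidence of change), flagged in the difference map's `observed` mask.

Per-class refinement: the pipeline carries named difference maps and a
kinase→class assignment table, so families whose inactive state differs
(e.g. kinases able to bind type II inhibitors in a minimally perturbed,
extended-loop conformation) can be threaded against a map built from their
own ensembles.

## Panel statistics

* **Hit rate**: number of inhibitors with measured Kd strictly below the
  cutoff (default 10000 nM).  A Kd equal to the censor value (10000 nM)
  means "no binding detected at the assay ceiling" and never counts, at any
  cutoff.  Never-assayed pairs are NaN and excluded from denominators —
  missing is distinct from censored.
* **Selectivity labels**: hit rate ≤ threshold (default 10; 5/15 variants)
  → selective, else promiscuous.
* **Subset randomization**: draw k inhibitors (default 16) uniformly without
  replacement, count kinases under each hit-rate ceiling, repeat (default
  10000 iterations); reports mean/sd and the full-pool reference counts.
* **ROC/AUC**: positive class = selective, higher score predicts selective;
  trapezoidal AUC (equal to the tie-corrected Mann–Whitney statistic, ties
  counted 1/2 — cross-checked against a brute-force oracle in the tests);
  best cutoff = Youden-maximal point.
* **Binning**: kinases sorted by score descending, chunked into consecutive
  groups (25 for hit-rate means, 35 for affinity fractions); the final
  partial group is kept and flagged.
* **Affinity classes**: strong Kd < 100 nM, average 100 ≤ Kd ≤ 5000 nM,
  weak Kd > 5000 nM.  The strict published boundaries leave Kd = 100 nM
  unassigned; it is placed in the average class (documented closure).
* **Predictor evaluation**: ground truth is binary binding at a cutoff
  (default 100 nM; censored pairs are never binders); predictions rank pairs
  by predicted Kd.  AUPR integrates the threshold-ordered PR points and
  replaces the optimistic (recall 0, precision 1) anchor with a flat
  extension, so a constant predictor scores exactly the prevalence.
  Per-regime true-positive rates count a pair correct when the predicted Kd
  falls in the same (lo, hi] affinity regime as the measured one; the
  default regimes (≤10, ≤100, 100–5000, >5000 nM) are deliberately partially
  nested, matching how such tables are reported.

## Pseudolikelihood inference

`fit_pseudolikelihood` maximizes the per-site conditional log-likelihood
with L2 penalties (defaults λ_h = 0.01, λ_J = 0.005 per parameter) by L-BFGS
with an analytic gradient, then returns the model in zero-sum gauge.  It is
deterministic given inputs.  Degenerate alignments (all-identical sequences,
single-state columns) warn and fall back to heavy regularization instead of
crashing.  This fitter exists for recovery experiments at desk scale (L of
order tens); it does not attempt to reproduce any published kinome model,
whose inference and reweighting choices are outside this package's scope.

Recovery behavior (checked in the acceptance suite): sampling from a known
L = 5, q = 3 model and refitting gives true-vs-inferred coupling
correlations that rise with sample size (n ∈ {1000, 10000, 50000}) and
exceed 0.9 at the largest n.

## Gibbs sampling

`sample_sequences` runs n independent chains in parallel, each initialized
uniformly at random and advanced `burn_in + thin` full-site sweeps; the
final state of each chain is returned.  Parallel chains vectorize across the
sample dimension and give exchangeable draws; `thin` adds decorrelation
sweeps beyond the burn-in.  Sampled marginals are validated against exact
enumeration for small models (within Monte-Carlo standard errors).  One
seeded generator per call; fixed seed → bit-identical output.

## Synthetic worlds

`make_world` generates the complete study structure with known ground truth:

1. a sparse random Potts model (default L = 40, q = 8, 15% of pairs coupled,
   coupling/field scales 0.6/0.5), zero-sum fixed;
2. kinase sequences Gibbs-sampled from it (default 348, the panel size of
   the study setting it emulates);
3. two toy structural ensembles whose contact difference is +1 exactly on a
   controlled set of vertex-disjoint "flip" pairs (default min(10, L/4))
   drawn from the coupled pairs — residues are single atoms 20 Å apart on a
   line, the inactive state adds one pocket atom per flip pair 4 Å from its
   partner, and sub-0.4 Å jitter never crosses a contact margin;
4. per-kinase ΔG_reorg = reorg_scale × ΔT + N(0, noise_sd), defaults
   0.8 kcal/mol per score unit and 0.5 kcal/mol;
5. per-pair ΔG_bind = per-inhibitor mean (uniform on −10.5…−3.0 kcal/mol,
   the promiscuity spread) + N(0, 1.0) kcal/mol;
6. Kd[nM] = 1e9 · exp(ΔG_exp / RT), RT = 0.593 kcal/mol (298 K, 1 M standard
   state), censored at 10000 nM; the first 16 of 50 inhibitors carry the
   `davis` dataset tag.

The binding spread was set so the 50-inhibitor panel's fraction of kinases
under small hit-rate ceilings is of order tens of percent and a 16-inhibitor
subset overestimates selectivity, the qualitative shape of published panel
summaries.  Gatekeeper flags are random annotations carrying no generative
signal: ΔG_reorg is strictly reorg_scale × ΔT + noise, so the noiseless world
has Spearman(ΔT, ΔG_reorg) = 1 exactly.

What the generator does *not* emulate: real kinase geometry (the toy chains
exist only to exercise the contact machinery end-to-end), phylogenetic family
structure, assay error models, correlated inhibitor chemistry, or the actual
kinome Potts model.  Passing tests on these worlds demonstrate that the
machinery is correct and that the inference chain recovers planted signal;
they do not certify performance on real panels.

## Problem sizes and numerics

End-to-end checks use 200-kinase, 50-inhibitor worlds over a handful of
seeds, and recovery checks use L = 5, q = 3 with up to 50000 samples — sizes
at which every oracle (exhaustive enumeration, brute-force double loops,
exact subset enumeration) is computable while the statistics are stable.
Tolerances: gauge identities at 1e−9 to 1e−12 (pure floating-point
algebra); Monte-Carlo comparisons at 3–4 standard errors; the null-world
AUC band (±0.06 around 0.5) is three standard errors of a 5-seed mean for
~100/100-split AUCs.  Ties in ROC ranking use the mid-rank convention; ties
in score sorting are broken by original order (stable sort).  RNG: a single
`numpy` generator per entry point, seeded; `make_world` derives child seeds
for sampling and geometry from its one seed, so a world is fully determined
by its config (replayed by `load_world`).

## Known limitations

* The threading score is a proxy in statistical-energy units; no conversion
  to physical kcal/mol is attempted (the reorg_scale of the generator is a
  construction device, not a calibration).
* The pseudolikelihood fitter is dense and single-threaded; it is not meant
  for L ≳ 100.
* Difference-map entries for pairs unobserved in either ensemble are 0, which
  silently drops any true signal at never-resolved positions; the `observed`
  mask records where this happened.
* The gatekeeper adjustment is a single additive offset; richer sequence
  signals (anchor-residue conservation, family-specific terms) are carried
  as annotations only.
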