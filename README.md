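# pottsthread

Potts statistical-energy threading of kinase sequences over conformational
contact ensembles, and the panel statistics that connect the resulting
reorganization penalties to type II inhibitor selectivity.

## The problem

Type II kinase inhibitors bind the "classical DFG-out" inactive conformation
of the kinase catalytic domain, in which the DFG motif is flipped and the
activation loop is folded.  Before such an inhibitor can bind, the kinase
must pay the free-energy cost of reorganizing from its active DFG-in state:

```
dG_exp = dG_bind + dG_reorg
```

where `dG_exp` is the measured binding free energy, `dG_bind` the affinity
for the preformed inactive conformation, and `dG_reorg` the reorganization
cost.  Kinases that pay a large `dG_reorg` look *selective* in panel assays
(few inhibitors bind them below 10 uM); kinases that reorganize cheaply look
*promiscuous*.

`pottsthread` estimates `dG_reorg` per sequence from evolutionary couplings.
A Potts model over an alignment of kinase catalytic domains assigns each
sequence S the statistical energy

```
H(S) = sum_{i<j} J_ij(S_i, S_j) + sum_i h_i(S_i),     P(S) = exp(-H(S)) / Z
```

Each conformational state is summarized by a contact-frequency map: the
1/u-weighted average of binary 6 A contact matrices over an ensemble of
structures (u counts structures of the same kinase, so PDB-overrepresented
kinases do not dominate).  The **threading score** contracts the couplings
against the change in contacts between the two ensembles:

```
dT(S) = - sum_{i<j} J_ij(S_i, S_j) * dc_ij,      dc = c_out - c_in
```

evaluated in the zero-sum gauge.  A high dT means the couplings this
sequence relies on are lost upon reorganization — a high predicted
`dG_reorg`, hence predicted selectivity (conventionally dT > 6 selective,
dT < 2 promiscuous, with a configurable additive adjustment for large
gatekeeper residues).

The package implements the full chain — alignments, Potts models
(evaluation, zero-sum gauge fixing, Gibbs sampling, pseudolikelihood
inference for desk-scale models), contact ensembles from PDB coordinates,
threading, and panel statistics (hit rates, selectivity labels, subset
randomization, ROC/AUC, score-binned affinity distributions, and
precision-recall evaluation of external affinity predictors) — together with
a synthetic-data generator that realizes the free-energy decomposition with
known ground truth, so every stage is testable without downloads.

## Worked example

The `analysis/` drivers run the whole study on a synthetic world
(348 kinases, 50 inhibitors, 16 tagged `davis` / 34 `schrodinger`):

```bash
python analysis/01_simulate_world.py --seed 1   # writes results/world/
python analysis/02_threading_scores.py
python analysis/03_panel_statistics.py
python analysis/04_roc_and_bins.py
python analysis/05_evaluate_predictor.py
```

With seed 1 this prints, among other things:

```
  Spearman(dT, true dG_reorg) = 0.926
  predicted selective: 16
 ceiling  full_panel_count  full_panel_pct  davis16_count  davis16_pct
       2                84            24.1            278         79.9
 hit_cutoff_nM  selectivity_threshold   auc  best_score_cutoff
       10000.0                     10 0.954               2.77
```

Reading: threading scores track the constructed reorganization energies
(rank correlation 0.93 at the default noise level); a 16-inhibitor subset
makes 80% of kinases look selective (hit rate <= 2) where the full
50-inhibitor panel shows only 24% — the finite-sampling inflation that
motivates the randomization test; and the threading score separates
selective from promiscuous kinases with AUC ~ 0.95 under the hit-rate <= 10
definition.  `04_roc_and_bins.py` additionally shows the monotone trend of
mean hit rate and of strong/average/weak affinity fractions across
threading-score bins, and `05_evaluate_predictor.py` contrasts a memorizing
affinity predictor on seen vs unseen inhibitors (AUPR 1.00 vs 0.08).

The same stages are scriptable via the `threadscope` CLI
(`simulate | fit | contacts | thread | panel | run`); see
`threadscope --help`.

## Layout

```
src/pottsthread/     library: alignment, potts, contacts, threadscore,
                     panel, synthetic, pipeline, cli
analysis/            numbered narrative drivers (simulate -> evaluate)
scripts/acceptance.py
tests/               pytest suite incl. acceptance-level checks
docs/methods.md      model, parameters, generator, numerical choices
```
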