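# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic-data experiments do and do not
demonstrate.

## Substitution models and likelihood

Rate matrices are general time-reversible: Q_ij = s_ij·π_j for i ≠ j
with a symmetric exchangeability matrix s and stationary frequencies π,
diagonal set for zero row sums, and the whole matrix scaled so
−Σ_i π_i Q_ii = 1, making branch lengths expected substitutions per
site. Three models are provided:

- **LG** — the empirical amino-acid model; exchangeabilities and
  frequencies ship as a plain-text data file in the classic PAML layout
  (lower triangle + frequencies), with its sha256 pinned in code and
  verified at load.  Default frequencies are the model's own; a user
  simplex (e.g. alignment-derived, "+F") may be supplied.
- **binary_gap** — the symmetric two-state model over {a, g} used for
  ancestral indel inference. Under normalization its rate matrix is
  forced to [[−1, 1], [1, −1]].  The published description of the gap
  step names an equal-rates nucleotide model on a two-symbol coding;
  a two-state symmetric chain gives identical likelihood ratios up to a
  rate rescaling absorbed by the branch lengths, so it is implemented
  directly as two states.
- **JC_k** — equal-rates model on k states, mostly for tests.

Matrix exponentials use the symmetric eigendecomposition of
D^{1/2} Q D^{−1/2} (D = diag π), which is exact for reversible Q and
yields strictly row-stochastic P(t) after clipping round-off.

Among-site rate variation uses Yang's discrete-gamma approximation:
`ncat` equal-probability categories (default 4), each represented by its
**category mean** (not median), computed from the incomplete gamma
function and renormalized to mean exactly 1.  Category means are the
default of the standard reconstruction tools this pipeline mirrors.
The gamma shape α is a user input (or can be profiled via the likelihood
functions); no claim is made about any particular historical setting,
which published descriptions leave ambiguous.

Likelihoods come from Felsenstein's pruning algorithm, vectorized across
columns, with per-node rescaling (threshold 1e-280) and per-site log
bookkeeping; multifurcations enter the pruning product directly. Tips
with '-' or 'X' contribute a partial-likelihood vector of ones (the
standard missing-data treatment). Branch-length refinement is
coordinate-wise bounded univariate optimization (branch length capped at
50) cycling until a full cycle gains less than `tol`; a sub-tolerance
cycle is rolled back, so an unachievable tolerance returns the input
unchanged. Note that under a reversible model the two branches incident
to the root are only jointly identifiable (their sum is).

## Marginal ancestral reconstruction

Posteriors at a node are inside × outside partials normalized per site,
computed per gamma category and combined with weights proportional to
each category's site likelihood (empirical Bayes over rates; the
mixture weights prior is uniform). MAP ties are broken by alphabet
order and flagged. Gap inference recodes columns as {a, g} ('X' counts
as present), reuses the residue tree's branch lengths (no separate
re-estimation — configurable in principle, but re-estimation is not
implied by the procedures mirrored here), and masks a column iff the
posterior of 'g' exceeds 0.5 (a MAP rule; exactly 0.5 is left unmasked
and logged). Masked columns are dropped from the final sequence and an
output-position → alignment-column map is emitted (columns are 1-based
everywhere user-facing).

A consequence worth stating: a gap observed in a single taxon on a
*short* pendant branch is strong evidence for an ancestral gap (the tip
state has had little time to change), whereas on a long pendant branch
it reads as a lineage-specific loss and the ancestor keeps the column.
Both behaviors are checked against a joint-enumeration oracle.

## Kinetics

Michaelis–Menten fitting is untransformed nonlinear least squares on
v = Vmax·S/(Km+S); the double-reciprocal linearization supplies starting
values only (final linearized estimates would be biased under
multiplicative noise). Ko inference is unweighted OLS of apparent Kc on
dissolved O₂ (intercept Kc(N₂), slope Kc/Ko); no weighting scheme is
assumed. Vo is derived from the specificity factor identity, and
measured specificity factors are normalized so the wheat reference reads
exactly 100.0 at 25 °C. The rate/specificity tradeoff is fit as a power
law by OLS in log–log space; residuals are signed log-space deviations
so "below the extant frontier" is directly readable. The specificity
factor assay itself (total RuBP consumption in an oxygen electrode) is
not simulated mechanistically; τ enters as a measured input.

**Dissolved O₂ in air: 260 µM.** The air-referenced columns need one
constant — dissolved O₂ in air-equilibrated water at 25 °C.
Back-calculating it from every row of the published characterization
table (e.g. wheat: (19.2/10.9 − 1)·341 = 259.7 µM) pins it to 260 µM
within 0.5%, and 260 µM is also the standard Henry's-law value for
21% O₂ at 25 °C. It is configurable (`o2_air`).

## Synthetic data: what it emulates, what it does not

`simulate_alignment` draws the root from the stationary frequencies,
fixes one gamma category per column for the whole tree (the standard
gamma-sites assumption), evolves states edge-wise through P(t·rate), and
overlays indels as single-column presence/absence characters evolved
under the two-state model at rate `indel_rate` (columns present at the
root with probability 0.9 when indels are enabled — most columns of a
curated alignment are ancestrally present; gap-free when the rate is 0).
It does **not** emulate multi-column indels, site-specific frequency
profiles, structural constraints, or alignment error; closed-loop
accuracy here is therefore an upper bound on what identical settings
would achieve on real alignments, where model misspecification adds
error the tests cannot see.

`simulate_assay` draws rates from the competitive-inhibition MM surface
rate = Vc·S/(Kc·(1+O₂/Ko)+S) with lognormal noise of median 1, on the
assay grid the wet protocol uses: six CO₂(aq) levels from 5 to 550 µM at
four O₂ equilibrations (N₂, air, 60% O₂, 100% O₂ → 0, 260, 742.9,
1238.1 µM dissolved). Default generating constants are the ancestral
Form 1B values (Vc = 4.72 s⁻¹, Kc = 120 µM, Ko = 641 µM, τ = 49.6);
default noise σ = 0.05.

`radiation_tree` emulates the sampling design of a broad protein-family
alignment: a pure-birth tree with 120 extant tips is subsampled to
`n_taxa` (default 24). Incomplete sampling shifts the retained
divergences toward the root, which is the shape such alignments show.
"Total depth" of a tree here means the maximal tip-to-tip path length;
trees are ultrametric with root-to-tip height total_depth/2.

## Closed-loop experiment sizes

The root-recovery experiment runs 24 taxa × 300 sites under LG+Γ4
(α = 1.0; accuracy is insensitive to α in the 0.5–1 range) at total
depths {0.5, 1, 2, 4}, 20 seeds each — sizes chosen so the whole
experiment completes in seconds while the per-depth mean has a standard
error near 0.01. Measured means are ≈0.96/0.92/0.80/0.64: the 0.8 level
at depth 2 sits essentially at the Bayes-attainable frontier for these
conditions (the MAP estimator is optimal under the generating model, so
no implementation could score materially higher). Kinetic closed loops
use 200 seeds; recovery from noiseless assays is exact to numerical
tolerance, and at 2% rate noise the median signed error of Vc, Kc and Ko
stays below 0.1% (the estimators are unbiased; dispersion, especially of
Ko, is larger).

## Known limitations

- Marginal reconstruction only; joint ML reconstruction and posterior
  sampling of ancestors are out of scope, as are topology search, model
  selection and partitioned models.
- Reconstruction is done at requested nodes, not all nodes at once.
- The gap model reuses residue branch lengths; columns are treated
  independently (no indel length model).
- Ko inference assumes the linear apparent-Kc relation exactly;
  curvature from mixed inhibition would bias it.
- The tradeoff fit treats both axes as error-free and fits τ on Vc by
  OLS in logs; it is a descriptive frontier, not an errors-in-variables
  model.
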