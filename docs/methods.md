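# Methods

## Model

`ergmselect` works with exponential random graph models (ERGMs) for binary
undirected networks on a fixed node set of size $n$:

$$P_\theta(Y = y) \;=\; \frac{\exp\{\theta_1^\top s(y) + \theta_2^\top g(y, x)\}}{\psi(\theta)},$$

where $s(y)$ are endogenous statistics computed from the graph itself,
$g(y,x)$ optional exogenous statistics combining ties with nodal covariates
$x$, and $\psi(\theta)$ the normalizing constant summed over all
$2^{\binom{n}{2}}$ graphs.  The edge count $s_0(y)=|E|$ always enters first
and plays the role of an intercept; the model with only the edge term is the
Bernoulli random graph.

The term catalog covers the thirteen endogenous statistics commonly used for
binary undirected networks — `kstar(k)`, `dsp(k)`, `esp(k)`, `nsp(k)`,
`triangle`, `isolates`, `sociality`, `degree_cross_product`,
`degree_popularity`, and the geometrically weighted `gwesp`, `gwnsp`,
`gwdsp`, `gwdegree` — plus `nodecov`/`absdiff` covariate terms.  Two of these
have no universally fixed formula under their common name; we adopt the
reference-software conventions and document them as conventions:

* `degree_cross_product` = mean over edges of the endpoint-degree product
  (0 on the empty graph);
* `degree_popularity` = $\sum_v \deg(v)^{3/2}$.

The geometric decay $\tau$ of the `gw*` terms is a fixed hyperparameter
(default 0.5), never estimated; each `gw*` term is a single statistic, a
weighted sum of its shared-partner or degree spectrum with weights
$e^{\tau}\,[1-(1-e^{-\tau})^k]$.  `sociality` is a block of $n-1$ per-node
degree statistics with node 0 (the first label) excluded as the reference to
avoid collinearity with the edge term; it enters and leaves selection as one
block, and counts as $n-1$ parameters in the AIC.

### Counting conventions

`count_kstars(g, 2)` and `count_triangles` return the statistics the
likelihood uses: $\sum_v \binom{\deg v}{2}$ and the number of closed
unordered triples.  Some published network summary tables instead count
ordered 2-paths and ordered triangles — exactly twice each of these.
`motif_summary(..., convention="ordered")` reports that convention, and the
bundled-network registry stores its published rows in it.

## Estimation

**Change statistics.** Every term exposes
$\delta_{ij}(y) = s(y^+_{ij}) - s(y^-_{ij})$ computed locally from the dyad's
neighbourhood ($O(\deg)$ to $O(\deg^2)$ per toggle).  Toggle consistency —
local change equals the full-recount difference, exactly, for every term —
is the central correctness oracle of the test suite.  The Metropolis sampler
mirrors these formulas in a compiled (numba) kernel on a dense adjacency
matrix; kernel and Python implementations are tested against each other.

**Sampling.** Metropolis–Hastings with uniform single-dyad toggle proposals.
Defaults: burn-in $20\binom{n}{2}$ toggles, thinning interval
$\binom{n}{2}$, 512 retained samples, all configurable.  Randomness is an
explicit xorshift128+ state seeded from one root seed, with documented
per-component derivation (`derive_seed(root, token, replicate)`), so every
chain, fit and replicate is reproducible.  One caveat worth knowing: at
$\theta$ where every proposal is accepted (e.g. the edges-only model at
$\theta_0=0$) the chain flips edge-count parity deterministically and is
parity-periodic; any rejection restores aperiodicity.

**MPLE.** Maximum pseudo-likelihood: logistic regression of the dyad
indicators on the change statistics at the observed graph, fitted by damped
Newton iterations.  For dyad-independent models (edges, sociality, nodecov,
absdiff) the pseudo-likelihood *is* the likelihood, so the MPLE is the exact
MLE and its AIC is exact; the edges-only MPLE is `logit(density)` in closed
form.  Coordinates whose estimates pass ±20 on the log-odds scale, or whose
change-statistic column is identically zero, are flagged as separated with a
sign.

**Divergence ("estimates at infinity").** The MLE of an exponential family
fails to exist exactly when the observed statistic lies on the boundary of
the convex hull of attainable statistics.  Three detection routes, in order:

1. *Boundary certificate* — a nonnegative count-like statistic observed at 0
   (or an observed complete/empty graph for the edge term) is a sufficient
   certificate; the coordinate is flagged $-\infty$ (resp. $+\infty$) with
   no fitting at all.
2. *Chain degeneracy* — during MCMC fitting, simulated statistics frozen at
   a constant different from the observed value (a chain collapsed onto the
   empty or complete graph) flag the fit divergent.
3. *Threshold* — $|\hat\theta_j| > 20$ on the log-odds scale (configurable).

MPLE separation alone is deliberately **not** treated as MLE nonexistence:
on small graphs the pseudo-likelihood can separate while the exact MLE is
finite and small (verifiable by enumeration at $n=5$), so an uncertified
separated MPLE only triggers a clipped, safe starting value.

**Contrastive-divergence initialization.** Robbins–Monro ascent
$\theta \mathrel{+}= \frac{a}{t+b}\,(s(y_{\rm obs}) - s(y_{\rm CD}))/|s(y_{\rm obs})|$
with short chains ($4\binom{n}{2}$ toggles) restarted at the observed graph;
defaults $a=1$, $b=10$, 300 iterations, started from the MPLE clipped to
±3.  CD with short chains has its own (biased) fixed point — it is an
initializer whose job is to land in the MLE's basin, and the tests assert
exactly that (it climbs the exact likelihood on enumerable toys), not that
it equals the MLE.

**MCMC MLE.** Iterated importance-weighted Newton steps on the simulated
log-likelihood-ratio surface, with step length capped at 1 per update;
convergence is declared when the observed statistics fall within one MC
standard error of the simulated means.  The log-likelihood at $\hat\theta$
is then estimated by thermodynamic integration along a linear path from a
Bernoulli reference model fitted to the observed density (whose
log-normalizer is closed-form): default 16 grid points, 512 statistic draws
each, trapezoid rule, with an MC standard error propagated from the
per-point variances.  On enumerable models ($n=5$) this estimate matches the exact AIC within a
few hundredths of an AIC unit, and on a bundled 16-node network it agrees
with an independent importance-sampling bridge (i.i.d. Bernoulli reference
draws) within 0.05 nats — both checks are part of the test suite.  Dyad-independent models skip MCMC entirely (their AIC is exact)
unless `force_mcmc` is set; this makes the null AIC deterministic, so the
replicate noise in selection comes from the candidate side.

## Stepwise selection

**Order bounds.** For each of kstar/dsp/esp/nsp, univariate edge+family($l$)
models are fitted for $l = 2, 3, \dots$; the scan stops at the first run of
3 consecutive divergent fits (both defaults configurable, hard cap
$l = n-1$) and returns the largest non-divergent order.  High orders are
usually observed at 0 and dispatched instantly by the boundary certificate.
On degree-regular graphs even $l=2$ can sit on the hull boundary (the
2-star count is minimal given the edge count), so a bound of 0 is a
legitimate outcome.

**Stochastic forward selection.** With the candidate set $S_M$ (bounded
families up to their bounds plus the nine unbounded terms), each candidate
enters a univariate model whose MCMC-estimated AIC is compared with the null
AIC through the relative change $b = (\mathrm{AIC}_0 -
\mathrm{AIC}_i)/\mathrm{AIC}_0$ (positive = improvement).  Each univariate
model is refitted $R$ times (default 30) with distinct derived seeds; a term
survives when the 10th percentile $\hat b$ of its replicate $b$ values is
positive (linear-interpolation percentile).  Divergent refits are excluded
from the percentile but counted; a divergent majority removes the term.
The replicate behaviour sorts terms into three categories: (1) every finite
replicate improves the AIC; (2) degenerate or harmful (divergent majority,
or negative mean with $\hat b \le 0$); (3) ambiguous, resolved by the sign
of $\hat b$.  Selection is one-pass univariate screening; no multi-term
forward steps are taken.

**Degeneracy screening and ranking.** The surviving terms generate the model
space of all one- and two-term models (plus edges).  Each fitted model is
screened by simulating networks and comparing the mean simulated edge count
$H_M$ with the observed $H_O$: discard when $|H_M - H_O|/H_O \ge 4$.  The
threshold 4 (a 400 % relative error) is deliberately lenient — it catches
only models collapsed toward the empty or complete graph — and is exposed
as a parameter.  Models whose fit diverged never reach simulation and are
reported with the distinct reason `divergent-fit`.  Surviving models are
ranked by the normalized L1 motif score
$\sum_{m \in \{\text{edges, 2-stars, triangles}\}} |\bar m - m_{\rm obs}| /
\max(m_{\rm obs}, 1)$ (an implementation choice; "closeness" has no
canonical metric), ties broken by fewer terms, then term names.

## Data

Three classic networks are bundled as plain-text edge lists rebuilt from
canonical public sources (`scripts/make_fixtures.py`): Zachary's karate
club, and Padgett's Florentine marriage and business networks (16 families
including the isolated Pucci).  The loader validates each against its
published node/edge/2-star/triangle row at load time.  Six further classic
networks (Lazega lawyers, two Kapferer tailor-shop networks, the synthetic
molecule, Faux Mesa High, and the E. coli transcription network) are
registered with their published counts but not bundled: they have no
redistributable plain-text source here, and loading them raises
`FixtureUnavailableError`.

The synthetic generators define the study conditions for every stochastic
test: Bernoulli graphs $G(n, p)$, and well-mixed ERGM draws via
$100\binom{n}{2}$-toggle chains started from a density-matched Bernoulli
graph.  The recovery studies use edges+gwesp(0.5) at
$\theta = (-2.5, 0.8)$ on $n = 30$ — density ≈ 0.28 with clearly elevated
transitivity, inside the non-degenerate regime.  What synthetic data does
not emulate: covariate-driven tie formation, degree heterogeneity beyond
what gwesp induces, and any directed or valued structure — so passing
recovery tests demonstrate internal consistency of the machinery, not
field validity on arbitrary real networks.

## Problem sizes and tolerances

* Enumeration oracles run at $n \le 5$ (1,024 graphs; hard cap
  $\binom{n}{2} \le 21$).
* Simulation-vs-enumeration checks use 2,500 samples thinned at 301
  toggles and a 3-MC-standard-error band.
* Recovery runs use 10 data sets, $R = 10$ replicates, and slightly
  reduced path-sampling settings (12 points × 320 draws) — precision well
  beyond what the ±AIC-unit decisions need.
* The full-pipeline demonstrations run on the bundled networks with
  $R = 10$ ($R = 5$ and 256-sample chains for the karate club, whose dyad
  count is 4–5× larger).

## Known limitations and observations

* Exact likelihoods exist only at toy scale; everything else is Monte
  Carlo with seeded determinism.
* On the Florentine marriage network the precise AIC estimator finds *no*
  single endogenous term that improves on the Bernoulli null (e.g. the
  kstar(2) coefficient is ≈ 0.006 with AIC 112.1 vs 110.1): the stepwise
  procedure correctly returns an empty surviving set there.  Analyses that
  report survivors on this network rest on noisier AIC estimates.
* Degenerate-but-finite regions (quasi-separation without a boundary
  certificate) are decided by the runtime chain diagnostics; these are
  heuristics, and the threshold 20 is a finite-precision proxy for
  "infinite".
* Directed and valued networks, multigraphs, curved-ERGM estimation of
  decay parameters, and Bayesian/temporal variants are out of scope.
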