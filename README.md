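# mceminem

Structure learning for **Nested Effects Models (NEMs)** from gene-perturbation
screens, combining a closed-form Expectation-Maximization algorithm,
mode-hopping Markov chain Monte Carlo over the EM local maxima, and an
empirical Bayes estimate of the effects-attachment prior.

## The problem

A perturbation screen knocks out (or mutates) each of *S* signalling
components — for example the subunits of a protein complex — and measures the
genome-wide expression response of *E* downstream genes.  NEMs explain such
data with two graphs:

- the **signals graph** Γ, a binary S×S adjacency with unit diagonal, where an
  edge k→s means that perturbing k also perturbs s (the effects of s are
  *nested* inside the effects of k);
- the **effects attachment** Θ, assigning each observed gene to exactly one
  signal — or to a virtual **null node** whose genes are predicted never to
  respond (built-in feature selection).

The model predicts an effect of gene *e* under perturbation *k* exactly when
there is a two-step path k→s→e, i.e. Γ<sub>ks</sub> = 1 for the signal *s*
that *e* is attached to.  The data enter as a log-odds matrix *R* (effects ×
perturbations): R<sub>ek</sub> is the log ratio of the evidence for "gene e
changed under perturbation k" versus "did not change", as produced upstream by
a moderated-t / FDR pipeline (that pipeline is out of scope here).

With a row-stochastic attachment prior ν and edge-wise independent Bernoulli
priors on Γ, the marginal log posterior of the signals graph is

```
log P(Γ | D) = Σ_e log( Σ_s ν_es · exp( Σ_k Γ_ks R_ek ) + ν_e,null )
             + Σ_{k≠s} log P(γ_ks)   (+ const)
```

## The algorithm

1. **EMiNEM** — the E-step computes the attachment responsibilities ω given
   the current Γ; the expected complete log-posterior is *linear* in the
   entries of Γ, so the M-step maximizes it edge by edge in closed form:
   γ′<sub>ks</sub> = 1 iff Σ_e ω<sub>es</sub> R<sub>ek</sub> +
   logit(p<sub>ks</sub>) > 0.  Each iteration provably increases the marginal
   posterior; a fixed point is a local maximum and is reached in a handful of
   steps even for thousands of effects.
2. **Mode-hopping MCMC** — the posterior landscape is rugged, so a
   Metropolis chain perturbs a raw graph by random edge flips, maps every
   proposal to its nearest local maximum by EM, and evaluates the Hastings
   ratio on the *mapped* graphs.  The recorded mapped graphs are
   approximately a sample from the posterior restricted to the set of local
   maxima.
3. **Empirical Bayes** — the attachment prior ν is initialized from the data
   (softmax of each gene's log-odds row against the null), then iteratively
   replaced by the average attachment posterior over the sampled graphs,
   until it stops changing.  This adaptively concentrates each gene's prior
   on its true target (or the null node) and is what removes spurious edges.

Bi-directionally connected signals are statistically indistinguishable and can
be merged into a single node (`merge_indistinguishable`), and fitted effects
can be grouped by attachment × direction of regulation for downstream
enrichment analysis (`group_effects`).

## Worked example

```python
import numpy as np
from mceminem import (SimScenario, sample_nem, generate_logodds,
                      MCEMiNEM, evaluate_edges)

rng = np.random.default_rng(0)
scenario = SimScenario(n_signals=5, n_effects=200, alpha=0.05, beta=0.1)
truth = sample_nem(scenario, rng)                      # random ground-truth NEM
R = generate_logodds(truth, scenario.alpha, scenario.beta, rng)

model = MCEMiNEM(n_steps=2000, burn_in=1000, thin=5, rounds=3,
                 random_state=1).fit(R)

print("inferred edges:", sorted(model.graph_.edges()))
print(evaluate_edges(model.graph_, truth.graph))
```

Output:

```
inferred edges: [('s1', 's2'), ('s3', 's2'), ('s3', 's5'), ('s4', 's1'),
                 ('s4', 's2'), ('s5', 's1'), ('s5', 's2'), ('s5', 's4')]
(1.0, 1.0)
```

All 8 true edges of the simulated 5-node signals graph are recovered with no
false positives (edge sensitivity 1.0, specificity 1.0).  Of the 200 simulated
genes, 165 survive pre-filtering (a gene whose log-odds row has no positive
entry can never raise the posterior and is dropped); the rest of the 20%
null-attached genes are absorbed by the null node during fitting.

The same pipeline is available from the shell:

```bash
mceminem simulate --signals 5 --effects 200 --beta 0.1 --seed 0 -o sim/
mceminem fit sim/logodds.tsv -o fit/ --steps 2000 --rounds 3 --seed 1
mceminem benchmark --signals 11 --betas 0.05,0.1,0.2 --replicates 10 -o bench/
```

`fit` writes the inferred adjacency (TSV/edge-list/DOT), the per-gene
attachment table, the sampled-graph trace and per-edge sample frequencies.

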