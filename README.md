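# indelfit

Simulation-based inference of **indel dynamics parameters** from a
multiple sequence alignment (MSA) and a phylogenetic tree.

Substitution model parameters are routinely estimated from data, but the
parameters governing insertions and deletions — how often indels occur
relative to substitutions, and how long they are — usually have to be
guessed when simulating sequences or running parametric bootstraps.
`indelfit` estimates three of them directly from an alignment:

- **IR** — the indel-to-substitution rate ratio (total indel rate per
  site, with the substitution rate normalized to 1 per site per unit
  branch length);
- **a** — the slope of the Zipf (power-law) indel length distribution,
  Pr(k) ∝ k⁻ᵃ truncated at a maximum length of 50;
- **RL** — the length of the ancestral sequence at the root of the tree.

## Method

The inference is approximate-Bayesian-computation–flavored. An input MSA
is summarized by five attributes **x** = (alignment length, total number
of gap blocks over rows, average gap block length, minimal and maximal
ungapped sequence length). For a candidate parameter triple Θ = (IR, a,
RL), *N* alignments are simulated along the fixed input tree with a
Gillespie indel process that tracks residue homology exactly (so the
*true* alignment is known, not re-estimated), and their attribute
vectors yield a mean **μ** and covariance **S**. The fit of Θ is the
squared Mahalanobis distance

    D²(x) = (x − μ)ᵀ S⁻¹ (x − μ),

which is minimized over Θ by coordinate-wise golden-section search
(RL → IR → a) from three root-length starting points (shortest sequence,
longest sequence, number of columns), with common random numbers across
evaluations so the objective is deterministic. At the optimum, D² is
recomputed on a larger confirmation ensemble and converted to a
goodness-of-fit p-value, p = 1 − CDF_χ²(v−1)(D²) with v = 5 attributes:
a small p flags an alignment whose indel structure the fitted model
cannot reproduce.

## Worked example

Simulate a "real" alignment with known parameters and recover them:

```python
import numpy as np
from indelfit import (IndelParams, SearchConfig, generate_benchmark_tree,
                      infer_parameters, simulate_true_msa, write_msa)

tree = generate_benchmark_tree(n_taxa=29, total_length=5.0, seed=1)
truth = IndelParams(ir=0.02, a=1.3, rl=350)
msa = simulate_true_msa(tree, truth, np.random.default_rng(5))
res = infer_parameters(msa, tree, SearchConfig(n_sims=50, seed=1))
print(res.ir, res.a, res.rl, res.d2, res.pvalue)
```

prints (one line, wrapped):

```
0.019976707849886435 1.1964394744355145 357
0.4902012220455545 0.9744478536879205
```

The true IR = 0.02 and RL = 350 are recovered almost exactly; the slope
a is the hardest parameter (one ~500-column alignment contains only a
few dozen indel events to learn a length distribution from), and over
replicate datasets its estimates scatter around the truth of 1.3. The
confirmation D² of 0.49 against a χ²(4) reference gives p ≈ 0.97: the
fitted model reproduces the alignment's indel summary statistics, as it
should here.

The same run from the shell, with the alignment and tree as files:

```sh
indelfit infer --msa example.fasta --tree example.nwk --n 50 --seed 1
```

emits a JSON result embedding the version, seed and fully resolved
configuration. `indelfit simulate` writes alignments under given
parameters (e.g. to mimic a real data set after inferring its
parameters), `indelfit fit-test` prints the attribute table and fit
p-value for a fixed parameter triple, and `indelfit benchmark` runs the
parameter-recovery experiment below.

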