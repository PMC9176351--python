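# Methods

## The monitored statistic

For a functional group *f*, a window of the generation stream, and the
generator's (unlabelled) training set, define

- `P_f` — fraction of *valid* in-window molecules containing at least
  one match of *f*'s SMARTS pattern (presence, not match count),
- `P_tf` — the same fraction over the valid training molecules,
- `P_E = P_f / P_tf` — the enrichment ratio.

`P_E` is a ratio of occurrence probabilities; the literature sometimes
calls it an odds ratio, and the API keeps the neutral name `p_e`. The
window is the half-open index range `(end − L, end]` on the 0-based
stream, advanced by a stride; defaults are L = 100 and stride 1.
Invalid SMILES stay in the stream for index bookkeeping but never enter
a numerator or denominator, and duplicates count every time they occur
(no deduplication rule is imposed). Windowed counts are computed from
cumulative sums, so a full trajectory costs O(n·G); a brute-force
recount oracle in the tests verifies every window on 1,000-molecule
streams.

Degenerate baselines: with `P_tf = 0` and `P_f > 0` the ratio is
reported as `inf` with a warning — the formula is a plain ratio and is
never silently altered; an optional pseudocount ε computes
`(P_f+ε)/(P_tf+ε)` for plotting. `0/0` is defined as 1 (no signal).
No confidence intervals are attached: the statistic is a point ratio,
and its sampling noise is handled in validation by explicit binomial
bands.

## The functional-group catalog

Catalogs are user-editable JSON/TSV (name, SMARTS, description), so a
disagreement about a group's definition is configuration, not code.
The shipped defaults:

| group | SMARTS | note |
|---|---|---|
| ketone | `[#6][CX3](=O)[#6]` | excludes aldehydes/acids/amides |
| diketone | `[#6][CX3](=O)[CX3](=O)[#6]` | α-diketone (adjacent carbonyls); "diketone" is ambiguous and the α reading is deliberate — β-diketones such as acetylacetone do not match |
| aniline | `[NX3;!$(N=*)]c1ccccc1` | amine N on a benzene carbon; excludes nitro/imine N and non-benzene heteroaromatics |
| azo | `[#6]N=N[#6]` | E/Z unconstrained |
| 1,2-quinone | `O=[#6]1-[#6](=O)-[#6]=,:[#6]-[#6]=,:[#6]-1` | ortho-dione six-ring; the `=,:` ring bonds admit benzo-fused members |
| 1,4-quinone | `O=[#6]1-[#6]=,:[#6]-[#6](=O)-[#6]=,:[#6]-1` | para analog |
| 1,2-naphthoquinone | `O=C1C(=O)c2ccccc2C=C1` | fused bicyclic core |
| 1,4-naphthoquinone | `O=C1c2ccccc2C(=O)C=C1` | fused bicyclic core |

The patterns nest as chemistry dictates (naphthoquinone ⊂ quinone ⊂
diketone/ketone); the test suite asserts this and cross-checks curated
positive/negative examples for every group against OpenBabel's
independent SMARTS matcher. No tautomer enumeration or alternative
aromaticity models are attempted.

## Reward

`r(I) = F(I) · G(I)` with

- `F(I) = (tanh(slope·(λ_I − θ)) + 1)/2`, slope 0.003 nm⁻¹, θ = 400 nm.
  Strictly increasing in the wavelength estimate λ, equal to exactly
  0.5 at θ, confined to (0, 1).
- `G(I) = (−tanh(SA_I − 4) + 1)/2`, strictly decreasing in the
  synthetic-accessibility score (1 easy … 10 hard), 0.5 at the pivot 4.

These closed forms are reconstructions: the published equations are
typographically flattened, and the forms above are the unique tanh
sigmoids consistent with the stated anchors (range (0, 1), F(400) = 0.5
at θ = 400, monotone directions). Both providers are injection points:

- wavelength: the default is a structural surrogate
  `λ̂ = 150 + 25·conjugate_length + 20·aromatic_rings` (nm). It stands
  in for an electronic-structure calculation and preserves only the
  qualitative monotonicity — more conjugation and more aromatic rings
  red-shift the estimate. The coefficients were chosen so that typical
  small training molecules land below θ (λ̂(benzene) = 320 nm) while
  fused conjugated systems cross it, giving the search a usable
  gradient; they are configuration, not chemistry.
- SA: the Ertl–Schuffenhauer fragment-contribution scorer bundled with
  RDKit when available, else a structural proxy
  `1 + 0.3·rings + 0.05·heavy_atoms` capped at 10.

Invalid (unparsable or empty) molecules receive reward 0 by convention
so the search can always rank rollouts.

## Desk-scale generator

The production-scale setup this emulates — a recurrent network trained
on ~150k ZINC SMILES, searched on thousands of cores — is replaced by
components that run in seconds while preserving the search machinery:

- **Language model.** An order-k Markov model (default k = 3) over
  SMILES tokens with add-ε smoothing (ε = 0.01), vocabulary restricted
  to the H/C/N/O grammar subset. Sequences are terminated with an
  explicit end token whose transitions are counted, so termination is
  learned and, through smoothing, reachable from every context. The LM
  satisfies the generic contract (next-token distribution given a
  prefix) and can be swapped for a recurrent model.
- **Search.** MCTS over token prefixes. Child *i* of parent *p* is
  selected by `u_i = tR_i/(v_i+vl_i) + C·P_i·√(v_p+vl_p)/(v_i+vl_i+1)`
  with C = 2 (configurable); unvisited nodes carry a +∞ sentinel and
  ties break by prior then token order, which makes runs reproducible.
  The √ over the parent counts and the placement of the +1 only in the
  exploration denominator are reconstructions of a flattened printed
  formula, by analogy with standard parallel-UCT/PUCT forms; both are
  isolated in `node_score`. Virtual losses are incremented along the
  selected path and cleared at backpropagation; `n_virtual` selections
  are batched before evaluation (default 1, which reduces to serial
  MCTS while still exercising the vl terms — multi-process execution is
  out of scope). Rollouts sample the LM to the terminator or a 60-token
  cap; every rollout is logged in order with its reward breakdown, so
  the log is the molecule time series the monitor consumes.

## Synthetic streams and what validation shows

Streams are built by sampling labelled SMILES pools — one pool per
catalog group plus negatives matching no group — rather than by graph
mutation, so ground-truth group presence is known by construction. A
trend maps stream index to occurrence probability p(t) (constant, step,
ramp); at each index the pool is chosen categorically, with earlier
trends keeping their mass if probabilities ever sum past 1. Default
stream length is 2,000, a deliberate ~20× scale-down of a production
run so validation completes in seconds.

Validation shows parameter recovery: on injected step and ramp trends,
≥90% of windows (L = 100) put the realized `P_f` inside the 3-standard-
deviation binomial band around the injected window-mean probability,
and the `P_E` trajectory therefore tracks p(t)/q. What this does *not*
show: real generator output is autocorrelated (consecutive molecules
share tree ancestry), chemically diverse beyond the pools, and its
per-group occurrences are not independent Bernoulli draws — so the
binomial bands are a best case, and on real streams `P_E` noise at a
given window length will be somewhat larger.

## Properties and envelopes

Descriptors: molecular weight (standard atomic masses, implicit H
included), aromatic ring count (SSSR rings with all atoms aromatic),
and conjugate length. Conjugate length has no standard definition; it
is fixed here as the atom count of the largest connected component of
the conjugated-bond subgraph (deterministic, cheap, monotone under
π-extension), with the longest-simple-path alternative behind
`method="path"`. Envelopes report per-window mean and percentile bands
— defaults (5, 95) and (15, 75), the latter kept asymmetric as printed
in the source material rather than "corrected" to (25, 75) — using
linear interpolation between order statistics. The mean is not
guaranteed to lie inside the narrow band for skewed windows; only band
nesting is an invariant. External per-molecule values (e.g. computed
wavelengths) can be enveloped by adding columns to the log CSV.

## Known limitations

- No quantum chemistry: absorption wavelengths are a monotone
  structural surrogate, so absolute λ values and any downstream F
  magnitudes are not comparable to computed spectra.
- The Markov LM produces many invalid SMILES on tiny corpora; the
  search tolerates this (reward 0) but validity rates are far below a
  trained recurrent model's.
- Enrichment is reported without significance testing; use the
  synthetic null (constant trend at the training rate) to gauge noise
  at a chosen window length.
- The u_i and F/G closed forms are documented reconstructions of
  flattened printed equations; both are isolated behind single
  functions should an authoritative form differ.
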