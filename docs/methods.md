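# Methods

## The revision operator

An agent holds a probabilistic opinion over K mutually exclusive events: a
vector of nonnegative weights `p_k` with a free overall normalization `M`
(1 for ordinary probabilities, 100 when elicited in percent). A persuading
agent holds `q` with the same normalization. Revision is modeled as two
heuristics applied in sequence:

1. **Linear pooling.** The agent forms the mixture
   `pi_k = eps*p_k + (1-eps)*q_k`, where `eps` in [0, 1] is the weight he
   places on his own opinion (equivalently, one minus the persuader's
   credibility).
2. **Projection (trimming).** The mixture is pulled back toward the prior:
   `w_k = p_k^eps * pi_k^(1-eps)`, the unique functional form that commutes
   with probabilistic conditioning, so that it does not matter whether a
   conditioning step is applied before or after the projection.

The revised opinion is `w` renormalized to `M`. The composite rule

    p~_k  ∝  p_k^eps * (eps*p_k + (1-eps)*q_k)^(1-eps)

satisfies, by construction and verified exactly in the axiom test suite:

- **locality / free normalization** — the weight for event k depends only on
  `(p_k, q_k)`, and the rule is homogeneous of degree one in a joint
  rescaling of both opinions;
- **zero preservation** — `p_k = 0` implies `p~_k = 0` (the convention
  `0^a = 0` for `a > 0`);
- **no-overlap invariance** — disjoint supports leave the opinion unchanged
  (each surviving weight is proportional to `p_k`, so renormalization
  restores `p` exactly);
- **identity invariance** — `p = q` implies `p~ = p`;
- **conservatism / credulity limits** — `eps = 1` returns `p`; `eps = 0`
  returns `q` whenever all `p_k > 0`. The `eps -> 0` limit is discontinuous
  at events with `p_k = 0`: for any positive `eps` such events stay at zero,
  while at `eps = 0` exactly the rule would need to adopt `q` there. The
  implementation returns `q` at `eps = 0` when `p` is everywhere positive
  and raises a degenerate-revision error otherwise.

A **reverse-order variant** applies the two heuristics the other way
around: project `q` onto `p` (renormalized to `M`), then pool. Both orders
produce qualitatively similar revisions; the library asserts this as (a)
the Hellinger distance between the two variants' outputs being smaller than
the larger of the two movements and (b) a positive cosine between the two
movement vectors. The pool-then-project order is the default because
advice-taking experiments favor it.

## Boomerang continuation (eps > 1)

When the persuader's credibility is so low that `eps` exceeds 1, the pooled
vector `pi = eps*p + (1-eps)*q` becomes a signed measure. The rule is
continued as

    p~_k  ∝  p_k^(2-eps) * |eps*p_k + (1-eps)*q_k|^(eps-1)

which coincides with the main rule at `eps = 1`, keeps both exponents
nonnegative throughout `1 < eps <= 2`, and is non-smooth only through the
absolute value. Its signature phenomenology, all verified in the test
suite:

- overlap events with `p_k < q_k` lose raw weight whenever the pooled value
  has not crossed below `-p_k` (i.e. `q_k < p_k (eps+1)/(eps-1)`), and the
  revised Gaussian density lies pointwise below the prior throughout the
  region where the persuader outweighs the prior and the pooled measure is
  still positive. After renormalization the per-event statement is *not*
  universal for arbitrary discrete opinions — a strongly negative pooled
  value raises `|pi_k|` again, and renormalization can rescale mildly
  affected events upward — so the tests assert the raw-weight theorem, the
  K=2 no-crossing case (where the normalized statement is provable), and
  the density-region statement;
- the dominant anchor displaces *away* from the persuader, its peak is
  enhanced and narrowed (measured as FWHM);
- the revised density has a deep local minimum (below 5% of the dominant
  peak) near the zero crossing of the signed pooled measure;
- with equal anchors, the dispersion inequality of the normal regime is
  reversed: a sharper persuader *widens* the opinion;
- presenting two symmetric persuaders in sequence flips from recency to
  primacy at a crossover `eps* ≈ 2.81` (binary setup, located by
  deterministic bisection).

## Gaussian opinions, latitudes, weighted-average limit

Gaussian opinions `N(mu, sigma^2)` carry the social-judgment zones:
acceptance `|x - mu| <= 2 sigma`, non-commitment the 2–3 sigma shell,
rejection beyond 3 sigma, with masses 95.4%, 4.3%, 0.3% (analytic and
quadrature routes agree to one decimal). Opinions overlapping only in their
rejection zones barely move each other; "negligible" is operationalized as
Hellinger change < 0.05 (the qualitative claim carries no printed number).

For small anchor discrepancy `m = mu_q - mu_p` the full rule reduces to the
weighted-average model: the revised anchor is `w_A mu_p + w_B mu_q` with

    w_B = (1-eps)^2 sigma_p^3 / (eps sigma_q^3 + eps(1-eps) sigma_p sigma_q^2 + (1-eps)^2 sigma_p^3)

derived as the first-order expansion of the rule's stationarity condition;
`w_B` vanishes at `eps = 1`, reaches 1 at `eps = 0`, grows with the
persuader's confidence `1/sigma_q` and falls with the agent's own. In the
boomerang regime the analogous expansion gives a negative `w_B` (the anchor
recoils). The dispersion changes to first order by
`1 ± (1-eps)^2 (sigma_q - sigma_p)/sigma_p` (sign flipped for `eps > 1`).
The tests verify that the predicted shift's relative error against the full
rule at least halves each time `m` halves.

## Distances

Hellinger distance in the [0, 1] convention, `H^2 = 1 - B` with
`B = sum sqrt(p q)` the Bhattacharyya overlap, and total variation
`(1/2) sum |p - q|`, both on unit-mass rescalings. The Gaussian closed form

    H^2 = 1 - sqrt(2 s_a s_b / (s_a^2 + s_b^2)) * exp(-(mu_a - mu_b)^2 / (4 (s_a^2 + s_b^2)))

is cross-checked against adaptive quadrature (scipy.integrate.quad) to
1e-6 on random parameter pairs. The f-divergence family
`D_f(p||q) = sum_k q_k f(p_k/q_k)` is exposed with the three convex choices
that recover twice the squared Hellinger distance (`(sqrt(y)-1)^2`), total
variation (`|y-1|/2`), and Kullback–Leibler (`y log y`; the convention
`0 log 0 = 0`, with `p_k > 0` over `q_k = 0` reported as an infinite
sentinel rather than an exception).

## Repeated persuasion

Iterating the rule with a fixed, everywhere-positive persuader and
`0 < eps < 1` contracts the opinion onto the persuader: every `D_f(p_t||q)`
is a Lyapunov function (non-increasing each step, strictly until the fixed
point), verified per step for all three f choices on 200 randomized runs.
Convergence is declared at Hellinger distance below 1e-8 (default);
monotone-decay assertions use a 1e-12 tolerance and are suspended below a
distance of 1e-6, where `sqrt(1 - B)` hits its floating-point noise floor.

The Le Chatelier property is tracked through the envelope ratios: the
largest `p_k/q_k` decays monotonically and the smallest rises monotonically
(zero violations across all randomized runs). Individual mildly
over/under-estimated events can transiently overshoot, because the extreme
events dominate the early renormalization — the per-event form of the
principle holds unconditionally only for K = 2.

The law of diminishing returns fails: for the archived witness
`p0 = (0.9, 0.0005, 0.0995)` against a uniform persuader at `eps = 0.5`
(found by a deterministic grid search over the 3-simplex, no RNG), the
second persuasion moves the opinion more than the first, in Hellinger and
in total variation.

Repeated persuasion in the boomerang regime splits the opinion: the
rightmost secondary peak migrates monotonically onto the persuader's
anchor (inside his acceptance latitude) while the dominant peak sharpens
and drifts away. With a Gaussian persuader the drift decays only
algebraically (consecutive Hellinger ~ 1/t), because the persuader's tails
never vanish where the escaping peak sits; true stationarity is reached
asymptotically. With a compact-support (bump) persuader the escaping peak
leaves the support and the iteration becomes effectively stationary within
a few hundred steps; the tests assert consecutive changes below 1e-4 and
still decreasing, plus the bimodal structure.

## Change versus discrepancy

With `p = N(0, sigma_p^2)` and `q = N(m, sigma_q^2)` at fixed dispersions,
the opinion change `h(m) = H(p, p~)` is an inverted U: zero at `m = 0`,
maximal at an `m*` inside the prior's non-commitment latitude
(`2 sigma_p < m* < 3 sigma_p` for mid-range eps), and decaying for larger
discrepancies as the overlap vanishes. At small eps the dominant anchor
jumps discontinuously back toward the prior when a sub-dominant peak
overtakes the shifted one; the detector flags an adjacent-step change in
anchor shift exceeding 5x the local secant slope (with a floor of two grid
spacings to be robust to resolution). With equal anchors and the
discrepancy driven by `sigma_q` alone, the change is monotone in the
discrepancy, in Hellinger and in total variation.

## Numerical choices

- **Grids.** Figure-style runs use 100 points; quantitative tests use
  1201–8001 points spanning every anchor ± 6 dispersions. Quadrature is
  trapezoid throughout; grid self-convergence from ~100 to ~2000 points
  changes a revision by less than 1e-3 in Hellinger distance.
- **Bump family.** `C_b exp(-b/(1-x^2))` on (-1, 1): infinitely
  differentiable, exactly zero outside the support, near-Gaussian for large
  `b`, near-uniform for small `b`; `C_b` is computed by adaptive quadrature
  (no closed form assumed).
- **Anchors.** Strict interior local maxima, plateaus collapsed to their
  midpoint, positions refined by local quadratic interpolation; peaks below
  a height fraction of the global maximum (default 1–2%) are ignored.
- **Dissonance classification.** Two peaks of comparable height (ratio
  within 3) are "dissonant"; otherwise the dominant peak's proximity to the
  old or new anchor labels the outcome dominated-old / dominated-new.
- **Validation tolerances.** Input weight sums must match the declared
  total mass to 1e-9 relative; grid densities must integrate to 1 within
  1e-6; outputs are renormalized exactly. Mixing different total masses is
  an error, never a silent rescale, because the axioms require a common
  normalization.
- **Determinism.** Every scenario in the catalogue and every scan
  (bisection for the primacy crossover, the simplex search behind the
  diminishing-returns witness) is deterministic; randomized suites take
  explicit seeds. JSON output uses 17 significant digits so byte-identity
  checks are meaningful.

## What the synthetic scenarios do and do not show

All inputs are synthetic: parametric opinions and randomized Dirichlet
weight vectors. They exercise the operator's mathematics — axioms, limits,
convergence, order effects — not the fit of the model to human data. The
scenario catalogue's parameter sets (opinion shift, reinforcement,
dissonance, boomerang) are deterministic witnesses chosen by scans to
exhibit each phenomenon clearly; no claim is made that they match any
particular experimental setting. Known limitations: one-dimensional event
spaces only; no long-term-memory mechanism (so the model produces primacy
only in the boomerang regime); the boomerang rule is non-smooth at the
signed measure's zero crossing, and for `eps > 2` a zero prior weight makes
the continuation's first exponent negative (handled by the zero-preservation
convention, but the regime `eps > 2` should be treated as formal).
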