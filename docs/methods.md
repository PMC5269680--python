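# Methods

## Model

The object of study is the distribution of start-to-start distances between
consecutive occurrences of a DNA word within a scope (a chromosome-scale
sequence, a pooled set of regions such as gene-upstream windows, or the
starts of variable-length genome elements).  Occurrence scanning is
overlap-inclusive and forward-strand only; matching is exact over A/C/G/T
and windows containing N never match.

Under letter independence the distances are geometric,
P(d) = ω(1−ω)^{d−1} with ω the product of the word's letter probabilities,
so the survival curve is exponential with characteristic distance
x₀ = 1/|ln(1−ω)|.  Clustered words deviate from this null in the tail; the
fitted model is the q-exponential survival curve

    C(d) = e_q(−(d−1)/x₀),    e_q(x) = [1 + (1−q)x]^{1/(1−q)},

whose entropic index q measures the clustering level (q = 1 is the
exponential limit; q > 1 gives a d^{−1/(q−1)} power-law tail).  Words are
ranked by fitted q alone; R² and RMS are reported but never used for
ordering, and non-converged or undersampled words are appended below the
ranking with a reason rather than interleaved.

## Conventions and numerical choices

- **Distance** = start-to-start difference in bp; the minimal conceivable
  distance is 1 (overlapping occurrences).  An end-to-start "gap" mode
  exists for element-interval analysis.
- **Survival orientation** P(D ≥ d): the first plotted/fitted point is
  exactly 1.  The null closed form is written with the same anchoring,
  P(D ≥ d) = (1−ω)^{d−1}, so both curves equal 1 at d = 1.
- **Fit protocol**: residuals over the distinct observed distances (one
  point per distinct distance, unweighted), in linear CCDF space by default
  (log10 space available), minimised with a bounded trust-region
  least-squares (q ∈ [1, 3.5], x₀ > 0; cost/step tolerances 1e-10, at most
  10⁴ evaluations).  q is initialised at 1.5 and x₀ from a log-linear
  exponential pre-fit.  The model is anchored as e_q(−(d−1)/x₀) to match
  the empirical anchor at the minimal distance; an offset-free form is
  available.  Fits are deterministic: same input and configuration give
  bitwise-identical results.
- **q-family numerics**: within |q−1| < 1e-12 the exact exp/log limits are
  used; e_q is evaluated through log1p so the q → 1 limit stays accurate;
  the Tsallis cutoff (bracket ≤ 0, only reachable for q < 1) returns 0 so
  the function is total.
- **q-log diagnostic**: transforming the empirical survival values with the
  fitted q and regressing on d by OLS should give a straight line
  (slope −1/x₀ for the offset-free form).  Because ln_q amplifies the
  relative sampling error of a survival value c by roughly c^{−q},
  extreme-tail points supported by fewer than `min_tail_count` (default 30)
  observations are excluded from the regression; with them included the
  diagnostic measures tail noise, not curvature.
- **Minimum sample**: survival curves are only built from ≥ 50 distances
  (configurable); smaller samples are refused explicitly.
- **N handling**: words never match across N, but coordinates (hence
  distances spanning short N stretches) stay in true bp; N-runs of ≥ 1000
  bp (assembly-gap scale, configurable) split the scope so no distance
  bridges them.  Region-restricted analysis likewise never lets a distance
  bridge two regions.
- **Upstream windows** default to 2000 bp, strand-aware and clipped at
  chromosome bounds.  This width is a declared default — the appropriate
  promoter span is organism- and question-dependent — and overlapping
  windows of adjacent genes are not merged.

## Synthetic data: what it emulates and what it does not

The generators provide the three regimes the method's claims rest on.

1. `random_genome` — i.i.d. letters with chosen probabilities: the null in
   which every word should fit q ≈ 1.
2. `sample_q_exponential_distances` — inverse-transform sampling
   d = max(1, ⌈−x₀ ln_q(u)⌉), u ~ U(0,1].  The ceiling discretisation gives
   exactly P(D ≥ d) = e_q(−(d−1)/x₀), the fitter's own convention, so
   parameter recovery is a clean closed loop.
3. `planted_cluster_sequence` — realises such a distance sample as an
   actual sequence.  In exact mode the gaps are filled from the letters the
   word does not use, so no window containing filler can match, and each
   sampled distance is clamped up to the nearest "clean" value — one at
   which two copies of the word provably create no accidental third
   occurrence (precomputed per word by constructing the two-copy string and
   scanning it; relevant only for self-overlapping words like AA).  The
   construction is verified by re-scanning, so planted positions are exact
   ground truth.  In contaminated mode the filler uses all four letters
   with chosen background probabilities and chance occurrences are accepted
   as real — the realistic regime for ranking experiments, where the
   planted word sits *among* background words.

What the synthetic regimes deliberately do not emulate: isochore-scale
composition heterogeneity, repeats, and multi-word joint structure.
Passing tests on them demonstrate the estimator and ranking machinery, not
claims about any particular genome.

### Study conditions used by the tests and the acceptance script

- Null calibration: 1 Mb uniform i.i.d. sequence; CG yields ~6×10⁴
  distances.
- Parameter recovery: q ∈ {1.1, 1.3, 1.5, 1.8, 2.2} × x₀ ∈ {20, 50, 200}
  at n = 10⁵ distances; recovery within |Δq| ≤ 0.05 and |Δx₀/x₀| ≤ 10%,
  strictly monotone in the planted q.
- Shuffle contrast: planted CG with q = 1.8, x₀ = 20 bp, 2×10⁴ occurrences
  (≈1.8 Mb).  x₀ = 20 keeps the sequence CG-dense enough that the shuffled
  baseline still yields ≥ 50 distances to fit.
- Ranking power: planted CG (q = 1.8, x₀ = 20, 10⁴ occurrences) in a
  CG-sparse i.i.d. background (P(A)=P(T)=0.47, P(C)=P(G)=0.03), ten
  replicates.  The background must be CG-sparse for the oracle to be valid:
  see below.

## Known limitations and honest caveats

- **Self-overlapping words clump under the null.**  In an i.i.d. sequence
  the homodimers AA/CC/GG/TT have an excess of distance-1 recurrences
  (runs), which the free-q fit absorbs as q ≈ 1.25–1.3.  The q ≈ 1 null
  statement is exact only for non-self-overlapping words; rankings should
  compare homodimers against homodimers, or against a shuffled baseline of
  the same sequence, which reproduces the same artifact level.
- **The geometric closed form is an approximation even for
  non-self-overlapping words.**  The exact i.i.d. law of inter-CG distances
  is phase-type (first-passage of a 2-state letter chain): its decay
  eigenvalue is (1+√(3/4))/2 ≈ 0.9330, not 1−ω = 0.9375, and the minimal
  distance is 2, not 1.  Consequently the empirical null CCDF differs from
  (1−ω)^{d−1} by up to ω = 0.0625 at the head (and by ~0.025 even after
  aligning the support by one position).  The closed form remains the right
  intuition and the exponential *family* still fits the null extremely well
  (free-q fits land at q = 1.00); only the literal (1−ω)^{d−1} curve with
  theoretical ω should not be expected to match within ~0.03.
- **Shadow clustering in planted constructions.**  If a clustered word is
  planted on a filler alphabet excluding its letters, boundary words (the
  filler-word junction dimers, and GC inside adjacent CGCG) occur *only*
  near planted copies and are therefore genuinely clustered — a correct
  ranking puts them high too.  Ranking-power experiments therefore use the
  contaminated construction with a background in which those boundary words
  are common and random.
- **Protocol sensitivity.**  Fitted q values depend on the weighting
  convention (one point per distinct distance here), the fit space, and the
  model anchoring; cross-study comparisons of absolute q values are only
  meaningful under one fixed protocol.  Ordinal claims (word A more
  clustered than word B) are robust in our experiments.
- No reverse-complement folding, no IUPAC ambiguity codes, no
  maximum-likelihood estimation of the discrete law, and no confidence
  intervals for q (bootstrap is future work).
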