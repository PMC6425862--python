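# Methods

## Model and procedure

The analysis asks a categorical question per gene — is its diel expression
concentrated in the dusk window, the dawn window, or neither? — and a
comparative question per ortholog group — is the CAM species' gene scheduled
opposite to its C3 orthologs?  There is no continuous phase estimation
(no cosinor/JTK-style fitting); the two 3-hour windows are the unit of
inference, which keeps the procedure robust to waveform shape and directly
comparable across species with different light regimes.

### Preprocessing

* **Resampling.**  A species sampled every 4 h is brought onto the common
  2-h grid per gene with a cubic spline, not-a-knot boundary.  Not-a-knot
  reproduces any cubic polynomial exactly, which gives a sharp test oracle
  and behaves well on smooth unimodal diel waveforms.  Knot values are
  preserved bit-for-bit.  Hour 22 lies beyond the last 4-h knot (20 h), so
  it is filled by the natural polynomial extension of the last spline piece
  rather than a periodic wrap; for smooth profiles the extension error is
  far below the ranking granularity the downstream statistics use.  Negative
  interpolants at *inserted* hours are clamped to 0 and counted in the run
  manifest, so resampling can never delete a gene; genes with negative
  *observed* values are removed afterwards.
* **Filtering.**  Genes with mean FPKM < `min_mean_fpkm` (default 0.01) or
  with at least `max_zero_fraction` (default one half) of their sampling
  points exactly zero are dropped.  The filter is idempotent and
  order-preserving.
* **Normalization.**  Each retained profile is converted to integer
  pseudo-counts `c_t ≥ 0` with `Σ c_t = C` (default `C = 1000`) by
  largest-remainder rounding of `C·x_t/Σx`.  This makes the enrichment test
  purely shape-based: the counts are invariant under positive rescaling of
  the profile.  Sensitivity to `C`: the window sums scale linearly with `C`,
  so the hypergeometric test becomes more powerful as `C` grows (more
  "observations" per gene) and more conservative as it shrinks; `C = 1000`
  puts roughly 80 counts per 2-h time point, enough that rounding error
  (±0.5 counts per cell) is negligible against sampling noise, while keeping
  tail sums cheap to enumerate.  `C` is exposed as `normalization_scale` and
  should be held fixed within a study; changing it changes power, not the
  direction of any call.

### Window enrichment

For gene *g* and focal window *W* the 2×2 table is
`[[S_W(g), S_opp(g)], [Σ_W − S_W(g), Σ_opp − S_opp(g)]]`, with `Σ` the
column totals over all genes of that species.  The right tail
`P(X ≥ S_W(g))` under the hypergeometric law with those margins is summed
directly in log-factorial (gammaln) form over the support — exact to
floating precision for any table size (verified against rational-arithmetic
enumeration).  The table orientation lives in one small function
(`_contingency_table`) so an alternative layout is a one-line change.

Benjamini–Hochberg is applied separately to the dusk p-vector and the dawn
p-vector of each species; a null is rejected iff its q-value ≤ α
(equivalently, the classic step-up rule), α = 0.05 by default.  A gene
rejected in both windows — possible only in pathological margins — takes
the window with the smaller q-value; an exact tie falls back to `neither`
with a warning.  Both windows rejected and ties are logged because neither
case arises under the intended data-generating process.

### Rescheduling calls

Spearman's ρ is the Pearson correlation of mid-rank vectors, computed with
exact integer arithmetic on doubled mid-ranks so that perfectly monotone
(or anti-monotone) trios return exactly ±1 rather than 1 − 1 ulp; this
matters because the planted-truth invariants assert exact ±1 and the ±0.6
thresholds are strict inequalities.  Constant profiles have no defined rank
correlation; such combinations are excluded and logged rather than guessed.

Correlations default to the raw (post-interpolation, pre-normalization)
profiles on the common 2-h grid; since Spearman is rank-based, any
within-gene monotone transform — including the pseudo-count normalization up
to rounding ties — gives the same value, and `rho_on: normalized` is
available to verify exactly that.

Groups with several genes per species are evaluated over every
(CAM, C3-a, C3-b) combination; the group is *rescheduled* if any combination
passes both criteria, and all combinations are written out so stricter
aggregation rules (e.g. all-combinations-pass) can be applied downstream
without rerunning.  "Opposite window" is resolved by label, not hour
arithmetic, because the tomato-regime dusk window (8, 10, 12) sits at
different clock hours from the 12-h-photoperiod dusk window (10, 12, 14).

### Literature-hit filtering

Keyword matching is case-insensitive plain substring ("stomata" matches
"stomatal"); a regex mode is provided for word-boundary-sensitive scans.
The E-value threshold (default 1e-3) is inclusive.  Filtering is idempotent
and monotone in the threshold.  The three-way partition reports all seven
Venn regions; the *underexplored* set is the literature-mined set minus the
union of the annotated and known sets.

## Synthetic studies

The generator emulates the processed form of real diel RNA-seq data:

    x_t = baseline · (1 + A·(1 + cos(2π(t − peak)/24))/2) · exp(ε_t),
    ε_t ~ N(0, σ²)

with defaults baseline 10 FPKM, amplitude ratio A = 3, σ = 0.2, 200 ortholog
groups of which 20 are planted anti-phase (CAM peak hour 12, C3 peak hour 0),
grids of 2 h / 2 h / 4 h across the three species, and 300 background genes
per species with peaks drawn uniformly on [0, 24).  The background matters:
the enrichment test compares each gene to the transcriptome-wide dusk/dawn
balance, so a transcriptome of focal genes alone (all sharing one phase)
would make every table match its margins and no gene significant.  Phases
spread around the clock are also what real diel transcriptomes show.

The cosine is evaluated through the circular distance to the peak, which is
mathematically identical to `cos(2π(t − peak)/24)` but makes hours
equidistant from the peak bit-identical — without this, IEEE `cos` breaks
rank ties asymmetrically and noise-free anti-phase trios come out at
ρ ≈ −0.993 instead of exactly −1.

What the generator does **not** emulate: count-based sampling noise
(FPKM-level overdispersion is approximated by log-normal noise),
non-sinusoidal waveforms, inter-gene correlation, day-to-day variation, or
genes absent from the annotation.  Passing tests therefore demonstrate that
the inference machinery recovers planted schedule shifts under realistic
amplitude and noise, not that any particular biological dataset would yield
a particular gene list.

## Numerical choices

* Largest-remainder ties (equal fractional parts) break toward earlier
  time points, deterministically.
* `bh_fdr` rejects at q ≤ α; with the standard q-value definition this is
  the exact step-up rule (strictly-less would drop boundary rejections such
  as p = (0.01, 0.02, 0.03, 0.04) at m = 5, α = 0.05).
* Hour 24 is canonicalized to hour 0 everywhere at parse time, so the dawn
  window {22, 24, 2} is stored as {22, 0, 2}.
* Result tables render statistics at 6 significant digits; expression
  matrices are written with shortest round-trip `repr` and re-parsed with
  Python's exact `float()`, making write→read the identity.
* All randomness flows through a single seeded `numpy` Generator per study;
  identical specs produce byte-identical study files.  Cross-platform
  bit-identity of floating-point noise is not promised; statistical tests
  use seeds plus tolerances.

## Problem sizes

The planted-truth evaluation uses ten studies of 200 groups + 300 background
genes across three species, and the null evaluation ten studies of 500 flat
genes, chosen to put a few thousand exact tests and several hundred
rescheduling verdicts behind each reported rate while keeping a full
evaluation in the tens of seconds on a single core.

## Known limitations

* The contingency-table orientation and the pseudo-count normalization are
  this package's own concrete choices for steps often left unstated in
  comparative diel analyses; both are isolated and configurable, and all
  intermediate artifacts are written so the effect of alternatives is
  auditable.
* The design is fixed at one CAM species versus exactly two C3 species.
* The 4-h → 2-h resampling extrapolates one boundary hour (22) rather than
  wrapping periodically; for strongly non-smooth profiles this is the least
  trustworthy grid point.
* Window-enrichment p-values treat pseudo-counts as hypergeometric draws;
  multiplicative noise makes them mildly over-dispersed, so the per-gene
  p-values are approximate even though FDR control holds comfortably in the
  null simulations.
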