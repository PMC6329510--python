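# Methods

## The model

The package simulates a speech-communication loop between a fixed **master
agent** and independently developing **learner agents**, over a joint
probabilistic model of five variables — speaker object `O_S`, gesture `M`,
sound `S`, listener object `O_L`, and a communication-success switch `C`:

    P(C, O_S, S, M, O_L) = P(O_S) P(M | O_S) P(S | M) P(O_L | S) P(C | O_S, O_L)

Objects are the seven vowels /i u e o ɛ ɔ a/ with a uniform prior.  Gestures
live in a 3-D articulatory box (lip height, tongue body, tongue dorsum,
normalized to [−1, 1]); sounds are (F1, F2) points on the Bark scale,
`F[Bark] = 7·asinh(F[Hz]/650)`.  `P(C=1 | O_S, O_L)` is 1 iff the two
objects coincide, so conditioning on `C = 1` couples speaker and listener.

All learned conditionals are Gaussian: a per-vowel sound Gaussian
(`P(S|O_L)`, the sensory repertoire), a sound Gaussian per discretized motor
cell (`P(S|M)`, the internal forward model), and a per-vowel gesture
Gaussian (`P(M|O_S)`, the motor repertoire).  Inference is grid-based: the
motor box is discretized to `levels³` cells (25³ = 15,625 at full scale) and
the formant plane to 59×73 points covering the forward image plus a 0.5-Bark
margin.

### The forward map

The articulatory-to-acoustic map `s = f(m)` is pluggable.  The default
surrogate composes two logistic response surfaces,

    F1_Hz = 250 + 450·σ(−1.2·x₁ − 1.8·x₃)
    F2_Hz = 700 + 1800·σ(0.8·x₁ − 1.6·x₂ + 0.4·x₃),

converted to Barks.  It is smooth, deterministic, and many-to-one (each
sound has a 1-D preimage family), which is all the downstream results rely
on.  The coefficient signs are conventions.  An affine variant
(`LinearForwardModel`) is provided for analyses that need an exactly
Gaussian-representable environment (see "Ideal learning" below).

The default acoustic targets for the master's vowels approximate French
vowels *projected into the surrogate's reachable image*: the two logistic
ranges cannot reach natural back-vowel acoustics (low F1 together with low
F2), so /u o ɔ/ sit at the compressed back corner of the image.  Any seven
in-image targets more than ~1 Bark apart behave equivalently.

### The master agent

Per vowel: motor mean = the motor grid cell whose image best matches the
target; motor covariance `0.1·I₃`; gesture draws are clipped to the box.
Every emitted sound receives environmental noise of variance
`σ_Env = 0.01 Bark²` per formant.  The master's own categorizer is a Bayes
rule over per-vowel sound Gaussians calibrated once by pushing 20,000
fixed-seed draws (seed 7919) through the forward map, so all learners in an
experiment face an identical master.  With the compressed back corner the
calibrated /u o ɔ/ distributions overlap more than three pooled standard
deviations — the fitter warns about each such pair rather than failing.

## Learning

Three strictly sequential phases, default 300,000 steps each (full scale) or
30,000 (desk scale).  Every repertoire entry is an online Gaussian: count,
mean, and scatter updated Welford-style, exactly equal to the batch sample
statistics of all observations pooled with the prior pseudo-observation.
Covariances get an additive diagonal ridge (`variance_floor = 1e−4`), which
keeps them positive definite even when every observation coincides.

1. **Sensory.**  Supervised pairs (o, s) from the master update the
   per-vowel sound Gaussians.
2. **Sensorimotor accommodation.**  The learner hears a master sound s,
   draws a cell from `P(M|s) ∝ P(s|M)` (uniform cell prior), produces it,
   and updates that cell with its own output `f(m)`.  Self-audition is
   noiseless, so a cell only ever observes its own image and its variance
   collapses toward the floor as visits accumulate.
3. **Motor.**  Two variants.  *Imitative*: draw a cell from
   `P(M|o, s) ∝ P(M|o)·P(s|M)` and record it unconditionally.
   *Communicative*: draw from `P(M|o, C=1) ∝ P(M|o)·A(m, o)` with the
   acceptability plateau `A(m, o) = Σ_S P(S|m)·P(O_L=o|S)` (grid sum with
   the cell density renormalized over the sensory grid; `P(o|S)` from Bayes
   inversion of the learned sensory repertoire), then produce the sound with
   environmental noise and record the gesture only if the master categorizes
   it as o.  The plateaus are frozen at phase start — the systems they
   depend on no longer change.

All categorical draws are computed in log space with max subtraction; total
underflow falls back to a uniform draw (an unexplored region).  Each agent
owns one PCG64 generator seeded `base_seed + agent_index`; draws occur in a
fixed order (object, master gesture, noise, learner gesture), so a run is
bit-reproducible from its configuration.

### Priors

All entries of a system share one broad prior so that inference before
learning is exactly uniform.  The per-vowel repertoires use pseudo-count 1
with covariance `diag(half_extent²)` of their space.  The per-motor-cell
internal model uses pseudo-count 0.02 with the same shape: a cell receives
only tens of visits (steps / n_cells), and a unit-weight whole-space prior
would keep its sound covariance at the Bark scale for the entire run —
wiping out the acoustic precision of imitation that the model is supposed
to exhibit.  With the light prior a visited cell's covariance collapses to
the observation scale within a few visits while untouched cells keep the
full-width prior.

## Perception

Three decoders map a sound to a vowel posterior (uniform prior):

* **auditory** — `P(o|s) ∝ P(s | O_L=o)`, Bayes inversion of the sensory
  repertoire;
* **motor** — `P(o|s) ∝ Σ_cells P(cell|o)·P(s|cell)`, with `P(cell|o)` the
  motor-repertoire density on the grid normalized to a categorical;
* **perceptuo-motor** — the entrywise product of the two unnormalized
  scores, renormalized (conditioning on `C = 1`).

Whole-grid categorization maps take the argmax per sensory cell, ties to
the lowest vowel index.

### Prototypes

*Production*: the exact grid expectation of `f` under the normalized motor
repertoire density — the deterministic limit of the sample-and-average
procedure.  *Perceptual*, two definitions:

1. **Distribution means** (used for the regression tables): the mean of each
   decoder's predictive sound distribution — the sensory-repertoire mean
   (auditory), the weighted mean of per-cell sound means (motor), and the
   grid mean of the renormalized product density (perceptuo-motor).  The
   motor mean is conditioned on *explored* cells: never-visited cells still
   carry the grid-centered prior, and including them would drag every
   prototype toward the grid center by exactly the unexplored mass — an
   artifact of the prior's location, not a model prediction.
2. **Categorization-region means** (`*_map` channels): the unweighted mean
   of the sensory cells a decoder labels with the vowel, over the whole
   grid.  Region means are far noisier across agents because region
   boundaries and the grid margins move with small changes in the learned
   densities; they are reported for completeness but not regressed.

### Relative F1 and regressions

Per agent and channel, F1 values are rescaled so the high-vowel mean
(average of /i u/) maps to 0 and /a/ maps to 100; the four mid vowels
/e ɛ o ɔ/ are then compared across agents.  For each mid vowel and each
perception channel we fit ordinary least squares of perceived on produced
relative F1 across the 12 agents and report slope, intercept, and Pearson r.
Idiosyncrasy magnitude is summarized as the per-vowel mean Euclidean Bark
distance between agent production prototypes and the master's calibrated
prototypes, plus the over-vowel mean.

## Ideal learning and decoder equivalence

When the learner's systems are set analytically to the master's generative
truth (`make_perfect_learner`), the auditory and motor decoders should carry
the same information.  With Gaussian repertoires this holds exactly only
when the environment's per-vowel sound distributions are themselves
Gaussian, i.e. when the forward map is affine.  The equivalence test
therefore uses the `LinearForwardModel` with interior motor prototypes and
closed-form calibration, and compares posteriors on the support of the
environment's sound distributions (maximum vowel density above `e⁻⁴`):
outside the support both decoders merely extrapolate tails, and a truncated
mixture tail and a Gaussian tail diverge arbitrarily.  On-support, the
maximum absolute posterior difference is below 0.02 (0.004 at 21 motor
levels).  With the nonlinear surrogate the Gaussian repertoire is
misspecified and the decoders become measurably distinguishable — the
"normal conditions" regime in which idiosyncrasies can propagate to
perception at all.

## Scales, run time, and the desk preset

The `full` preset reproduces the reference conditions: 25³ motor cells,
300,000 steps per phase, 12 agents per variant.  The `desk` preset — the
default, and what the tests and the acceptance script use — runs 15³ motor
cells and 30,000 steps per phase with the same 59×73 sensory grid, 12
agents, and both variants; one full desk experiment takes roughly five
minutes on one CPU.  The tenfold reduction preserves the qualitative
regime: sensory repertoires converge (mean error ≪ 0.1 Bark), motor cells
relevant to the vowels are visited tens to hundreds of times, and all
headline statistics (distance ratio, decoder slopes, correlations) match
the full-scale structure.

## Known limitations

* The surrogate's compressed back corner places /u o ɔ/ prototypes at the
  articulatory box faces.  About half of the master's noisy emissions for
  those vowels fall outside the learner's reachable image, and the
  inversion folds them back inward; this biases imitative reproduction of
  the corner vowels by ~0.05 Bark (pure bias, not sampling noise — it does
  not shrink with more steps).  Mid vowels imitate to 0.02–0.03 Bark.
* The environment is a single fixed master; idiosyncrasies measured here
  are by construction "free" (not inherited).  Multi-master environments,
  corrective feedback, interleaved or lifelong learning, and speaker
  normalization are out of scope.
* The synthetic world has no inter-trial articulatory variability, no
  age- or sex-related vocal-tract differences, and only two formants, so
  passing tests demonstrate the internal consistency of the mechanism — not
  that human idiosyncrasy data would be fit quantitatively.
* Serialization stores full agent state as JSON (a few MB per agent at full
  scale); binary payloads were not needed at these sizes.
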