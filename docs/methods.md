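# Methods

## The dyadic assay and its statistics

A dyad is a pair of flies in opposite semicircular compartments of a
30 mm circular arena bisected by a 1.5 mm barrier. Coordinates are in
millimetres with the origin at the arena center and the barrier along
the y-axis; each compartment's barrier *face* is the chord-parallel
segment offset half the barrier thickness into that compartment, so
"distance to the barrier" is compartment-local: the Euclidean
point-to-segment distance from the fly's centroid to its own face
(14.25 mm at the pole of a default arena; laterally beyond the chord
endpoints the nearest endpoint governs). Positions outside the arena
circle are flagged out-of-bounds and dropped as invalid by the metric
layer rather than clipped.

The **interactivity index** is the Pearson correlation of the two
flies' distance series over the whole session, with pairwise deletion
of frames where either fly is untracked and no detrending. It is
undefined — and the dyad is excluded with a recorded reason, never
silently scored zero — when fewer than 3 paired frames remain, when
either series has zero variance, or when either fly is immobile
(session-mean speed at or below the 0.1 mm/s threshold; a constant
distance series has no variance to correlate).

A **coincidental approach** is a maximal episode with both flies
simultaneously within one body length (3 mm, closed boundary: the
permissive reading of "within") of the barrier; each episode scores one
event regardless of duration, and a new event requires at least one fly
to have left the zone in between. Untracked frames are treated as
unknown: they neither extend nor end an episode, so co-occupancy runs
separated only by dropouts merge — dropouts cannot fabricate exits.
Counts are normalized by the dyad mean speed (grand mean of the two
flies' session-mean speeds).

## Null models and inference

The shuffled-pair null re-pairs flies recorded in the *same session*
into perfect matchings that contain no true dyad, and recomputes the
index on the time-aligned series of each fictive pair. Pairing across
sessions is disallowed because the index is a temporal correlation.
Two modes exist — side-preserving (left flies re-paired only with right
flies of other arenas, emulating a physical reshuffle of one side) and
side-free (any cross-pairing) — since either convention is defensible;
side-free is the default. Matchings are drawn by seeded rejection
sampling with a bounded retry budget.

Observed-vs-null distributions are compared with the two-sample KS test
using the asymptotic Kolmogorov p-value (effective n = n_x·n_y/(n_x+n_y));
this is accurate for the tens-of-dyads samples in scope and a documented
approximation for very small ones. Group contrasts of mean |index| use
Welch's unequal-variance t-test (the robust default where the variance
structure is unknown) with Bonferroni adjustment. Bootstrap standard
errors are the SD (n−1 denominator) of the statistic over 1000 seeded
resamples at original size.

Day-to-day persistence is the Pearson correlation of per-dyad indices
between two days (identity-matched intersection; per-dyad day means when
a day has several sessions), tested as z = atanh(r)·√(n−3) against the
standard normal. Signed indices are the default — the scatter of
interest is signed — with an absolute-value mode exposed. For designs
with many sessions, per-dyad means over the first and last two sessions
give one early and one late value per dyad.

## SIN construction

The connection threshold is the mean of the first and third quartiles
of all dyads' absolute indices, with quartiles by linear interpolation
between order statistics (the type-7 convention, the dominant default;
the convention is recorded in the graph's `threshold_rule` attribute).
Edges require |index| strictly above the threshold; isolates are kept.
Because the threshold lies between Q1 and Q3, the edge fraction on
continuous index populations falls in [0.25, 0.75]. Applying one day's
threshold to a later day is supported and recorded, so repeat networks
are comparable; overlap is reported as shared-edge count and Jaccard
index (defined as 1 when both edge sets are empty, flagged degenerate).

## Trajectory handling

Trajectories are per-fly, per-session frame series at 29.9 fps. Tracking
dropouts up to `max_gap_frames` (default 15, ≈0.5 s — short enough not
to fabricate approaches) are filled by linear interpolation and marked
imputed; longer gaps and gaps touching the track ends stay invalid.
Whether imputed frames enter the index is configurable (`use_imputed`,
default on), since either convention is defensible. Per-step speed is
displacement × fps / frame-gap; steps touching an invalid frame are
excluded from means. Immobility is assessed per fly per session, and a
dyad is discarded if either member is immobile.

## The synthetic generator

Each fly performs a reflected Gaussian random walk (per-axis step SD
0.5 mm/frame) confined to its compartment, with a small constant drift
(0.01 mm/frame) toward its barrier face. Social coupling adds drift
κ·s(d_partner), where s is a logistic function of the partner's barrier
distance with half-saturation at one body length (3 mm) — chosen so the
coupling acts exactly where coincidental approaches are scored — and κ
routes through the two sensory channels:

    κ = (w_vision·[barrier clear]·[both see] +
         w_olfaction·[barrier open]·[both smell]) · coupling term

Genotype profiles mask channels (anosmic: olfaction off; blind: vision
off) or widen the latent-sociability spread (low-acuity profile,
emulating the higher inter-dyad variability of white-eyed flies). In
experiment mode the coupling term is the product of the two flies'
latent sociabilities, drawn standard-normal and evolved across days as
a stationary AR(1) with parameter ρ (`persistence_rho`), so both
coupling signs occur, degree heterogeneity is realistic at the fly
level, and the expected day-to-day coupling correlation is ρ². The
generator also produces immobile flies (probability 0.03 per
fly-session, sub-threshold jitter — matching the ~3% discard rate of
the real assay) and per-frame dropouts (probability 0.005).

Channel weights default to w_vision = 0.015, w_olfaction = 0.20
mm/frame, fixed once by `calibrate_channel_weights` (a coarse grid
search shipped with the package) so that simulated group means
reproduce the assay's qualitative ordering: open-clear wild type
highest; anosmic flies behind open-clear barriers at roughly a third of
the wild-type mean |index| (mirroring the strong reduction reported for
olfactory mutants); solid-black at the null level; and the blind
profile close to wild type. An additive channel model cannot
simultaneously make vision the dominant channel *and* reproduce that
large olfactory-knockout effect, so the weights favour olfaction; the
barrier ordering open-clear ≥ open-black holds by construction either
way.

Numerical points of the integrator: the first 500 steps are discarded
as burn-in — without it, the shared relaxation from the uniform start
toward the attraction equilibrium positively biases the index of even
fully uncoupled dyads (measured +0.03; with burn-in, κ=0 gives mean r
= +0.004 ± 0.006 over 600 dyads). Boundary handling is reflection at
the face plane and radially at the circular wall (three passes), with a
final exact projection guaranteeing containment. All generators are
pure functions of their seed; batches integrate many dyads in lockstep
for speed.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analyses assume:
barrier-distance coupling with controllable sign and strength, sensory
gating, day-persistent individuality, immobility, dropouts, and the CSV
dialects of the pipeline. It does not attempt biomechanically realistic
locomotion — simulated speeds (~18 mm/s) are faster than real walking
flies so that desk-scale sessions (default 10,000 frames, ≈5.6 min at
29.9 fps, vs the 1 h assay) mix well; pheromone diffusion and visual
fields are not modelled. Passing tests therefore validate the analysis
chain and its statistical behaviour, not any biological claim about
real flies. Two quantitative consequences worth knowing: the null
|index| has a floor set by the walks' autocorrelation (mean |r| ≈ 0.09
at 10,000 frames), and the index response to fixed coupling is
non-monotone at large κ — very strong attraction pins both flies at the
barrier and *compresses* distance variance — so group differences are
calibrated in the latent-coupling regime, and sign-recovery accuracy
(not |r|) is the monotone readout of coupling strength.

## Y-maze metrics

The turn classifier is reconstructed from the arena geometry (arms
15.5 mm, 120° apart, 5.2 mm circular ends): frames are assigned to the
nearest arm's 120° sector; an arm visit registers on entering the arm's
distal half (the stricter of the defensible entry rules, configurable
via the maze spec); consecutive distinct visits yield one turn, rightward
when the new arm is the clockwise neighbour. Any consistent convention
gives the same bias distribution up to a global L/R flip. Turning bias
is #R/#total, undefined (fly excluded) with no turns. Speed-distribution
KDEs use Gaussian kernels with Silverman's rule on a fixed grid spanning
the data ± 3 bandwidths; the 95% band is the pointwise 2.5/97.5
percentile over bootstrap resamples re-estimated under the same rule.

## Pairing designs

Scheme 1 is a seeded random perfect matching; scheme 2 samples a simple
k-regular pairing graph by pairing-model construction (any simple
k-regular graph is admissible under the design's description); scheme 3
is all C(n,2) pairs, scheduled by the classical circle method —
(n−1)·repeats rounds of n/2 disjoint dyads, every dyad exactly once per
block — which is the canonical deterministic choice where the original
schedule is unspecified. Multi-session scheme-2 runs cover the pairing
graph by greedy maximal matchings. Odd fly counts (bye rounds) are not
supported.

## Problem sizes

Defaults were chosen at desk scale as the package's own study
conditions: 10,000-frame sessions, 100–200-dyad calibration batches,
and 2-day persistence experiments; the full-length 1 h session
(~107,600 frames) is a config option. The acceptance script runs the
whole chain at these sizes in well under a minute.

## Known limitations

- The KS p-value is asymptotic; tiny samples should use an exact test
  elsewhere.
- The quartile convention for the SIN threshold is type-7 by choice;
  other conventions shift the threshold slightly on small populations.
- The shuffled null excludes only true pairings; flies sharing an arena
  wall with a fictive partner are not treated specially.
- Simulated speeds and session lengths are scaled for desk use (above);
  absolute index magnitudes are therefore not comparable to the real
  assay, only their contrasts and orderings.
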