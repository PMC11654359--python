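# Methods

This note documents the models, conventions and design choices behind
`roachtrack`, in the order data flows through the package.

## Coordinates, arena and calibration

Pose tracks are pixel coordinates in image convention: origin top-left, x
rightward along the runway's long axis, y downward, frames 0-indexed. A
missing detection is NaN in both members of an (x, y) pair; a half-missing
pair is rejected at validation. The HDF5 layout mirrors the analysis export
of common pose-estimation tools (`tracks`: n_tracks × 2 × n_nodes ×
n_frames; `node_names`; `fps` as a file attribute, falling back to 60 when
absent).

The arena is a rectangle in pixel space with known physical size (default
24 × 4 in = 60.96 × 10.16 cm). One isotropic calibration,
`pixels_per_cm = (x_max_px − x_min_px) / length_cm`, converts both axes;
anisotropic pixels and lens distortion are out of scope. The runway is
partitioned into `n_zones` (default 4) equal half-open intervals along x;
positions left of the runway clamp to zone 1 and at/right of its end to
zone `n_zones`, so zone assignment is total on finite inputs. The exposure
port sits in zone 4 by default.

## Occupancy scoring

Manual scoring in this assay assigns each 1-second interval the quadrant
containing the animal's head. The automated scorer reproduces that
contract: second *s* covers frames `⌊s·fps⌋ … ⌊(s+1)·fps⌋−1`, and its label
is the majority vote of the head's per-frame zones among frames where the
head was detected. A second with no detection is labeled missing, which
preserves the conservation identity
`Σ_zone seconds + missing = duration`. Ties break toward the previous
second's label (temporal continuity), else toward the lower zone index; the
aggregation rule is a package convention, since whole-second scoring by a
human never needed one. A trailing partial second is ignored. The frame
rate is explicit everywhere: published recordings here are nominally
60 fps, but a 2-minute, 3,600-frame session (30 fps effective) is equally
valid and used for the large simulation studies below.

## Kinematics

Per-node speed at step i is the Euclidean displacement between frames i and
i+1 divided by `pixels_per_cm` and multiplied by fps. Steps with a missing
endpoint are NaN and excluded from means. Distance per quadrant accumulates
the metathorax's per-step displacement into the zone of the step's starting
frame — unambiguous for boundary-spanning steps and exactly conservative
(total = Σ zones). Occupancy uses the head and distance/velocity the
metathorax because those are the anchors this assay reports for each
metric; both are configurable. Heat maps are 2-D frame-count histograms
over the arena rectangle; detections poking past a wall (an antenna tip
beyond the runway end) are clipped onto the edge bin so the grid total
equals the number of detected frames.

## Ethogram

Features are built per retained frame: every node's speed (cm/s), then
every node's x and y position (cm). Frames missing any node at i or i+1 are
dropped; each column is z-scored (constant columns stay at 0) with the
transform recorded so raw summaries can be recovered.

Positions default to the **egocentric** frame — each node relative to the
metathorax — so the position block describes posture rather than location.
With arena-absolute positions, all 27 x columns are near-copies of the
animal's runway position; after z-scoring that block carries more
splittable variance than any behavioral speed contrast, and k-means
partitions by where the animal was rather than what it was doing. Centering
on the body anchor (standard practice in pose-based behavior clustering)
removes that confound; the arena-absolute variant and unstandardized
features remain available as options.

Clustering is k-means with k = 4 and a fixed random seed (default 42,
matching the stated "42 random states" convention of the assay's analysis),
run per session. Semantic names are attached heuristically: resting = the
cluster with the lowest mean midline-node speed, scurrying = the highest,
and the remaining two split by signed left-minus-right mean leg speed
(positive → left leg movement). Ties break deterministically toward the
lower cluster id and are flagged; clusters whose body-speed spread is below
half the pooled within-cluster spread are flagged degenerate (e.g. a
session that is all resting), and raw cluster ids are always retained.
Bouts are maximal constant-label runs; time per behavior is label count
over fps, so times sum exactly to retained frames / fps.

Embeddings are PCA (deterministic up to axis sign) or UMAP with the assay's
stated hyperparameters (2 components, 15 neighbors, min_dist 0.1, spread
1.0, Euclidean). A standard UMAP replaces the parametric (neural-network)
variant; only visualization depends on this substitution.

## Statistics

The comparison tree runs Shapiro–Wilk per group and Levene across groups at
the gate alpha (default 0.05, configurable). Any rejection — including a
zero-range group, where normality is untestable — selects the
nonparametric branch: Kruskal–Wallis omnibus, all pairwise Mann–Whitney U
tests, Benjamini–Hochberg adjustment. Otherwise a one-way ANOVA (or mixed
ANOVA via pingouin when a within-subject factor is supplied) runs with
Tukey HSD (default) or Dunnett-vs-control post hocs. Mann–Whitney uses the
exact null distribution for small untied samples and the tie-corrected
normal approximation otherwise, so `U_a + U_b = n_a·n_b` always. BH
families are panel-scoped: all pairs of one metric within one comparison
(e.g. the 3 group pairs for one quadrant), never pooled across metrics.
Groups need n ≥ 3 (the gates are undefined below that).

Agreement between manual and automated seconds-per-quadrant tables is the
per-cell absolute difference divided by session duration, as percent of
video length, summarized by its mean and a paired t test across cells.
Confusion-rate metrics are plain arithmetic on validation percentages:
recall = tp/(tp+fn), precision = tp/(tp+fp), accuracy =
(tp+tn)/(tp+tn+fp+fn), reported to one decimal. Day trends are ordinary
least squares of value on day.

## Synthetic sessions

The generator emulates the assay's conditions: one animal, 120 s sessions,
a 27-node skeleton, the default arena, start in the middle of quadrant 1.
Behavior follows a first-order Markov chain over four states with
per-frame self-transition (dwell) probabilities and uniform exits. Default
regimes:

| state | body speed (cm/s) | limb amplitude (cm) | dwell |
|---|---|---|---|
| resting | 0.05 ± 0.02 | 0.02 | 0.993 |
| scurrying | 6.0 ± 0.6 | 0.2 (both sides) | 0.99 |
| left leg movement | 0.3 ± 0.1 | 0.8 (left) | 0.99 |
| right leg movement | 0.3 ± 0.1 | 0.8 (right) | 0.99 |

These are stand-ins, not study estimates. They are calibrated so that the
*session-average* air-group body speed measured by the pipeline is
~2.0 cm/s and per-session path length ~240 cm — the scales this assay
reports for air-exposed animals (a session-average of 2 cm/s over a mix of
states implies scurrying bursts well above it, hence 6 cm/s). Resting is
the most common state under the stationary mix, matching the assay's
observation that animals rest more than they scurry.

The body centroid performs run-and-tumble motion along x: a persistent
heading, re-chosen with probability 0.02 per frame, moves at the state's
body speed and reflects at the walls (the centroid therefore never leaves
the arena). Port preference is one parameter, `port_bias ∈ [−1, 1]`: when
the heading is re-chosen, the probability of heading toward the port is
`(1 + bias)/2` — drift on motion, not on the behavior chain. Lateral (y)
motion is a small reflected random walk.

Nodes ride on the centroid at fixed anatomical offsets (a ~7 cm animal
always facing +x; body orientation is not modeled). Appendages oscillate
sinusoidally, each at its own frequency (4 Hz ± 25%, fixed per session) and
phase: the active side's legs at the state's full amplitude, its antenna
and palp nodes at half, and the non-anchor axial nodes at a quarter
(body rocking). Desynchronized per-node frequencies matter: with a common
frequency the oscillation block forms coherent, highly splittable
directions in feature space that distort clustering. Antennae and palps
also tremble faintly (0.01 cm jitter) at all times. Observations add
Gaussian pixel noise (default 0.25 px — frame-to-frame jitter of a
well-trained model on stable nodes, which is much smaller than its absolute
localization error) and independent per-node dropout (default 1%).
Ground-truth occupancy is the per-second majority-vote quadrant of the
noiseless head trajectory, sharing the scorer's aggregation rule, so
noiseless sessions are recovered exactly by construction of the rule — the
recovery test exercises the full observation path (coordinates → zones →
seconds), not the rule itself.

What the generator does **not** emulate: body orientation and turning,
gait-coupled limb phases, position-dependent behavior (real animals rest
against walls), pose-estimation error structure beyond noise + dropout,
and any pharmacology. Passing tests therefore demonstrate pipeline
correctness under a controlled motion model, not biological fidelity.

## Validation studies and problem sizes

The validation module runs four end-to-end studies (sizes chosen as the
package's own defaults; all randomness is seeded):

* **Occupancy recovery** — 100 noiseless 3,600-frame sessions; requires
  exact conservation (120 s accounted for) and zero disagreement with
  ground truth.
* **Ethogram recovery** — 5 sessions at full generator defaults (60 fps,
  noise and dropout on); mean frame-wise semantic agreement must reach
  0.90. Typical values are ~0.97.
* **Null calibration** — 200 replicates of a 3-group × 6-animal × 3-day
  cohort with zero port bias everywhere; the pooled BH-adjusted pairwise
  rejection rate for port-zone time must stay ≤ 0.08 at α = 0.05. The
  3-day span keeps 200 replicates affordable; Type-I control under the
  null does not depend on the day count.
* **Aversion power** — 50 replicates of the full 3 × 6 × 14-day study
  design with vehicle port_bias −0.6 and nicotine +0.2, per-animal
  port-zone seconds averaged across days (as the assay averages); the
  air-vehicle pair must be flagged (adjusted p < 0.05, vehicle lower) in
  ≥ 80% of replicates. Day-averaging is what makes n = 6 groups
  well-powered; single-day cohorts detect the same contrast in only ~30%
  of replicates.

## Known limitations

* Rigid posture and fixed facing direction in the generator; no turning.
* One linear calibration axis; no perspective correction.
* The semantic labeling heuristic assumes the four assay behaviors; other
  ethograms should keep raw cluster ids.
* Mixed ANOVA requires balanced within-subject data ordered by level
  blocks; it delegates to pingouin and is not re-derived.
* Cross-session clustering pools per-session-standardized features; no
  batch correction beyond that.
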