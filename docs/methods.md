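# Methods

## The measurement model

A screen compares two bait strains, each expressing a BirA fusion of one
bait protein, against a shared prey library whose members carry an
N-terminal AviTag. The readout is a nitrocellulose dot-blot array pinned
from 384-well lysate plates into a 1,536-dot (32 × 48) layout and imaged
in two channels: streptavidin (SA, biotinylation signal) and anti-H3 (LC,
loading control). Each (bait, prey) pair — a *set* — appears on nine dots:
three biological replicates (separate membranes) × three technical
replicates (separate positions on each membrane).

The signal model assumed throughout, and implemented literally by the
simulator, is

    LC_dot ∝ load,     SA_dot ∝ strength(bait, prey) · load · ε,

where `load` is the amount of lysate deposited and ε is mean-one
multiplicative lognormal noise with coefficient of variation
`replicate_cv`. Dots are rendered as 2-D Gaussian spots (σ
`dot_sigma_px`, default 3 px) truncated at 3σ, on a planar background
(`background_level` + `background_gradient` · (x + y)) with Gaussian read
noise, quantized to 16-bit. The SA/LC ratio therefore estimates
`strength · ε / gain` independently of load — which is exactly why the
loading-control normalization works.

### Planted ground truth

Preys are partitioned into categories by `category_fractions`
(largest-remainder apportionment, so counts match round(fraction · n) and
sum to n): *null* (strength 0 for both baits), *equal* (identical
strength), *prefers_A* / *prefers_B* (strength ratio equal to
`true_fold_change`, default 4). Per-prey baseline strength is lognormal
with log-sigma `strength_sigma` (default 0.4), mimicking the wide dynamic
range of real interaction signals. Failure modes planted with known
labels:

- **missing strains** (`missing_strain_fraction`, default 1%): pre-lysis
  OD600 set to 0.01 and protein load reduced to 1% — a strain lost during
  library construction;
- **per-dot dropouts** (`dropout_fraction`): individual dots with load
  collapsed ~1000-fold, a failed pin transfer (the median aggregate
  absorbs these);
- **whole-set signal dropouts** (`set_dropout_fraction`): one set's SA
  channel collapsed on every replicate, producing the low-tail Z-score
  exclusion case.

### Replicate layout

Two layouts map preys to grid positions. `block` (used whenever
capacity allows) follows the 384 → 1,536 pinning convention: each prey
owns a 2 × 2 quadrant block and its technical replicates fill three of
the four positions, leaving the fourth empty — those empty positions
double as the sample of the background used for the detection floor.
`packed` fills the grid row-major with consecutive triples, allowing up
to 512 preys × 3 replicates = 1,536 occupied positions with no empties.
The replicate-to-position convention of the original instrumentation is
not fixed by the assay itself; this choice is the package's own.

## Quantification

Grid fitting is automatic (the wet-lab original used an interactive
ImageJ plugin; an automatic fit is required for testability): spots are
detected on the channel-wise maximum image by thresholding at
median + k · (1.4826 · MAD) with k = 5 — the robust sigma is floored at
one count so a perfectly flat background still admits detection — then
labelled, and centroids of components ≥ 5 px are assigned integer lattice
indices after de-rotating by the median near-neighbour angle (folded mod
90°). The final grid is the least-squares affine fit of centroids to
indices; the residual RMS is reported and a residual > 3 px raises a
gridding error. On synthetic membranes this recovers centers to ~0.03 px
for rotations up to 2°.

Each grid position is measured in both channels as the summed intensity
over a disk ROI (radius 0.4 × spacing) minus area × the median of an
annulus (0.45–0.6 × spacing) around it, clipped at zero. Summed (not
mean) ROI intensity with a *local* annulus background is the chosen
contract; with 24 px spacing and 3σ-truncated spots of σ = 3 px the
annulus never touches a neighbour. Negative corrected values are clipped
to zero because intensities are physical nonnegatives and downstream
ratios must not flip sign. Positions whose ROI leaves the image are
measured on the clipped support and flagged `edge`, never dropped. Pixel
coordinates are 0-based internally; grid indices are 1-based in every
file.

## Normalization, QC, preference calling

- **Per-dot ratio**: SA_corrected / LC_corrected. A loading control below
  `control_floor_frac` (default 0.1) × the membrane's median occupied LC
  marks the dot invalid instead of yielding an unbounded ratio.
- **Aggregation**: the set aggregate is the **median** of its valid
  replicate ratios (robust to a single bad dot; the mean is not), with
  the sample SD reported. Fewer than `min_replicates` (default 3) valid
  ratios refuses aggregation.
- **Exclusions** (in priority order): no OD record; pre-lysis OD below
  `od_floor` (default 0.05) — the strain was missing to begin with; too
  few replicates; aggregate more than `z_threshold` (default 10) SDs
  *below* the rest of its bait's membrane stack. The Z-score is
  leave-one-out (mean and ddof-1 SD of all *other* aggregable sets of the
  same bait), and the rule is strictly one-sided: a set 20 SDs *above*
  the population is retained, because strong interactors are the signal
  of interest. Sets with replicate SD above `sd_flag_threshold` (default
  3) are flagged for the reproducibility report but not excluded.
- **Detection floor**: the screen never observes "no interaction"
  directly, only signal indistinguishable from background. The floor on
  the ratio scale is the 95th percentile of empty-position pseudo-ratios
  (empty-position corrected SA divided by the membrane's median occupied
  corrected LC — empty positions have no loading control of their own).
  A membrane without empty positions (packed layout) falls back to a
  fixed configurable floor (default 0.1). This is the largest free choice
  in the pipeline and is deliberately a config knob.
- **Call**: both signals below the floor → `no_interaction`; exactly one
  above → preference for that bait (fold change reported against the
  floor); both above → `prefers_X` iff max/min **strictly** exceeds
  `preference_threshold` (default 2), else `both`. The symmetric max/min
  form makes the threshold apply identically in both directions, so
  relabelling the baits exactly swaps the two preference categories and
  fixes everything else.

Aggregates are compared across baits without any cross-membrane scaling
step: the SA/LC ratio already cancels per-membrane gain, and a
channel-wide gain change applied to all membranes rescales ratios and the
recomputed floor together, leaving every category unchanged.

## Hydropathy analysis

Candidate translocon substrates are preys with a signal peptide or a
transmembrane domain (or both) and no predicted mitochondrial targeting
signal; annotation is an input, never predicted here. For each preference
group, the profile reports, at each position p ≤ `max_len` (default 25,
covering typical SP lengths), the mean Kyte–Doolittle value over all SPs
long enough to reach p, with SEM = sample SD / √n(p) (0 when n = 1).
**No sliding-window smoothing is applied by default**: the discriminating
signal sits in positions 1–3 — the region the 3-residue prefix-swap
construct exchanges — and windowing would blur it. A `window` option
exists for conventional smoothed profiles.

Synthetic SP groups are sampled residue-wise from exponentially tilted
distributions over the 20 standard residues whose per-position expected
hydropathy equals the target (solved by Brent's method on the tilting
parameter), so group profiles converge to their targets as n grows;
targets at the scale extremes (±4.5) degenerate to all-Ile / all-Arg.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on synthetic data:
quantification accuracy on 16 × 24 noise-free membranes (claims checked
against the direct pixel sum of each rendered spot); preference recovery
on the full 512-prey, 32 × 48, 3 × 3-replicate screen; exclusion rules on
a 192-prey equal-only screen where planted low-OD strains, whole-set
dropouts and injected ±12/20 SD outliers have known outcomes. Exact
float equality is asserted only where the arithmetic guarantees it
(power-of-two channel gain; index permutations); everything else carries
explicit tolerances. Degenerate inputs (blank images, zero-length
sequences, empty ratio lists, duplicate IDs) raise errors naming the
offending record.

## What the simulation does and does not establish

The generator reproduces the statistical structure the analysis relies on
— multiplicative replicate noise, load variation cancelled by the loading
control, planar background, missing strains and dropouts — so passing
tests show the pipeline recovers planted truth *under that model*. It
does not emulate membrane texture, dust and scratches, optical vignetting
or bleed between saturated neighbouring dots, spatial position effects
correlated with plate geometry, or biological crosstalk (indirect
biotinylation through shared complexes). Recovery rates measured here are
therefore upper bounds on what identical settings would achieve on real
membranes, and the grid fitter assumes every lattice row and column
contains at least some detectable spots. Two preys sharing identical true
signals are indistinguishable by construction; the pipeline makes no
attempt to separate technical from biological absence of signal — an
excluded or no-interaction call is explicitly ambiguous between the two.
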