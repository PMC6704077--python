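# Methods

## Scope and data model

`mscope` post-processes per-node scalar fields from tDCS simulations; it
does not solve field equations.  Its inputs are the three tables a
finite-element tDCS simulator can export:

* a node cloud — integer node ids with 3D coordinates in mm;
* one field vector per montage — a non-negative scalar per node, the
  magnitude of current density (MCD) or of the electric field (MEF);
* an atlas label table — (hemisphere, lobe, gyrus) per node, with
  hemisphere ∈ {left, right} and lobe ∈ {frontal, parietal, temporal,
  occipital, limbic, sublobar}, i.e. 12 (hemisphere, lobe) categories.

All files are UTF-8 tab-delimited text with a header row.  Coordinates
are RAS millimetres with the left hemisphere at x < 0; a node with x = 0
exactly is assigned to the left hemisphere (a deterministic tie-break for
a measure-zero case).  Published MCD tables print the unit "mA" although
current density is dimensionally current per area; the package treats
field values as unlabeled "field units" throughout, which is safe because
every selection quantity is either a ratio or compared within one field.

Native-space clouds are brought into atlas space by a user-supplied 4×4
affine; nodes whose mapped coordinates leave a configured bounding box
are dropped, emulating coordinates that fail atlas lookup (real
Talairach-mapping pipelines silently lose a few percent of nodes this
way; the true failure criterion of such services is not published, so an
axis-aligned box is used as the stand-in).  Overlap between montages is
computed by node-id intersection, which assumes all fields were simulated
on the same head model — the normal case, since simulators ship one
built-in head.

## Synthetic head model

The generator exists so every downstream stage can be exercised, with
realistic statistical structure, without a FEM package or atlas database.
It emulates the study conditions of a 10-montage reading-pathway
experiment: ~35k cortical nodes, a 12-category parcellation with named
gyri, 2 mA montages with anode CP5 (dorsal) or TP7 (ventral) against
cathodes CZ, contralateral supraorbital, contralateral maxilla, nape of
the neck, or the contralateral homologous site, with pad sizes 5×5, 3×3
and 5×7 cm².

**Geometry.**  The head is a sphere of radius 85 mm (adult scalp).
Cortical nodes are sampled uniformly (seeded) on a spherical cap of
half-angle 120° at radius 0.78·85 ≈ 66 mm; 10 % of nodes sit on an inner
shell at 0.55·85 ≈ 47 mm and are labeled sublobar.  Electrode sites
follow the proportional 10-10 system as fixed spherical angles (18° per
row step; CZ at the apex); the extracephalic maxilla and neck sites are
fixed synthetic directions below the equator, since a sphere has no neck.

**Parcellation.**  Labels are a deterministic, scale-free function of
each node's unit direction (ux, uy, uz): a medial band |ux| ≤ 0.22 is
limbic; above uz = 0.45 the azimuth from anterior splits frontal
(< 85°) from parietal; below, azimuth ≤ 45° is frontal (orbital), ≥ 145°
occipital, and the lateral remainder temporal.  Gyri subdivide each lobe
by azimuth/height bands — e.g. the supramarginal band is the lateral
(|ux| ≥ 0.55) parietal sector at azimuth 95–125°, which contains the
cortical projection of CP5, and the temporal gyri stack by height
(superior ≥ 0.28 > middle ≥ 0.08 > inferior ≥ −0.12 > fusiform), placing
the middle/inferior temporal bands under TP7.  The band boundaries were
chosen once, on this anatomical reasoning, so that the synthetic
experiment reproduces the published selection structure qualitatively;
they are constants of the atlas class, not tuning knobs of individual
runs.

**Field model.**  For a montage with pad area A (cm²) and current I (mA),

    value_i = (I / 2) · (25/A)^0.5 · [ G_σ(d(x_i, anode))
              + 0.35 · G_25(d(x_i, arc)) ] + noise,  clipped at 0

where G_w(d) = exp(−d²/2w²), σ = 35 mm · (A/25)^0.5, d(x, anode) is the
Euclidean distance to the anode's radial projection onto the cortex
shell, and the arc is the anode→cathode great-circle scalp path sampled
at 64 points and projected to the cortex shell.  This encodes the four
qualitative properties real simulations show and the analysis relies on:
the peak sits under the anode; current spreads toward the cathode (so the
cathode position steers the off-target territory); the field is strictly
linear in I (exact with noise off); and smaller pads give sharper, higher
peaks (gain (25/A)^0.5, spread (A/25)^0.5).  Defaults: σ0 = 35 mm, both
size exponents 0.5, leak fraction 0.35, path width 25 mm, noise off.
Noise, when enabled, is seeded i.i.d. Gaussian per node, added after the
deterministic field and clipped at zero.

## Selection statistics

* **avg_MCD** is the *unweighted* mean of the per-category means (not the
  node-weighted grand mean): the reference line is a property of the lobe
  profile, and categories with zero nodes are omitted rather than counted
  as zero.  Exceedance is 100·(mean − avg)/avg, reported only for
  categories above the reference; the spread count excludes the maximum
  category itself.
* **Thresholding** keeps nodes *strictly* above fraction × max (default
  0.5); ties at the threshold are excluded, and the maximum over labeled
  nodes defines the threshold so overlap and lobe statistics see the same
  support.  Because the threshold is relative to each field's own
  maximum, threshold sets, p, r, CMCD ranks and max-lobe identity are all
  invariant under global positive scaling — hence exactly invariant under
  current changes.
* **p** uses the first (dorsal) montage's above-threshold count as
  denominator.  p = 0 is returned rather than raised; r is undefined only
  when p1 + p2 = 0.  For display next to published tables, p is shown
  truncated at two decimals and r conventionally rounded, matching how
  the published values behave (a printed p of 0.19 corresponds to
  213/1092 = 0.195).
* **CMCD** is a sum, not a mean, so cluster extent and intensity both
  contribute; clusters are (hemisphere, gyrus) pairs with a deterministic
  alphabetical tie-break on equal sums.
* **ANOVA / Tukey HSD** treat node values as independent observations
  grouped by category (scipy `f_oneway`, statsmodels `pairwise_tukeyhsd`,
  α = 0.05).  Nodes of a smooth field are spatially autocorrelated, so
  these tests replicate the field's customary reporting convention; they
  are not spatially corrected inference.  Degenerate inputs are defined:
  all-identical observations give F = 0, p = 1.
* **Decision procedure.**  Principle-1 candidates must place their
  maximum at the target lobe and not share it (within relative tolerance
  1e-6) with a non-target lobe; ranking is by spread count, then total
  off-target exceedance, then name.  Principle 2 by default evaluates
  only survivor pairs (`scope="all"` evaluates every pair independently;
  `scope="winner_row"` restricts to pairs containing each pathway's top
  candidate) and takes the minimal overlap count with a lexicographic,
  flagged tie-break.  Principle 3 passes if any target gyrus appears in
  the top-k (default 5) clusters.  The final pair is the principle-2
  winner when it survives principle 1 and passes principle 3; conflicts
  are reported, not silently resolved.

## Sensitivity analysis

Electrode displacement moves a site 10 mm along the scalp geodesic in the
four tangent directions (superior/inferior, anterior/posterior),
re-projected exactly onto the sphere; at a pole, where a tangent
degenerates, the lateral axis provides the fallback frame.  The analysis
simulates the baseline plus the four anode- and four cathode-displaced
variants and reports per-lobe mean deltas and whether the max-MCD lobe
moves.  Intensity sensitivity compares 2 mA and 1 mA: with noise off the
per-lobe means halve exactly (model linearity) while every scale-free
selection quantity is unchanged; with noise on, per-(seed, category)
means over a list of seeds are compared by a paired t-test, reported
descriptively alongside the deltas since no canonical test exists for
this design.

## Problem sizes and determinism

The pipeline default is the paper-scale 35,057-node head; the test suite
and the end-to-end checks run at 4,000–10,000 nodes, which preserves all
qualitative structure (the partition populates all 12 categories from
~2,000 nodes) at a few seconds per full 10-montage experiment.  Every
random draw (node placement, optional noise) is owned by an explicit
seed; a run's artifacts are stamped with the config hash, and rerunning a
config reproduces byte-identical reports.

## What the synthetic model does and does not show

Passing the end-to-end checks shows that the *selection machinery* —
grouping, thresholding, overlap, clustering, ranking, the decision rules
— behaves correctly on fields with the assumed qualitative structure, and
that the published selection outcome follows from that structure (an
anode-adjacent peak spreading toward the cathode) rather than from
FEM-specific detail.  It does not validate any FEM solver, reproduce
absolute published MCD magnitudes (head-model-specific, ~0.15–0.24 in the
simulator's units, versus ~1 in synthetic field units), or model tissue
conductivity, electrode-skin interfaces, or field directionality.

Known limitations of the generator observed in its own test runs:

* A homologous-return montage (e.g. CP5→CP6) in a real head produces
  near-equal stimulation under both pads; the synthetic path-leak term
  only partially emulates this, so the CP5_CP6 analog is *not* excluded
  by the shared-maximum rule as its real counterpart would be, and its
  bilateral spread actually lowers its relative off-target exceedances
  (the avg_MCD reference rises with it).  It therefore edges out the
  CP5_CZ analog on the principle-1 tie-break, although both survive and
  the final selected pair is unaffected.
* The synthetic TP7_Neck analog's temporal and parietal means are close
  enough that one of the eight 1-cm displacement variants can move its
  max lobe; the dorsal CP5_CZ analog is stable under all eight.
* The spherical two-shell geometry has no sulci or cortical folding; the
  inner (sublobar) shell sits closer to the cortex than real deep
  structures do and accordingly receives more synthetic field than real
  sublobar regions would.
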