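# Methods

`wmnquant` quantifies heterotopic white-matter neurons (WMN) in NeuN-stained
brain sections. It implements four counting workflows over a common
synthetic-slide generator that supplies exact 3D ground truth, the density
model they share, the agreement statistics used to compare them, and a
control-referenced certainty scale for calling mild Malformation of Cortical
Development type II (mMCD II). This note documents the models, their
assumptions, the defaults, and what the synthetic fixtures do and do not
establish about real tissue.

## The counting problem

A section of thickness *T* μm is imaged in brightfield after NeuN
immunohistochemistry (DAB, brown) with haematoxylin counterstain. Counting
2D profiles per area (Na, profiles/mm²) overestimates cells per volume,
because a cell of height *h* intersects every section plane within *h* of
its centre: the section samples an effective depth *T + h*. The Abercrombie
correction inverts this,

    Nv = 1000 · Na / (T + h)        [cells/mm³; T, h in μm],

equivalently a corrected count n·T/(T+h). *h* is estimated per case as the
mean equivalent circular diameter of the detected profiles (a global
override is available). Using the profile mean rather than the unknowable
true cell height introduces a small bias; the simulation suite quantifies it
at well under 1% for the default conditions (10 ± 2 μm cells, T ≈ 17 μm,
minimum profile area 10 μm²) because the profiles lost below the minimum
area and the underestimate of *h* from face-clipped profiles nearly cancel.

Design-based stereology needs no such correction: the optical disector
counts each cell once by a unique point (the top of its sphere) falling
inside a 3D probe, so ΣQ / sampled volume is unbiased for any cell-size
distribution.

## Synthetic slides

The generator emulates a temporal-lobe block: a cortical band occupying
`cortex_band_frac` of the tissue height, whose deepest
`layer6_band_frac` is a dense layer-VI analogue, above white matter with
sparse heterotopic neurons. The grey/white interface is straight by default;
an optional sinusoidal undulation (amplitude/wavelength configurable)
exercises boundary-sensitive logic on curved interfaces.

Cells are spheres from a homogeneous 3D Poisson process per compartment.
Every sphere intersecting the physical slab [0, T] enters the ground truth,
with centres effectively uniform over [−d/2, T + d/2]; the expected profile
count per area is therefore exactly Nv·(T + h̄)/1000 — the generator's core
contract, verified to 2% over hundreds of draws.

The rendered profile of a cell is the **largest chord** of its sphere–slab
intersection: the full equatorial diameter when the centre lies inside the
slab, the chord cut by the nearer face otherwise. This models the
extended-focus projection a slide scanner produces, and it is the
profile-size model under which profile counting plus Abercrombie correction
is self-consistent. (Rendering each profile as a chord at a uniformly random
plane was considered and rejected: it biases the corrected estimate by
roughly −7% under the default conditions, which would misrepresent a method
that works in practice.)

Colours follow Beer–Lambert absorption with the Ruifrok–Johnston
haematoxylin/DAB optical-density vectors against a light grey background
(235/255 on all channels). Because the renderer and the unmixer share one
stain matrix, separation is exactly invertible on noiseless fixtures up to
8-bit quantisation. Gaussian intensity noise (default sd 2 grey levels)
is added per channel.

Key defaults (all configurable):

| parameter | default | note |
| --- | --- | --- |
| mpp | 1.0 μm/px | desk-scale rasters, ~6 Mpx per demo slide |
| thickness T | 17 μm; cohorts draw N(17, 5) truncated at 5 | measured-section emulation |
| cell diameter | 10 ± 2 μm | spans the small/medium/large profile classes |
| WMN density | 1500 cells/mm³ | recovery-study condition |
| cortex / layer VI density | 20 000 / 50 000 cells/mm³ | order-of-magnitude contrast with white matter, as in tissue; gives the compartment classifier realistic features |
| DAB disc OD | 1.0 | vs detection cutoff 0.31 |

Cohorts draw per-case true densities uniformly from group ranges, default
controls U(500, 1500) and epilepsy-like U(800, 4500) cells/mm³ (12 vs 30
cases) — chosen so the group maxima differ roughly three-fold while the
ranges overlap, the regime in which a control-referenced threshold is
actually interesting. No published per-case density distribution exists to
calibrate against, so these ranges are free parameters of the simulation,
not estimates.

## The four workflows

**WSA automated.** Tissue is separated from glass by a brightness threshold
(default 200/255), a local homogeneity cap (default 2.1 units; one unit maps
to 10 grey levels of local standard deviation in a 3 μm window — the
nominal knob of the original acquisition software is kept, its absolute
scale being proprietary), and a 450 μm² minimum object size. The tissue is
tiled into superpixels (SLIC on a 4× decimated raster; the initialisation
scale 0.4 maps to a target segment area of 0.4 × 62 500 μm², smaller always
meaning finer). A 1-nearest-neighbour classifier over z-scored segment
features (mean R, G, B, mean DAB and haematoxylin OD, local density of
detected NeuN profiles) is trained from a handful of user-labelled example
segments and classifies the slide into cortex / border / white matter /
background; white-matter connected components under 10% relative area are
demoted to border. Ties in 1-NN distance resolve to the lowest training
index, so classification is deterministic. The automated white-matter mask
keeps tissue near the grey/white interface, which is exactly its documented
failure mode: on slides with a dense deep-cortical band the automated
density runs above the manual one.

**WSA manual.** The user-outlined white-matter polygon is rasterised
(pixel-centre semantics, so a 1 mm² square is exactly 10⁶ px at 1 μm/px)
and eroded by a Euclidean distance-transform margin, default 0.5 mm, from
everything classified cortex or border. With the generator's geometry this
provably excludes every layer-VI neuron. Profiles are detected on the
unmixed DAB optical density (default cutoff: nominal intensity 3.1 × 0.1
OD/unit = 0.31 OD), 8-connected, minimum area 10 μm². Touching profiles are
resolved by a local watershed on the distance transform, applied only to
components above 60 μm² and with peaks closer than 4 μm suppressed, so
single convex profiles are never split. Size classes use the fixed bins
small < 126.36 μm² ≤ medium ≤ 370 μm² < large (the medium bin closed on
both edges).

**SA (field sampling).** Square fields (default 15 per case) are placed
uniformly at random without overlap, fully inside the margin-excluded ROI,
by bounded rejection sampling; fewer fields are returned with a warning if
the ROI cannot hold them. Detection in this mode thresholds the raw R, G, B
channels (defaults capture DAB brown on the generator's palette). The
sampled area is necessarily the smallest of the three image-based methods,
reproducing the area ordering automated ≥ manual ≥ field.

**Stereology.** The disector operates on the ground truth's 3D coordinates
restricted to the ROI — the live-microscopy focal sweep has no image
analogue here, and simulating one would only re-encode the same
coordinates. Frames are a uniformly shuffled subset of a jittered tiling of
the ROI (clipped tile areas count toward the sampled volume); subsets are
nested across the escalation ladder 25% → 50% → 75% → 100%, so the
coefficient of error CE = 1/√ΣQ (the Poisson form appropriate to uniform
random sampling) can only fall as sampling escalates, stopping at CE ≤ 0.1
where possible. Counting-frame inclusion/exclusion edges are realised as
half-open intervals: the tiles partition the plane, so no unique point can
be counted twice or lost on an edge. At full sampling the count is exactly
exhaustive. Guard zone and disector height are unreported in routine
practice write-ups; defaults are guard 2 μm and height T − 4 μm, both
configurable, and the recovery studies use guard 0 with height T.

## Statistics

Test–retest reliability: Pearson r, the intraclass correlation ICC(A,1)
(two-way model, absolute agreement, single measure; computed through
`pingouin.intraclass_corr`, with a direct ANOVA mean-squares fallback below
3 pairs) with its 95% F-interval, and Bland–Altman mean difference with
d̄ ± 1.96 sd limits of agreement. Method and group contrasts:
Kruskal–Wallis omnibus with pairwise two-sided Mann–Whitney post-hocs
(exact enumeration up to n = 8 per group without ties, normal approximation
with tie correction otherwise; all-identical inputs return p = 1 by
contract). Covariate screens: Spearman correlation, flagged significant
only below a Bonferroni-adjusted alpha (default 0.002). The test suite
checks ICC against an independently assembled mean-squares computation to
1e-10 and Mann–Whitney against full enumeration.

In the pipeline's reliability stage, re-analysis repeats the stochastic
stages (field placement, disector tile subset) with a fresh sub-seed;
whole-slide analysis of the same raster is deterministic and reproduces
exactly, which is why it attains the best ICC in simulated retests — the
same ranking argument used to designate manual whole-slide analysis the
reference method.

## mMCD II certainty scale

`fit_control_reference` summarises a control series (mean, sd, max of the
corrected densities under one method); `classify_case` assigns, by default:
within the control range up to mean + 2 sd; borderline up to the control
maximum; mMCD II strictly above the control maximum. The cut expressions
are configurable strings over {mean, sd, max}, because the appropriate
numbers belong to each laboratory's own controls and method — the package
deliberately hard-codes no absolute density threshold. A published example
control maximum (2298 cells/mm³, whole-slide automated counting, temporal
lobe) ships as a documented constant only. Under its own reference no
control case can be called mMCD II, and the tier is monotone in density.

## Numerical and degenerate-input choices

- Pixel semantics: 0-based indices, pixel centres at (c + 0.5)·mpp; areas
  are pixel counts × mpp², so area assertions in tests are exact.
- Empty inputs degrade explicitly: a blank image yields an empty tissue
  mask; an empty ROI yields zero detections with a warning; zero counts
  flag CE and size fractions as undefined rather than raising.
- Raster budget: a configurable `max_pixels` (default 2²⁶) guards against
  accidentally cluster-scale raster requests.
- Determinism: every stochastic stage takes a seed; the pipeline derives
  all sub-seeds from the run seed via `numpy` seed sequences, and repeated
  runs produce byte-identical density tables.

## Problem sizes used by the verification suite

The acceptance checks run at desk scale: 200 white-matter slides of
1.9 × 2.0 mm at 1 μm/px for the recovery and stereology-agreement studies
(pooled Monte-Carlo standard error ≈ 0.6%, comfortably inside the 2%
recovery bands); 24 cortex slides of 2 × 3 mm with a 150 μm interface
undulation for the contamination and area-ordering studies; 200 simulated
cohorts of 12 + 30 cases (truth-only, 1 × 1.1 mm) for separation power and
classification calibration. These sizes are the package's verification
conditions, not limits of the implementation.

## What passing tests do and do not show

The generator has crisp compartments, uniform stain amplitude, ideal
optics, and no gliosis, vasculature, folds, or scanner artefacts. Passing
recovery and agreement tests therefore establishes that the *estimators and
their implementations* are correct under the stated geometric and staining
model — not that any particular real-world staining run satisfies that
model. On real slides the detection thresholds, the homogeneity/brightness
tissue parameters and the RGB bounds must be recalibrated per batch, and
absolute density values are method- and laboratory-specific; that is
precisely why the classification scale is control-referenced rather than
absolute.

## Known limitations

- The "intensity 3.1 units" and "homogeneity 2.1 units" knobs of the
  original acquisition stack are proprietary scales; they are preserved as
  nominal values behind documented linear calibration constants, not
  reproduced absolutely.
- h is the mean *profile* diameter, not the true cell height; the residual
  bias is absorbed well within the stated tolerances but is not zero.
- The 1-NN compartment classifier is intentionally minimal (it mirrors a
  point-and-click training interaction); it exposes no class probabilities
  and will inherit any ambiguity of a blurred grey/white interface — by
  design, since that contamination mode is one of the findings the
  simulations reproduce.
- Stereology consumes ground-truth coordinates; there is no z-stack image
  simulation.
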