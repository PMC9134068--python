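# Methods

## The model

`rootflux` simulates auxin (IAA) transport in a multicellular template of
the *Arabidopsis thaliana* root tip.  The state holds one concentration per
cell (cytoplasm) and one per wall (apoplast compartment).  Auxin is a weak
acid: the protonated fraction f(pH) = 1/(1 + 10^(pH − pKa)) crosses
membranes passively, the anion is moved by carriers.  The flux density
across one membrane segment, positive out of the cell, is

    J = P_IAAH (f_cyt A_cell − f_wall A_wall)
      + P_eff  g (1 − f_cyt) A_cell
      − P_AUX w g (1 − f_wall) A_wall

where `P_eff` is the segment's total efflux permeability, `w` the influx
carrier weight, and `g` a Goldman-type membrane-potential factor (below).
Auxin also diffuses cell-to-cell through plasmodesmata (per-wall
permeability × wall length × concentration difference), diffuses along the
apoplast between endpoint-adjacent wall compartments
(D_wall/distance coupling), is synthesized at rate α and degraded at rate
μ in cells, enters the template as a constant influx over the shootward cut
of the stele files (phloem delivery), and leaves through two open
boundaries (below).  Everything is linear in the concentrations, so the
tissue assembles into dA/dt = M A + b with sparse M; steady states are one
sparse solve (least-squares fallback for singular closed systems, residual
tolerance 1e−10 relative to the backward-error scale) and time courses use
BDF with the exact Jacobian.

### Scenario algebra

The transporter-mediated efflux of a membrane segment is the sum of three
components — ABCB-independent (∝ number of ABCB members), PIN-independent
(∝ number of PIN members), and co-dependent (∝ the product of the two
counts) — toggled by the interaction scenario:

| scenario | abcb | pin | co-dependent |
|----------|------|-----|--------------|
| I        | ✓    | ✓   |              |
| II       |      |     | ✓            |
| III      | ✓    | ✓   | ✓            |
| IV       | ✓    |     | ✓            |
| V        |      | ✓   | ✓            |

By default all three permeabilities are equal (P_ABCB = P_PIN = P_SYN =
0.56 µm/s per member).  The co-dependent component can be made
antagonistic (negative), in which case the segment total is floored at
zero: a negative total efflux permeability would be unphysical.

### Carrier placement

Placements are editable rule tables (`rootflux.transporters`), with
defaults following the established localization data for this tissue:

- ABCBs, nonpolar (same count on every face): ABCB1+ABCB19 in stele,
  pericycle, endodermis, cortex and QC; ABCB4 alone in epidermis, outer
  LRC and the outermost columella tier; ABCB1 in the inner LRC; nothing in
  the inner columella tiers.  The rule table is user-editable, so the
  alternative reading in which ABCB1 also sits in the epidermis can be
  tested without code changes.
- PINs, polar, with the member(s) recorded per entry: PIN1/3/7 rootward in
  the stele, PIN1 rootward in pericycle and endodermis, PIN2 shootward in
  the EZ epidermis and the LRC, PIN2 rootward in the MZ cortex and
  shootward in the EZ cortex (the well-known cortical polarity flip), and
  PIN3/7 nonpolar in the columella.
- AUX1/LAX influx carriers, apolar: LRC, EZ epidermis, columella
  (AUX1+LAX3), and MZ stele (AUX1+LAX2, the phloem-unloading region).  In
  the EZ the stele influx is restricted to the axial (shootward) faces:
  this stands in for the interior protophloem files of a fully resolved
  stele, which take up auxin from the axial walls of the conduit but are
  shielded from the outer lateral apoplast.  Without this restriction the
  homogenized two-file stele scavenges laterally relayed auxin back into
  the descending stream and produces an artificial whole-organ
  recirculation loop.
- Plasmodesmata: a per-interface-type permeability table (default
  0.3 µm/s) with the cap–epidermis and cap–cortex interfaces set to zero —
  electron-microscopy counts show the root cap is symplastically isolated
  from the root body.
- A small background anion efflux permeability (0.056 µm/s, one tenth of a
  carrier) acts on every membrane, representing uncharacterized
  transporters; without it, cells expressing no efflux carrier become
  unbounded weak-acid traps.

Genotypes act on the tables: knockouts zero the named carrier everywhere;
RT-qPCR-derived expression changes multiply it uniformly (whole-root
measurements carry no spatial information).  ABCB4 can be switched to an
influx mode in which its count joins the influx weight (one unit per
ABCB4, the same weighting as AUX1/LAX) and leaves all efflux terms,
including the co-dependent product.

### Membrane-potential weighting

With potential V = −120 mV (inside negative) and N = −FV/RT ≈ 4.67, anion
efflux carries the Goldman unidirectional factor g = N/(1 − e^(−N)) ≈ 4.7.
Influx carriers are proton symporters whose translocated complex moves
down its electrochemical gradient, so carrier influx uses the same
favourable factor rather than the passive anion-entry penalty N/(e^N − 1)
≈ 0.04; with the penalty factor the influx carriers would be two orders of
magnitude weaker than efflux at equal permeability and the well-documented
influx-carrier-dependent accumulation patterns could not form.

### Boundaries

The template is a cut root, not a closed organ, and two boundaries are
open:

- the apoplast at the shootward cut loses auxin to the rest of the plant
  (outflow permeability 2 µm/s on the cut walls); without it the shootward
  conveyor piles auxin against a sealed wall and every scenario converges
  to the same artifactual distal accumulation;
- the root-cap surface (columella and LRC boundary walls) loses auxin to
  the medium (0.5 µm/s): the cap lacks a cuticle and sheds mucilage.  The
  root-body epidermis is sealed by its cuticle — if the whole surface
  leaked, the epidermal shootward conveyor would lose its cargo through
  the outer face at every step and basipetal transport would die.

## Default parameters

| parameter | default | unit | note |
|-----------|---------|------|------|
| P_IAAH | 0.56 | µm/s | passive permeability of protonated IAA |
| P_AUX | 0.56 | µm/s | per influx-carrier member |
| P_ABCB = P_PIN = P_SYN | 0.56 | µm/s | per member / member pair |
| background efflux | 0.056 | µm/s | all membranes |
| pH cytoplasm / wall | 7.2 / 5.3 | — | f_cyt ≈ 0.004, f_wall ≈ 0.24 |
| pKa (IAA) | 4.8 | — | |
| membrane potential | −120 | mV | single configured constant |
| D_wall | 32 | µm²/s | apoplast diffusivity |
| synthesis α | 1e−5 | µM/s | uniform background |
| degradation μ | 3e−4 | 1/s | cytoplasm only (t½ ≈ 39 min) |
| shoot influx | 4.0 | µM·µm/s | per µm of cut stele wall |
| PD permeability | 0.3 | µm/s | per interface table |

Membrane permeabilities and pH/pKa values are the conventional ones for
this model family; the source rates (influx, synthesis, degradation,
outflows) were fixed once so that the wild-type model reproduces the
canonical organ-scale behaviour — a reverse-fountain flux pattern, an
apical auxin maximum, influx-carrier-dependent accumulation in the outer
tissues, and organ transit times of minutes — and are configuration
values, not fitted constants.  The system is linear, so the absolute
concentration scale is set by the sources and all scenario/genotype
comparisons are reported scale-free.

## The regular template

The synthetic template stands in for confocal, segmentation-derived root
geometries.  It is a bilaterally symmetric arrangement of rectangular-cell
files: epidermis, cortex, endodermis and pericycle flanks (18/22/14/12 µm
wide; 20–25 µm cells) around two 20-µm stele files; a 210 µm meristem and
a 590 µm elongation zone; a QC row at the origin; three columella tiers
below it (outermost = most rootward); LRC files flanking the cap and
meristem, ending 90 µm below the MZ/EZ boundary (the cap tip does not
reach the elongation zone; the LRC-to-epidermis handoff happens inside the
meristem, where it is relayed onward only by ABCB-mediated efflux — a
load-bearing piece of anatomy for the scenario contrasts).  Walls are
shared edge stretches between adjacent rectangles (0.2 µm thick), the
uncovered remainder of each edge is outer surface, and every (cell, wall)
incidence is one membrane segment with a face label.  All sizes and counts
are configuration (`TemplateSpec`).

## DII-VENUS readout

Auxin binds its receptor (TIR1/AFB, association 1 /µM/s, dissociation
1.2 /s, total pool 1 µM) and the complex degrades the constitutively
produced reporter (0.03 /µM/s) on top of a slow basal turnover (3e−4 /s).
At fixed auxin the network's steady state is closed-form and strictly
decreasing in auxin; the predicted map applies it per cell (the reporter
is nuclear; wall compartments are excluded) and is normalized to 1 at zero
auxin.  The rate constants are representative values placing the sensitive
range of the curve over the model's concentration range; every comparison
made with the map is invariant to monotone rescaling.  A co-integration
mode (`dii_trajectory`) exists for deposition experiments but the
steady-state map is the default: the reporter network equilibrates in
minutes, fast relative to organ-scale redistribution.

## Single-cell-file model

A line of 60 identical cells (25 µm) separated by 0.2 µm apoplastic gaps;
PIN on the distal end of each cell, one ABCB at each end, co-dependence
where they co-occur, an apolar influx carrier (weight 1) at both ends —
without carrier-mediated re-entry no front propagates at order-one
concentrations — and no synthesis, degradation or background efflux.  Cell
0 is clamped at concentration 1.  The wave speed is the slope of the
interpolated front position (threshold 0.5 by default) against time, after
discarding the first 20 % of frames (transient) and any frames in which
the front has saturated the far end of the file.  A diagnostic checks that
thresholds 0.3–0.7 give speeds within 10 % of their mean in the
travelling regime.

## Long-distance transport assays

The in-silico analogue of radiolabelled-auxin experiments: a fixed amount
of auxin (10× the wild-type steady-state mass of the deposit region, the
same amount for every genotype) is added at t = 0 over the shoot-boundary
cells (rootward assay) or the apical cells (shootward assay).  Because the
system is linear, the deposit evolves independently of the background and
is tracked as its own homogeneous solution.  The readout is the
retained-label share after 1 h: deposit-derived auxin still in the readout
region plus the label of auxin degraded there (a radiolabel stays in the
segment as labelled metabolite), divided by the total label retained in
the root.  For the shootward assay, label that has left through the
shootward cut counts as part of the basal segment (the real root continues
beyond the cut); label rinsed off the cap surface is lost in both assays.
A plain concentration snapshot at 1 h is not usable here: at the model's
turnover rate the bolus decays below numerical resolution and the ratio of
two such snapshots is noise.

## Synthetic observations and scenario selection

Synthetic DII-VENUS "images" are the forward-model reporter level per cell
multiplied by log-normal noise exp(N(0, σ²)) with σ = 0.1 by default —
imaging intensities are positive with roughly multiplicative error — from
a seeded generator.  Observed and predicted maps are compared as zone
summaries (mean ± SE per epidermis/cortex × MZ/EZ bin) through a
scale-invariant score: both mean vectors normalized to unit mean, summed
squared differences.  The exact statistic is pluggable.
`scenario_selection` scores every scenario over a permeability grid
(default 0.28/0.56/1.12 µm/s, all efflux permeabilities equal) across the
requested genotypes and ranks scenarios by their best total score.

What the generator does not emulate: nuclear segmentation errors, depth
attenuation, cell-to-cell reporter expression variability, or any spatial
noise correlation.  Passing recovery tests therefore show that the
inference machinery separates the scenarios' predicted patterns at a given
noise level — not that the discrimination would survive every artifact of
real confocal data.

## Numerical choices and degenerate inputs

Steady states: direct sparse LU, least-squares fallback, backward-error
residual check, round-off negatives clipped at zero (a genuinely negative
solution raises).  Integration: BDF, rtol 1e−7/atol 1e−10 (tissue) and
1e−8/1e−12 (cell file), tiny negative excursions clipped.  Wall–wall
diffusion couples walls sharing an endpoint, conductance
D_wall/(midpoint distance).  Zone assignment ties (centroid exactly at the
MZ boundary) resolve to MZ.  A cell centred on the midline has no
inner-lateral face (both lateral faces count as outer); no default rule
distinguishes inner from outer lateral faces, so this affects nothing.
Mass accounting weights cells by area and walls by length × thickness.

## Known limitations

- The template is a static 2D section: no growth, no 3D wrapping of the
  cap, rectangular cells only.
- The stele is homogenized into identical files; vascular subtypes
  (protophloem/protoxylem) appear only through the axial-influx stand-in.
- Carrier kinetics are linear (no saturation), and transporter expression
  does not respond to auxin.
- The co-dependent component is phenomenological — proportional to the
  count product — and cannot distinguish PIN-activates-ABCB from
  ABCB-activates-PIN.
- Boundary outflows are single constants, not mechanistic descriptions of
  the shoot connection or mucilage exchange.
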