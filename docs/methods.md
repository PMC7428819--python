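# Model and methods

`ctcsim` is a mechanistic agent-based model of circulating tumour cell
(CTC) clusters: groups of cancer cells travelling together through the
bloodstream, whose collective survival and resistance to dissociation are
believed to drive much of their metastatic potential. The model asks how a
cluster's **size** (number of cells) and **density** (how tightly packed
its contact network is) shape its response to two microenvironmental
pressures: **resource availability** (nutrients) and **threat intensity**
(an abstraction of any extrinsic stressor — cytotoxic drugs, immune
attack).

## Agents and environment

Two agent types interact on a 33 × 33 toroidal grid of patches (1,089
patches; the torus removes boundary effects). Cells are 0.5 × 0.5 patch
objects that do not move, divide, or form new contacts; all dynamics are
driven by energy budgets and cell death.

**Patches** carry two scalar fields. `threat` is fixed for the whole run.
`resource` evolves: every tick a fraction `d` degrades, and every
`replenish_period` ticks each patch receives a fraction `k` of its eight
Moore neighbours' stock (diffusive delivery). Two diffusion rules are
implemented:

* `literal` (default): the patch gains `k * sum(neighbours)` with no
  matching outflow. With `k` chosen as
  `k = (1 - (1-d)^P) / (8 (1-d)^(P-1))` (the default when `k` is unset),
  the injection exactly balances degradation over one replenish cycle, so
  a uniform field follows a stationary sawtooth around the scenario's
  resource level. This models an environment that keeps being perfused —
  as a capillary bed does — rather than a sealed box running down. With
  `d = 0.05` and period 10 the sawtooth spans roughly 1.23–1.59 × the
  nominal level (cycle mean ≈ 1.27 ×).
* `conserving`: each patch exports fraction `k` split equally among its 8
  neighbours; with `d = 0` the grid total is conserved exactly and uniform
  fields are fixed points. Useful for closed-system comparisons, but with
  any degradation the whole field decays to zero, which contradicts the
  premise that cells can persist indefinitely under optimal conditions.

**Cells** are defined by four coupled properties, updated every tick from
the current contact network:

* `surface = 1 / (n_links + 1)` — the fraction of a cell's surface exposed
  to the environment; every physical link to a neighbour shields a share.
* `vulnerability = 1 / (1 + exp(-((surface * a - 1) * b)))` — a steep
  sigmoid of exposure. With the calibrated `a = 3.38`, `b = 10.66`, a cell
  with one link is nearly fully vulnerable (≈ 0.99), two links ≈ 0.66,
  three ≈ 0.16, four ≈ 0.031, five ≈ 0.0094: clustering shields cells
  strongly and nonlinearly. The exponent argument is clamped to ±500.
* energy: each tick a living cell pays `threat * vulnerability` and, if it
  survives the death check, harvests
  `resource * metabolic * surface` from its patch.
* death: a cell dies when its energy reaches zero, or by **anoikis** —
  detachment-induced programmed death — when no living cell remains within
  the anoikis radius.

The per-tick schedule is: patch update → property refresh → threat cost →
simultaneous death check (energy deaths first; anoikis evaluated once on
the post-energy-death snapshot, so within-tick cascades cannot depend on
iteration order) → survivors eat. The cost-then-eat order follows the
behavioural description (a cell that dies mid-tick does not eat); the
single-formula variant that applies gain and cost together is available as
`combined_energy_update`. A run ends when all cells are dead, when no
death has occurred for `steady_window` consecutive ticks (steady state —
the end states all summary statistics refer to), or at the `max_ticks`
hard stop.

### Contact support vs. adjacency

Two cells are *linked* when their centres are within `link_radius`
(1 patch). The anoikis check uses a slightly smaller default radius
(`anoikis_radius = 0.9`): forming the junctions that suppress anoikis
requires close membrane contact, not merely adjacency. Cells inside dense
regions always have support (growth enforces a nearest neighbour within
0.85), while the single-file bridges between lobes of loose clusters are
laid at 0.92 spacing — linked, but without anoikis support. Bridges are
therefore the cluster's breaking points: their interior cells die early
and the cluster dissociates along them. Setting
`anoikis_radius = link_radius` restores the one-radius variant.

## Cluster initialization

Layouts are random but conditioned on the biology of the density classes
(compare the spherical / branched / loose morphologies of patient-derived
clusters). All draws respect a hard non-overlap separation of one cell
extent (0.5) and yield a single connected contact network; layouts are
deterministic given the seed.

* **High density** — one compact blob: cells drawn uniformly in an
  equal-area ellipse (axis ratio grows with cluster size: large clusters
  are the more irregular ones) and accepted only adjacent to the growing
  blob; every cell must start with ≥ 4 links (under-connected cells are
  resampled). Each blob embeds `max(2, round(0.05 N))` **cohesive
  kernels**: 6-cell motifs (a pentagon of circumradius 0.505 plus its
  centre) in which every pair is linked, so kernel cells keep ≥ 5
  contacts for life. These model the tightly adherent, desmosome-rich
  cell cores that make dense clusters hard to eradicate.
* **Medium / low density** — `max(2, round(coef * sqrt(N)))` dense lobes
  joined by single-cell-wide bridge chains along the minimum spanning tree
  of the lobe seeds. Each lobe is grown around a 4-cell kernel (seed plus
  tight triangle, mutually linked) at the class spacing; looser classes
  use wider spacing and larger per-lobe footprints, which is what makes
  their rims fragile. Chains span the open gap between lobe rims at 0.92
  spacing.

Density classes differ by area-per-cell, in-lobe spacing, lobe count and
bridge length (`ctcsim.params`); the qualitative resource levels map to
0.2 / 0.4 / 0.6 / 0.8 / 1.0 resource units and "very low" threat to 0.05.

## What the dynamics produce

Fragmentation is strictly death-driven (no mechanical forces): bridges
lose their unsupported cells, peripheral low-degree cells drain their
budgets, and each death raises surviving neighbours' exposure, so pruning
cascades inward until it reaches cells whose harvest outpaces their
threat cost. Because the resource level scales the harvest and the threat
level scales the cost, the *stable core* of a cluster — roughly, the
cells that keep enough links — shifts with both pressures:

* optimal environment: only isolated/chain/rim cells (≤ 2 links) are
  unsustainable. Tight blobs lose nothing (SR = 1); lobed clusters lose
  bridges and rims, fragmenting into their lobe cores (SR ≈ 0.5–0.75
  with 2–3 fragments — SI ≈ 0.25).
* threat 0.4: four-link cells become unsustainable; dense blobs erode
  from the rim inward, more deeply when low resource weakens the harvest,
  until the cascade stalls near the kernel-anchored core.
* resource deprivation alone (very low resource, very low threat) kills
  nobody in a dense cluster: the cost term stays negligible. Starvation
  only matters in combination with threat — low resource levels by
  themselves do not trigger death.

## Outcome statistics

Per run, at termination: survival ratio `SR = N_final / N_initial`
(resilience) and stability index `SI = SR / components` (resistance to
dissociation), where components are the connected components of the
surviving-cell network (an isolated surviving node counts as one;
`SI := 0` on extinction, keeping `SI ≤ SR`). `SR − SI` measures
fragmentation. Sweeps report per-run values; summaries give median, Q1,
Q3, min/max and 1.5·IQR fences (linear-interpolation quantiles).

## Parameters

| name | default | meaning |
| --- | --- | --- |
| `a`, `b` | 3.38, 10.66 | vulnerability sigmoid position / steepness |
| `d` | 0.05 | per-tick resource degradation fraction |
| `k` | balanced (≈ 0.0796) | diffusion fraction per replenish event |
| `replenish_period` | 10 | ticks between diffusion events |
| `metabolic` | 0.04 | resource → energy conversion factor |
| `initial_energy` | 0.2 | starting energy budget |
| `link_radius` | 1.0 | contact distance (patch units) |
| `anoikis_radius` | 0.9 | contact-support distance for anoikis |
| `threat_level` | scenario | 0–0.8; "very low" = 0.05 |
| `resource_level` | scenario | 0.2–1.0 resource units |
| `steady_window` | 110 | deathless ticks declaring steady state |
| `max_ticks` | 200 | hard stop |

The energy-scale constants (`metabolic`, `initial_energy`, `a`, `b`) and
the density-class geometry are a single calibrated set: they were chosen
so that, under the scenario definitions above, the model reproduces the
qualitative regime structure described under "What the dynamics produce"
— full survival of dense clusters in optimal and resource-deprived
environments, partial lobe-core survival of loose clusters, and
resource-modulated rim erosion under threat. One parameterisation is used
for every experiment; no scenario gets private constants.

## Numerical choices

* Degrees, costs and deaths are computed vectorised per tick; deaths in a
  tick are applied simultaneously from a snapshot, so results are
  independent of cell ordering (relabelling cells permutes nothing but
  ids).
* Per-run seeds in sweeps derive from `(base_seed, cell_index,
  replicate)` via `numpy.random.SeedSequence`: any subset of a design, in
  any order, reproduces identical rows.
* Toroidal distances use minimum-image displacement; neighbour queries use
  a periodic KD-tree. Kernel motifs avoid cell pairs at exactly the link
  radius, where floating-point noise could break a link.
* Quantiles are linear-interpolation (type 7).

## Scope and limitations

The generator emulates morphology classes (tight ellipsoidal blobs,
lobed/branched loose clusters) — not any specific patient's geometry; real
clusters also contain non-cancer cells, experience flow and deformation,
and their cells differ genetically — none of which is modelled. Threat is
a single scalar; there is no pharmacokinetics, no resource consumption by
cells (eating does not deplete patches, matching the published resource
update), no cell movement or division, and no within-cluster heterogeneity
in metabolic rate. End states depend on the steady-state window and hard
stop: the reported equilibria are "no deaths for 110 ticks" plateaus, and
scenarios whose cascades outlive 200 ticks are truncated there. Passing
tests therefore show that the *mechanisms* (shielding, anoikis,
death-driven fragmentation, stressor synergy) behave as designed, not that
any particular cell line will show these numbers.

Experiment sizes used by the shipped analyses: 200 replicates per design
cell (the full factorial at 1,000 replicates is a command-line flag away,
`--reps 1000`).
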