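# Methods

## The model

`chaperostart` simulates replicative aging of a budding-yeast mother cell as
the interaction of two modules that compete for a single pool of Hsp70/Hsp40
chaperones (Ssa1/Ydj1, lumped into one species `Chap`; the pair operates as a
functional unit and splitting it would only add unidentifiable parameters):

**Proteostasis module.** Folded protein (`ProtF`) is synthesized in
proportion to cell volume, turns over, and misfolds into monomers (`ProtM`).
Misfolded species aggregate through two pools: dimers (`Agg2`, standing for
all non-nucleated oligomers) and hexamers (`Agg6`, the nucleated form —
hexamers are used as the critical nucleus size). Chaperones bind misfolded
material 1:1 per protein unit (`C1`, `C2`, `C6` complexes), refold monomers
and dimers back into the folded pool, or hand them to degradation; chaperones
stay bound until their substrate is refolded or degraded, with one
documented exception below. The Hsp104 disaggregase is a catalyst with basal,
volume-coupled synthesis plus induction proportional to the coated-hexamer
count (`kh0·V + kh1·C6`, the minimal monotone form), and dissociates coated
hexamers into six chaperone-bound monomers; it acts only on nucleated
aggregates, not on monomer or dimer refolding.

Aggregate growth is autocatalytic. Alongside the classical free-phase
reactions (dimerization `2·ProtM→Agg2`, primary nucleation `3·Agg2→Agg6`,
templated nucleation `Agg6+3·Agg2→2·Agg6`), three recruitment reactions let
aggregation compete with chaperone holding: held monomers coalesce
(`2·C1→C2`), held dimers nucleate (`3·C2→Agg6+6·Chap`) and are recruited by
coated aggregates (`C6+3·C2→C6+Agg6+6·Chap`), and aggregate surfaces convert
free misfolded monomers wholesale (`C6+2·ProtM→C6+Agg2`, same for free
`Agg6`). In these recruitment steps the displaced chaperones are released —
aggregates win the tug-of-war for substrate; without such a channel the
collapse time would scale with the sixth-to-twelfth power of chaperone
abundance and a 50% chaperone surplus would (incorrectly) double lifespan.
Finally, aggregate surfaces adsorb free chaperones irreversibly
(`Agg6+Chap→Agg6+CB`, `C6+Chap→C6+CB`), reflecting the observed
sequestration of Ssa1/Ydj1 into deposits with low exchange rates; this
first-order sink is what ultimately exhausts the free pool.

**Start module.** Cyclin Cln3 is synthesized as a precursor (`Cln3c`) at a
volume-independent rate (Cln3 translation is limited by its upstream ORF, so
synthesis does not scale with ribosome content), requires an encounter with a
free chaperone to reach its nuclear active form (`Cln3n`), and turns over
quickly in all forms. Active Cln3 inactivates the Whi5 inhibitor mainly
through an explicit enzyme–substrate complex (`Cln3n+Whi5a→CW`,
`CW→Cln3n+Whi5i`), which makes the inactivation flux enzyme-limited: G1
duration then scales with the Whi5 copy number and with Cln3 activity, so
Whi5 dosage and Cln3 dosage both move Start timing (a purely mass-action
`Whi5a+Cln3n` channel is retained at a negligible rate for completeness, but
it alone would make G1 duration independent of Whi5 dosage). Start fires
when the active-Whi5 count drops to 25% of its G1-entry value (75%
inactivated); the rest of the cycle is a fixed 75-min timer.

**Cell cycle and geometry.** The mother compartment grows exponentially
during G1 only (budded-phase growth builds the bud, i.e. the future
daughter) and saturates at `v_max`. At division the mother keeps all
aggregate pools and chaperone-complex species in full — the asymmetric
retention that makes daughters young — plus her free-chaperone endowment
(the model has no chaperone synthesis, so partitioning the pool would drain
it geometrically for reasons unrelated to aggregation); soluble pools
(`ProtF`, `ProtM`, `Hsp104`, `Cln3c`) are partitioned binomially by the
bud's volume share, nuclear Cln3 and the kinase complex are cleared, and
Whi5 is reset to the same concentration as the previous generation, so the
Whi5 number at G1 entry grows with mother size. A lineage ends in permanent
G1 arrest when no division occurs for `arrest_timeout` (900 min, about ten
young generation times) or is censored at 75 generations. Replicative
lifespan is the budding count.

**Why cells age here.** Chaperone-held dimers seed nucleated aggregates at a
rate set by the misfolding flux (not by chaperone abundance); the mother
retains every aggregate, so coated hexamers ratchet up across generations
and the adsorption sink slowly erodes the free pool. Meanwhile the mother
enlarges a few percent per cycle, raising both her misfolding flux and her
Whi5 burden. Once aggregate surfaces are abundant, recruitment of misfolded
monomers ignites, aggregate mass overwhelms the chaperone pool by orders of
magnitude within a few generations, free chaperone collapses, nuclear Cln3
follows, G1 stretches — which accelerates growth and the Whi5 burden further
— and the lineage arrests. The terminal slowdown spans roughly the last 2–4
cycles, reproducing the abrupt senescence-entry point (SEP) phenomenology.

## Stochastic and deterministic simulation

Trajectories use the exact Gillespie direct method over the jump process,
with cell volume advanced deterministically between jumps and propensities
re-evaluated at each jump time; Start, division, arrest and sampling are
deterministic boundary events checked against every jump. Propensities use
combinatorial counting for repeated reactants (`k·C(n,2)` for `2X→…`) and
the volume convention: synthesis ∝ V, first-order reactions
volume-independent, all multi-molecular reactions ∝ 1/V. The lumped
reactions of order > 2 stand for encounter-limited sequences (first
collision rate-limiting), hence the bimolecular 1/V rather than the
dilute-gas 1/V^(m−1), which would switch nucleation off entirely as mothers
grow. The core loop is numba-compiled; a wild-type lineage (~10^6 reaction
events) takes well under a second.

The deterministic mode integrates the fluid-limit ODEs (`n^s/s!` in place of
`C(n,s)`) with LSODA, with identical event handling via root-finding on the
Start threshold. It backs the calibration constraints and the parameter
scan; for first-order networks its solution equals the SSA ensemble mean
exactly, which the test suite exploits as an oracle (together with a direct
chemical-master-equation solution on a small toy network).

Single cells differ persistently in growth physiology: each lineage draws
its growth rate and birth volume from seeded lognormals (CV 0.12 each)
around the cohort medians. This documented heterogeneity is what gives the
lifespan distribution its realistic width (SD ≈ 4–6 cycles at mean ≈ 30).

## Calibration

Parameters (minutes, fL, molecule counts) were selected by deterministic
screening followed by stochastic verification so that the young cell shows
~10,000 chaperones (exact, the moiety is conserved), ~1,000 Whi5 molecules
at G1 entry, ~100 total Cln3 molecules, a folded pool capped below 10^5
molecules (enforced, as in the source model, by raising folded-protein
degradation rather than clamping), young interdivision times of ~85–90 min,
and a mean wild-type replicative lifespan of ~30 cycles over 75 lineages.
`constraint_check` re-evaluates all of these; `parameter_scan` screens
candidate sets deterministically before spending stochastic cohorts;
`sensitivity_analysis` perturbs single parameters by ±1/10/25% with a shared
seed block, the protocol used to choose the shipped mutant grades
(`data/scenarios.yaml`): deletion-grade reductions for genes with backups
(cln3 ×0.5 of Cln3 synthesis — basal Cln1,2 remain; ydj1 ×0.25 of the
chaperone pool — Sis1 remains), overexpression grades (oCLN3 ×3; oSSA1YDJ1
×1.5, the modest increase attainable from a galactose promoter), growth and
size variants, and the proteotoxic substrate. The PFD scenario adds a
constitutively misfolding substrate feeding the shared aggregate pools; CD
adds an inert control protein at the same expression level.

## Tunable parameters that matter most

| parameter | default | units | role |
|---|---|---|---|
| `chap_total` | 10000 | molecules | chaperone endowment; collapse threshold |
| `k_misfold` | 4.5e-3 | 1/min | misfolding flux (≈30/min young); master aggregation clock |
| `k_nucleate_held` | 2.0e-3 | 1/min | seeding rate from held dimers (stochastic onset) |
| `k_template_held` | 6.0e-3 | 1/min | autocatalytic ratchet growth |
| `k_adsorb` | 8.0e-5 | 1/min | chaperone adsorption on aggregate surface; terminal drain |
| `k_cln3_syn` | 25 | molecules/min | Cln3 supply; Start strength |
| `start_threshold_fraction` | 0.75 | – | Whi5 inactivation fraction firing Start |
| `growth_rate` | 2.75e-3 | 1/min | G1 growth of the mother; sets the size ratchet |
| `arrest_timeout` | 900 | min | operational definition of permanent arrest |

## Analysis procedures

* **Aligned ensembles** shift each trace so its final budding sits at t = 0
  and report the mean with Student-t 95% confidence limits per time point
  (bootstrap available for skewed observables).
* **Survival curves** are Kaplan–Meier estimates treating generation-cap
  lineages as right-censored; without censoring they reduce to the empirical
  fraction with lifespan > g, and the sum of S over generations equals the
  mean lifespan.
* **SEP detection**: first generation whose interdivision time exceeds the
  young mean (first half of the series) plus 3 SD, with the exceedance
  sustained to death over at least 2 generations. The 2-generation minimum
  departs from a single-point rule deliberately: a lone final outlier fires
  such a rule on ~0.1% of perfectly healthy noisy series, while the
  sustained form produced zero false positives in 1000 noisy constant
  series. The detector is validated on planted changepoints only; it is a
  stand-in for the published SEP definition, which this package does not
  reimplement.
* **Logistic event models** are maximum-likelihood fits (statsmodels) of a
  binary event within a follow-up window (default 180 min) on a continuous
  reading, reported as an odds ratio per predictor unit with a Wald 95% CI;
  perfect separation is flagged, not raised.
* **Mann–Whitney U** uses the exact null for n ≤ 16 without ties and the
  tie-corrected normal approximation otherwise (scipy).

## Imaging metrics

Foci are pixels ≥ 30% brighter than the median masked intensity, grouped by
8-connectivity, kept when the component area reaches the minimum size. The
minimal size of 0.4 µm is dimensionally ambiguous in the protocol it mirrors
and is interpreted as an equivalent-circle diameter (area ≥ 0.126 µm²); both
the threshold and the size are configurable. The nuclear compartment is a
projected disc of 17% of the cell area centred on the gravity centre of the
brightest pixels — operationalized as the top intensity decile weighted by
excess over the decile threshold, so flat background carries no weight.
The nuclear-over-cytoplasm excess implemented here is a simple documented
stand-in (disc mean minus cytoplasm mean), not the full optical correction.
The FLIP mobility index is the inverse fluorescence half-life of an
exponential fit (log-linear seed refined by nonlinear least squares, no
offset by default) to the normalized unbleached-region signal, with the
empirical size correction MI_c = MI·r^1.49.

## Synthetic data

Generators are pure functions of (spec, seed). Lineage cohorts emulate the
*statistical structure* of microfluidics mother-cell data: 10-min sampling,
lognormal young interdivision times, a planted SEP (×2.5 slowdown over the
last 3 generations), Gaussian fluorescence noise, and a per-cell foci-onset
indicator coupled to death-within-180-min at a planted odds ratio. Images
are uniform-background cells with planted nuclear discs and circular foci
plus Gaussian noise; FLIP traces are exponential decays. None of these model
optics, segmentation error, bleaching drift or non-Gaussian noise, so
passing recovery tests demonstrates the correctness of the estimators, not
their robustness on real micrographs.

## Numerical choices and degenerate inputs

Whi5 reset rounds to the nearest integer with a floor of 1. Ties between
simultaneous boundary events resolve as sampling < division < arrest.
Deterministic integration uses rtol/atol 1e-6 by default; negative
integrator excursions are clipped in rate evaluations (tighter tolerances
are counterproductive near proteostasis collapse, where the clipped
rate law has a kink at zero free chaperone and the step size collapses). `detect_sep` returns None (with a warning)
below 5 generations; `mobility_index` refuses non-decaying traces;
`logistic_event_model` requires both outcome classes. Networks with zero
propensity everywhere simply advance to the horizon.

## Known limitations

* Aggregates have no spatial identity: retention at division is a rule, not
  a geometry; there is no distinction between a single deposit and dispersed
  aggregates.
* The Start module has no Cln1/2 positive feedback; Start is strictly
  Cln3-driven, so genotype effects on lifespan flow only through Cln3.
* Absolute time is calibrated only loosely (young cycle ≈ 87 min);
  conclusions should be drawn from relative lifespans, not minutes.
* The free-chaperone pool is a conserved mother endowment; chaperone
  synthesis/turnover and the stress response beyond Hsp104 induction are
  not modelled.
* Interdivision times in the model drift upward slowly with mother size
  before the terminal collapse, so the detected SEP precedes the steep
  chaperone crash by several generations; the SEP aligns instead with the
  *onset* of the sustained chaperone decline (see the acceptance suite).
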