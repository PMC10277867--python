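# Methods

This note documents the modelling conventions, parameter provenance,
numerical choices and known limitations of `sgltpbpk`. It states nothing
that the test suite or `scripts/acceptance.py` does not itself compute.

## Disposition model

The body is 14 compartments: lung, heart, brain, muscle, adipose, skin,
bone/rest, spleen, gut wall, liver, kidney, reproductive organs, and
arterial and venous blood. All tissues are perfusion-limited: tissue and
exiting blood are in instantaneous equilibrium through the
tissue-to-plasma partition coefficient Kp, so for a tissue of volume `Vt`
perfused at whole-blood flow `Qt`,

    Vt dCt/dt = Qt·Rbp · (Ca − Ct/Kp_t).

Flows are whole-blood flows from the pinned reference table
(`data/physiology.csv`; cardiac output 336 L/h, regional flows balancing
it exactly); they enter the transport equations as plasma-equivalent
flows `Q·Rbp`, which is where the blood-to-plasma ratio acts. A lower
Rbp therefore slows tissue distribution (and raises/narrows the oral
peak) without changing steady-state partitioning — the behaviour the
sensitivity analyses of this drug class show for Rbp.

The lung sits between the venous and arterial pools. The liver receives
the hepatic artery plus the portal stream: venous outflow of spleen and
gut wall, and the absorbed oral dose after gut first-pass extraction.
Hepatic elimination is a linear plasma clearance applied to the
liver-exit concentration `C_liver/Kp_liver`, capped at the hepatic
plasma flow (well-stirred sanity cap). Renal elimination is filtration
only, `GFR × fup`, applied to the kidney-entry (arterial) concentration
— the convention the source parameter tables themselves use for renal
clearance of these compounds.

**Clearance basis.** The per-kilogram total and hepatic clearances in the
compound table are treated as plasma clearances (the convention of the
commercial platforms these parameter sets circulate in). The published
observed exposures of empagliflozin and henagliflozin are slightly above
what a bioavailability of 1 allows under this reading, so their
predictions sit at the absorption ceiling and carry AUC fold errors of
~1.2–1.4 — still well inside the two-fold qualification bound. The
alternative whole-blood reading removes that ceiling but makes
ertugliflozin's observed Cmax unreachable at any absorption speed, which
is why it was rejected.

## Partition coefficients

Kp values use the Rodgers–Rowland mechanistic equations for neutral
species: partitioning into extra-/intracellular water, neutral lipid
(`P·f_NL`), neutral phospholipid (`(0.3P+0.7)·f_NP`) and albumin-mediated
binding scaled by the tissue-to-plasma albumin ratio, with the albumin
association constant back-calculated from `fup`. Adipose uses the
vegetable-oil correction `log Pvo = 1.115·logP − 1.35`. The gliflozins
are C-aryl glucosides without a relevant ionisable centre at
physiological pH, which is what justifies the neutral-species branch.
Tissue composition constants are pinned in `data/tissue_composition.csv`
(a standard compilation); the unit tests verify the implementation
against an independent transcription of the equations to 1e-6.

Vss is the blood volume on a plasma-concentration basis (`V_blood·Rbp`)
plus `Σ Vt·Kp_t`, per kg of body weight.

## Oral absorption (ACAT)

Nine gut compartments — stomach, duodenum, jejunum 1–2, ileum 1–3,
caecum, ascending colon — with first-order transit. Defaults: stomach
0.25 h (fasted), small-intestinal transit 3.3 h split by the standard
fractions (0.08/0.29/0.23/0.18/0.13/0.09), colon 13 h split by luminal
volume. Luminal volumes are static; dissolved concentration is
`amount/volume`.

Dissolution is a lumped Noyes–Whitney term,
`rate = z · m_undissolved · (Cs − C)`, with `z` defaulting to 45 per
(mg/mL)·h — the z-factor of a micronised ~10 µm powder
(`z = 3D/(ρ·h·r)`). The physically plausible particle-size range 5–70 µm
maps to z ≈ 2–150, and the sotagliflozin calibration is bounded to that
range. The printed solubilities carry a unit tag read as mg/mL (the mg/L
reading is orders of magnitude below the known aqueous solubilities of
these drugs); no bile-salt solubilisation is modelled.

Absorption of dissolved drug is `ka_i = Peff · ASF_i` with geometric
scale factors `ASF_i = coeff · 2/r_i` (cylindrical surface-to-volume);
colonic segments are down-weighted ×0.1. The single coefficient is the
per-compound absorption calibration parameter, standing in for the
proprietary per-segment ASF model of the commercial platform. A scalar
gut first-pass extraction acts on the absorbed flux before the portal
vein; it is a calibration parameter for every compound because, with the
tabulated clearances fixed, the observed lowest-dose exposures imply
oral bioavailabilities below the permeability ceiling (small fitted
values for ertugliflozin/empagliflozin/henagliflozin, ~0.9 for
sotagliflozin, whose bioavailability is known to be low).

## Calibration and qualification

`calibrate_compound` fits, per compound, (ASF coefficient — or the
dissolution z-factor for solubility-limited sotagliflozin, with the ASF
coefficient held permeation-non-limiting — stomach transit, gut
extraction) to the observed AUC/Cmax/Tmax of the lowest published dose
(log-scale least squares, Tmax half-weighted because it is
grid-quantised and the noisiest published metric). All other dose levels
are simulated without further adjustment and scored by
`max(obs/pred, pred/obs)`; the model qualifies when every AUC and Cmax
fold error is ≤ 2. Under this protocol all 17 published dose levels
qualify (max fold error ≈ 1.5, henagliflozin Cmax at 5 mg).

The profile-fit layer (`fit_parameters`) does bounded least squares on
log concentrations (floor 1e-3 ng/mL, equalising absorption and terminal
phases) with a seeded multistart; uncertainties come from the Gauss–
Newton covariance at the optimum. Parameter recovery on synthetic data
(Peff, Rbp at 10 % multiplicative noise, sparse clinical grid) returns
both within ~5 %.

## Kidney glucose and transporter-inhibition conventions

The proximal tubule is quasi-steady: segment concentrations are
algebraic in the instantaneous plasma concentration. Luminal fluid flows
entering S1/S2/S3 default to GFR × (1.0, 0.6, 0.4) (about two-thirds of
filtrate reabsorbed along the proximal tubule); filtered drug
(`GFR·fup·Cp`) concentrates accordingly. Glucose transport defaults:
SGLT2 Km 2 mmol/L with 135 mmol/h capacity split 60/40 over S1/S2;
SGLT1 Km 0.4 mmol/L, 15 mmol/h in S3 (≈2.5 mmol/min total capacity,
~90/10 split — systems-pharmacology literature values, not fitted here).
Reabsorption in a segment is capped at the glucose flux arriving there,
so the cascade conserves glucose exactly.

Inhibitor-concentration conventions per site (all configurable):

* **Duodenum / jejunum I (SGLT1)** — total luminal drug concentration
  (dissolved + suspended, amount/volume). The dissolved-only,
  solubility-capped alternative cannot reproduce the published behaviour
  of sotagliflozin, whose reported jejunal concentration exceeds its own
  reference solubility — in vivo, bile-salt solubilisation and the
  suspended reservoir at the mucosa keep the effective exposure above
  the aqueous cap. Luminal glucose is fixed at the source convention of
  1670 mmol/L (physiologically implausible as a molarity, but the
  established reference condition for this calculation; only S/Km
  matters in the ratio).
* **S1/S2 (SGLT2)** — kidney tissue concentration (`Kp_kidney·Cp`).
  The free-filtrate alternative caps henagliflozin's peak SGLT2
  inhibition near 82 % even at infinite glucose Km, inconsistent with
  the near-complete SGLT2 occupancy this drug class shows clinically at
  approved doses; the tissue basis reproduces ≥97–99 % saturation for
  all four drugs.
* **S3 (SGLT1)** — free filtrate concentration (2.5-fold concentrated
  by water reabsorption), against the S3 glucose concentration computed
  with SGLT2 inhibited by the same simulation. This asymmetry
  (tissue-based SGLT2, filtrate-based SGLT1) is deliberate: the two
  bases are each anchored to the published site-specific magnitudes,
  which no single convention reproduces simultaneously.

## Virtual population and synthetic data

Virtual subjects are sampled parametrically: truncated-normal weight
(default 70 ± 10 kg, ±3σ) and height, log-normal GFR around
127 mL/min/1.73 m² (CV 0.2, mean-corrected), volumes scaling ∝ W and
flows ∝ W^0.75. This replaces a demographic database with the same
statistical role (inter-subject physiological variability only; compound
parameters fixed). The "90 % interval" of cumulative urinary excretion
is the pointwise 5th–95th percentile prediction band (inclusive
linear-interpolation percentiles) across subjects.

The synthetic-data generator forward-simulates a truth model, samples the
default clinical grid (0.25–48 h, 12 points) and applies mean-unbiased
multiplicative log-normal noise (default CV 0.15; 0.10 in the recovery
experiment). Truth parameters live in a sidecar the fitting path never
reads. What passing recovery tests show is identifiability under the
model's own noise assumptions — not robustness to model misspecification,
digitisation error or real assay error structure.

## Numerical choices and problem sizes

LSODA integration at rtol 1e-8 / atol 1e-10 on a 0.05 h output grid over
72 h (single dose); halving tolerances moves AUC by <1e-6 relative.
Multiple doses are integrated piecewise with stomach re-initialisation
at each dose event (no superposition). Global mass balance closes to
<1e-12 of dose. Calibration and population loops use rtol 1e-6 /
atol 1e-9 and (for the population) a 0.5 h grid over 48 h; the
population-coverage check uses a 260-subject pool (100 for the band,
the rest held out, 200 Monte-Carlo repeats of 10 points), sized so the
whole suite runs comfortably on one CPU.

Negative state values at solver round-off level are clipped to zero in
result views only; dissolution is signed, so a segment transiting into
supersaturation re-precipitates rather than creating mass.

## Known limitations

* Monodisperse dissolution cannot reproduce, for sotagliflozin, both the
  observed plasma peak (Tmax ≈ 1 h) and hours-long luminal retention of
  undissolved drug; a particle-size distribution would be needed. The
  calibrated model favours the plasma data, so predicted jejunal content
  at 3 h (and quantities derived from it) undershoots published values.
* The published site-specific inhibition maxima are mutually
  inconsistent under any single (S, Km, concentration-basis) choice for
  the intestinal sites; with the literature SGLT1 Km (0.4 mmol/L) the
  duodenal maxima for high-dose sotagliflozin saturate near 99 % and the
  low-permeability empagliflozin value overshoots by ~2×.
* No enterohepatic recirculation, luminal degradation, food effects,
  transporter-mediated renal drug handling, nonlinear metabolism or
  disease (T2DM) physiology. IV dosing is out of scope.
* Henagliflozin's peak S1/S2 SGLT2 inhibition computes to ~97.4 %, just
  under the 99 % saturation bound the class is described by; its high
  SGLT2 Ki (2.38 nM) and moderate kidney Kp leave no honest headroom
  within these conventions.
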