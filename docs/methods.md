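# Methods

## The linkage model

A kinase is represented as a discrete conformational ensemble: states
$s = 1 \dots n$ with relative statistical weights $w_s$ ($w_1 = 1$). Two
non-overlapping ligand sites are considered — orthosteric (ATP pocket) and
allosteric (e.g. the TPX2/monobody pocket of Aurora A, the myristate pocket
of Abl). A ligand $L$ binds state $s$ with dissociation constant
$K_{L,s}$; $K_{L,s} = \infty$ encodes state-exclusive binding and is
handled symbolically (the corresponding Boltzmann factor is exactly zero,
never a large float).

The grand partition function over the $4n$-species lattice
(conformation × {apo, orthosteric-bound, allosteric-bound, doubly bound})
at free concentrations $[O]$, $[A]$ is

$$Z = \sum_s w_s\left(1 + \frac{[O]}{K_{O,s}}\right)
              \left(1 + \frac{[A]}{K_{A,s}}\right)
      + \sum_s w_s (c_s - 1)\frac{[O]}{K_{O,s}}\frac{[A]}{K_{A,s}},$$

where $c_s \ge 0$ is an optional per-state ternary coupling factor
($c_s = 1$: pure conformational linkage, the default; $c_s \ne 1$: direct
interaction between the two bound ligands in state $s$).

Derived quantities:

* **Apparent affinity.** One ligand on a pre-equilibrated ensemble is
  exactly a single site: $1/K_\text{app} = \sum_s f_s / K_{L,s}$ with
  $f_s$ the populations of the ligand-free (but background-exposed)
  ensemble. A background partner at free concentration $b$ rescales the
  weights by $(1 + b/K_{B,s})$; $b \to \infty$ is taken analytically
  ($w_s \to w_s/K_{B,s}$, excluded states drop out).
* **Cooperativity factor.** $\alpha = K_\text{app}(\text{apo}) /
  K_\text{app}(\text{partner saturated})$; $\alpha > 1$ is positive
  cooperativity. Closure of the thermodynamic cycle makes $\alpha$
  identical for either probe; the package asserts this to $10^{-9}$ on
  1,000 random schemes.
* **Shift-only ceiling.** For a probe exclusive to the minor state of a
  two-state ensemble with $K_\text{eq}$ = [minor]/[major], the supremum of
  $\alpha$ over all partners is $(1 + K_\text{eq})/K_\text{eq}$: once the
  ensemble is fully shifted into the probe's state nothing more can be
  gained. At the Aurora A value $K_\text{eq} = 0.67$ the ceiling is 2.49 —
  above the measured 2-fold for one inhibiting monobody, below the 3-fold
  of the other, which therefore requires extra affinity for the
  drug-bound state (modeled by $c_s > 1$).
* **Inverse problem.** `solve_selectivity` inverts the fold-change
  equations for the partner's selectivity
  $s = K(\text{active})/K(\text{inactive})$: a 16-fold weakening of an
  active-exclusive probe at $K_\text{eq} = 0.67$ gives $s = 38.4$, which
  in turn predicts a 2.40-fold tightening for an inactive-exclusive probe.
  Tightening requests at or above the ceiling raise an infeasibility error.

**$K_\text{eq}$ convention.** Throughout, a two-state ensemble is ordered
(major/active first) and $K_\text{eq}$ = weight(second)/weight(first) =
[inactive]/[active]. Only this reading places the ceiling (2.49) between
the measured 2- and 3-fold monobody cooperativities; the opposite reading
($K_\text{eq} = 1/0.67 = 1.49$) would cap the shift-only gain at 1.67,
below even the 2-fold that shift alone is supposed to explain. The
constructor takes the scalar directly, so the convention is explicit at
every call site.

## Mass balance

ITC and FRET operate with enzyme comparable to ligand, so free
concentrations are solved from the coupled conservation equations by
nested bracketed root-finding (Brent) on $[0, \text{total}]$; each
residual is monotone in its own free concentration, guaranteeing the
bracket. Residual mass-balance error is verified to $10^{-8}$ relative.
Two ligands competing for one site (replacement ITC) use the closed-form
trigonometric root of the cubic in free enzyme; because that expression
cancels catastrophically when free enzyme is small compared to the totals,
the root is polished by Newton steps on the monotone mass-balance
residual, and agreement with a bisection oracle to $10^{-8}$ is part of
the test suite.

## Experiment models

**ITC.** Injection heats are $q_i = V_0 \sum_X \Delta H_X\,
\Delta[\text{complex}_X]_i$ with the "overflow" displaced-volume
convention: each injection of $dV$ scales pre-existing cell concentrations
by $(1 - dV/V_0)$ before syringe material is added. The cell volume is
190 µL (low-volume instrument) with 2 µL injections. Direct fits estimate
$(K_d, \Delta H, n)$ on $\log_{10} K_d$, multistart over five decades of
initial $K_d$; the first injection is always excluded from the objective.
Replacement fits hold the weak competitor's $(K_A, \Delta H_A)$ fixed from
a prior direct fit and fix $n = 1$ (weakly identifiable in that mode).
Confidence intervals are asymptotic 68.3% (±1σ) from the Jacobian. A
c-value ($[\text{cell}]/K_d$) below 1 triggers a poorly-constrained
warning; tight binders (c ≫ 1000) should be measured by replacement, which
is what the end-to-end pipeline does for the orthosteric drug.

**FRET (Morrison).** At 10 nM enzyme the bound fraction follows the
tight-binding quadratic
$F = F_0 + A\,\frac{[I] + E_t + K_d - \sqrt{([I]+E_t+K_d)^2 - 4E_t[I]}}{2E_t}$.
$E_t$ is fixed to the pipetted value (a flag allows co-fitting for
sensitivity analysis); fitting is ordinary least squares on linear
fluorescence with homoscedastic weights. The step-function diagnostic
re-simulates the fitted curve at $K_d/10$ and $K_d/100$: if either differs
from the fit by less than 3× the residual RMS, the curve is flagged
titration-limited (the titration is counting molecules; the fitted $K_d$
is an upper bound). The factor 3 demands clearly-above-noise separation
and is deliberate; at the boundary $K_d \approx E_t$ the verdict follows
the supplied noise level.

**Activity.** $k_\text{obs} = -\text{slope}(A_{340})/(\varepsilon\,l\,[E])$
with $\varepsilon_{340}(\text{NADH}) = 6220\ \mathrm{M^{-1}cm^{-1}}$,
path length configurable (plate geometry varies). Mechanistic fractional
activity is $\sum_s \text{cw}_s \times$ (fraction of state $s$ with a
drug-free orthosteric site), normalized to the zero-dose value; catalytic
weights cw are per-conformation activities in [0, 1]. ATP optionally
enters as a state-selective orthosteric competitor whose complexes remain
productive — it shifts the ensemble and competes the drug without
inhibiting, reproducing the observed ordering changes between binding and
activity assays. Empirical curves use the four-parameter logistic with the
zero-dose points anchoring the top; the dose for 10% residual activity is
defined relative to the same curve's own uninhibited rate and inverted in
closed form (4PL) or by bracketed root-finding (mechanistic). The two
routes agree within 2% on model-generated curves — the 4PL is an
approximant, not the mechanism. Jackknife standard errors resample the
concentration points of the curve.

## Presets and calibration

Preset schemes encode the printed anchors and fill everything else once:

| quantity | value | status |
|---|---|---|
| Aurora A $K_\text{eq}$ (inactive/active) | 0.67 | printed |
| activator monobody weakening | 16-fold | printed |
| inhibiting monobody folds | 2 / 3 | printed |
| imatinib $K_d$ AblKD / AblFL | 15 / 72.4 nM | printed |
| imatinib–asciminib folds KD / FL | 2 / 4 | printed |
| asciminib-alone inhibition KD / FL | 30% / 93% | printed |
| SKI preference for AblFL over AblKD | 5-fold | printed |
| danusertib $K_d$(inactive) | 1 nM | assumed anchor |
| monobody $K_d$(preferred state) | 100 nM | assumed anchor |
| asciminib / SKI $K_d$(closed) | 0.5 / 100 nM | assumed anchor |
| AblKD open⇌closing-competent $K_\text{eq}$ | 0.01 | assumed |
| binding enthalpies | −30…−60 kJ/mol | illustrative; only the 22.8 kJ/mol difference is anchored |

Derived parameters are solved at preset build time: danusertib selectivity
38.4 from the 16-fold; the AblFL closed-state weight (4.74), imatinib's
closed-state $K_d$ (0.37 µM) and asciminib's open-state $K_d$ from the
simultaneous 72.4 nM / 4-fold / 93% constraints; SKI's open-state $K_d$
from the 5-fold construct preference. Two calibrations use the ternary
coupling factor because shift alone is provably insufficient: the
3-fold monobody (ceiling 2.49) and the 2-fold imatinib–asciminib effect on
the isolated Abl kinase domain (shift-only maximum 1.40 given the 30%
inhibition floor — the study itself attributes the excess to a further
intra-domain equilibrium, which the coupling factor absorbs generically).
For the same reason asciminib's open-state $K_d$ is calibrated per
construct (22 nM on AblKD, 8.5 nM on AblFL): one tied-Kd ligand cannot
satisfy the 30% and 93% floors simultaneously once the 72.4 nM imatinib
anchor fixes the closed-state weight.

## Synthetic data

Generators emulate the stated experimental designs (20 µM cell / 150 µM
syringe monobody titrations, 10 nM enzyme FRET with optional 200 nM
allosteric background, 20 nM enzyme activity assays). Noise is additive
Gaussian on ITC heats (σ as a fraction of the largest |heat|) and
multiplicative on rates (replicate-style CV); generation is
deterministic given the seed (NumPy PCG64). Noiseless output equals the
forward models exactly, and every simulate → fit pair round-trips to
$10^{-6}$ without noise. What a green recovery test establishes: the
fitting pipeline is unbiased (<2%) and precise (<10% RMSE) at 1%
instrument noise *under the model's own assumptions*. What it does not:
real thermograms carry baseline drift, injection artifacts and
concentration errors that are explicitly out of scope.

## Numerical choices

* Root-finding: Brent with machine-precision tolerances, iteration cap
  200 (mass balance) / 500 (oracles); cubic roots Newton-polished.
* Fits: `scipy.optimize` trust-region reflective with
  ftol = xtol = gtol = 1e-15 so noiseless round trips are exact to the
  tested 1e-6; $K_d$ always on a log scale with five-decade multistart.
* Saturation limits are analytic, never large numbers; exclusive binding
  is an exact zero in the lattice.
* Degenerate inputs raise typed errors (configuration, undefined affinity,
  cannot-saturate, infeasible cooperativity, unreachable inhibition)
  rather than returning sentinels; the synergy grid is the one exception —
  an unreachable row is recorded as NaN because partial grids are the
  normal scientific outcome there.

## Known limitations

* Equilibrium only: no kinetics of conformational exchange or binding.
* The ternary coupling factor is a generic stand-in for mechanisms the
  two-site/N-state model cannot express (hidden sub-states, direct
  ligand–ligand contacts); it is calibrated, not predicted.
* Enthalpies beyond the one printed difference are illustrative, so
  simulated heat magnitudes are realistic but not literature values.
* Replacement-ITC simulation in the pipeline folds the allosteric
  background into the exact single-site equivalent of the orthosteric
  site; depletion of the background ligand during the titration is
  neglected (it is 1000-fold above its $K_d$ in those designs).
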