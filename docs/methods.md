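# Methods

This note documents the models, the parameter choices that matter, the
numerical decisions, and what the synthetic-data tests do and do not show.
Nothing here states an empirical result that the test suite or the analysis
scripts do not themselves compute.

## In vitro: open-loop flow-through dissolution

The flow-through cell is an ideally mixed vessel of volume `V` (default
20 mL, a typical powder/tablet cell working volume; the cell size of the
original experiment is not published) perfused at the protocol flow rate
`Q(t)`. Dissolved drug obeys

    dA_cell/dt = r_DLM(t) − (Q/V)·A_cell,     dA_out/dt = (Q/V)·A_cell,

and cumulative percent dissolved counts `A_out + A_cell` against the dose,
as a fraction collector would. At a media switch the cell contents are
replaced by the incoming medium instantaneously with dissolved drug carried
over; switches follow the half-open convention `[start, start+duration)` so
the lookup in the ODE right-hand side is deterministic. The default gradient
is FaSSGF 0–30 min at 8 mL/min, then FaSSIF-V2 (30–70), FaSSIF-V2 midgut
(70–150), SIF Ileum-V2 (150–210) and FaSSCoF (210–360) at 4 mL/min.
The three lower-intestinal media carry the published level-II compositions
(maleate buffer, pKa 1.83/5.99; totals 19.3/52.8/75.8 mM; pH 6.8/7.5/7.8;
taurocholate 1.5/0.8/0 mM); FaSSGF and FaSSIF-V2 use standard literature
compositions (pH 1.6, ~80 µM bile; pH 6.5, 3 mM taurocholate) since the
source text only notes they were toolkit-internal.

## Dissolution kinetics (DLM)

Spherical-particle Nernst–Brunner kinetics with a capped diffusion layer:

    dM/dt = S · Σ_i n_i · 4π r_i (r_i + h_i) · (D / h_i) · (Cs − Cb),
    h_i = min(r_i, hmax),    hmax = 30 µm (default)

with the dimensionless DLM scalar `S` multiplying the whole rate. The
commercial implementation names this model without printing its equation;
the form above is the standard published one, and since any scalar placement
is rate-linear the whole-rate convention is adopted. The rate floors at zero
at saturation — no precipitation or supersaturation is modelled, because the
workflow models release only. The particle population defaults to
monodisperse 10 µm (typical spray-dried ASD); the fitted scalar absorbs
size-distribution error by design, which is exactly the role the scalar
plays as a tuning parameter. Tacrolimus is non-ionizable in the studied pH
range, so per-medium solubility is a configured "apparent amorphous" value,
not computed from pH.

Default apparent solubilities are 2–8 µg/mL (gastric 2, proximal/mid gut 8,
distal ileum 6, colon 4), scaling with bile-salt content. The low-µg/mL
range matters structurally: the 5-mg dose against ~150 mL of total GI fluid
(~33 µg/mL) must exceed solubility for absorption to be dissolution- and
solubility-limited — the BCS II premise of the whole extrapolation — and it
is what keeps undissolved solid transiting into the ileum and colon so the
distal scalars are identifiable at all. Early drafts with 20–50 µg/mL
dissolved everything proximally and made the distal scan degenerate.

Numerics: the `m^(1/3)` radius–mass relation has unbounded slope at particle
exhaustion; the rate is multiplied by `m/(m+ε)` with ε = 1e-7 mg, which
keeps the right-hand side Lipschitz, leaves mass balance untouched and
changes release by less than the solver tolerance. Integration is LSODA at
rtol 1e-8 / atol 1e-10 (scalar sweeps span orders of magnitude), with BDF
and Radau fallbacks for extreme scalars.

## Scalar estimation

One scalar per medium is estimated from an observed cumulative profile by
bounded least squares on log₁₀-scalars (bounds 1e-4–1e3, unweighted SSE in
percent units, five log-spaced multistarts, best SSE kept; a start that
already fits to SSE < 1e-6 short-circuits the rest). The procedure honours a
three-media-per-experiment constraint as an object of study, in three
chained windows:

* W1 {FaSSGF} {FaSSIF-V2} {midgut} — retain all three;
* W2 {FaSSGF+FaSSIF-V2} {midgut} {SIF Ileum-V2} — retain only the ileal
  scalar;
* W3 {FaSSIF-V2} {SIF Ileum-V2} {FaSSCoF} — retain only the colonic scalar.

Grouped media share one scalar inside a window and lumped scalars are
discarded afterwards. Protocol segments not named in any group of a window
(FaSSGF and midgut in W3) attach to the nearest preceding group — the way a
three-media virtual experiment lumps the early gradient. A `joint=True`
escape hatch fits all five scalars at once for comparison.

Non-estimability: a medium is flagged when observed release is ≥ 99 % before
its segment starts, when fewer than two observations fall inside its
segment, or when the fit pins its scalar within 2× of the lower bound (a
flat profile carries no information; this last rule goes beyond the
qualitative published criterion, which does not cover that case). Flagged
media map to a sentinel over their GI regions (FaSSGF→Stomach,
FaSSIF-V2→Duodenum, midgut→Jejunum I–II, SIF Ileum-V2→Ileum I–IV,
FaSSCoF→Colon) that must be resolved by sensitivity analysis.

Self-consistency (noise-free profiles generated and refit by the package)
recovers W1 scalars essentially exactly; the retained distal scalars carry a
small bias from the lumped windows, with median relative error across random
scalar draws well under 10 % (asserted in the test suite). Under model
mismatch (e.g. Weibull-shaped data whose early rise exceeds what the gastric
medium can carry) fitted proximal scalars can pin at the upper bound,
meaning "as fast as washout allows".

## In vivo: GI absorption

Nine compartments in fixed order; solid and dissolved pools transit
sequentially at first-order rates. Gastric residence 0.25 h; total
small-intestinal residence 3.32 h apportioned over the seven SI compartments
proportionally to the in vitro media residence durations (40/40/40 min for
Duodenum and Jejunum I–II, 15 min each for Ileum I–IV); colonic residence
12 h. Fluid volumes 50/15/25/20/10/10/10/10/50 mL, radii 1.75 cm (SI) and
2.5 cm (colon). Regional solubility equals the matching biorelevant medium's
value — that identification is the design premise of the media gradient.

Per-region dissolution uses the DLM with that region's scalar; particle
radius is tracked per region through paired mass/count states (transit moves
both, dissolution only mass). Absorption flux is `2·Peff/R` per unit lumen
volume, zero in the stomach and scaled by 0.5 in the colon. Colonic
parameters (50 mL accessible fluid, scale 0.5) are deliberately absorptive:
colonic uptake is the design basis of prolonged-release tacrolimus, and with
a token colon (13 mL, scale 0.1) the colonic absorption ceiling is ~0.05 mg,
which would make the colon-scalar sensitivity analysis degenerate.
Absorbed drug passes a per-region enterocyte pool with first-order exit to
the portal vein (5 h⁻¹) competing against CYP3A metabolism (6 h⁻¹ × regional
abundance 0/1/1/0.8/0.6/0.5/0.4/0.3/0.1; CYP3A5 defaults to zero —
non-expressor — with a config switch). Colon exit of solid and dissolved
drug is fecal loss. The system is conservative by construction; tests assert
relative mass-balance error < 1e-6 including the disposition hand-off.

**Profile input mode.** A measured cumulative curve `d(t)` is converted to
the release hazard `λ(t) = d′/(1−d)` (piecewise-constant over the
observation intervals, capped at 50 h⁻¹, held at its final value beyond the
curve) and applied to all solid wherever it resides, so in vivo cumulative
release tracks the in vitro curve exactly when no competing solid sink
(fecal loss) intervenes. How the commercial platform maps a profile onto
transiting solids is proprietary; this hazard construction is our documented
choice, and it makes the two input modes provably equivalent in the
instant-release limit — provided solubility does not bind, since the hazard
has no saturation ceiling while the mechanistic rate is always capped at
`Cs`. The equivalence test therefore runs at non-saturating solubility.

## Disposition

Two compartments, plasma-referenced volumes, with saturable red-cell
binding `B:P(Cp) = 1 + (BPmax−1)/(1+Cp/C50)` (single-site form; one fewer
unidentifiable parameter than the mechanistic Hct/KD/Bmax variant) and
well-stirred hepatic elimination on blood concentrations,
`E_h = fu_b·CLint/(Q_h + fu_b·CLint)`, applied to portal inflow (first pass)
and hepatic blood flow (systemic). Whole-blood output is `Cp·B:P(Cp)`,
matching how tacrolimus studies are reported. The default compound set
(Vc 700 L, Vp 2400 L, Q 150 L/h, CLint 6000 L/h, fu 0.01, BPmax 35,
C50 2 ng/mL, Peff 1.5×10⁻⁴ cm/s) is **illustrative and configurable**: it
produces a tacrolimus-like curve (terminal phase spanning the 144-h window,
whole-blood Cmax in the tens of ng/mL at 5 mg) but is not the unpublished
parameter set behind the original simulations, and no acceptance quantity
depends on it. Population simulation draws per-subject log-normal
multipliers (mean 1) on configured parameters; each subject's GI model is
re-run with their own permeability and clearances.

## Metrics and sensitivity analysis

AUC₀–₁₄₄ₕ by linear trapezoid on the recorded grid, Cmax as the maximum,
Tmax its first time of occurrence (ties break early). Fold error is
`max(obs, sim)/min(obs, sim)` on study means, reported to two decimals;
≤ 1.25 is good, ≤ 2 acceptable (both boundaries inclusive on the better
side, since the published thresholds state no strictness). Ranking inside
the scalar selection uses unrounded ratios to avoid rounding-induced ties.

Non-estimable Ileum (shared I–IV) and Colon scalars are resolved by a
one-at-a-time grid — Ileum 0.005/0.05/0.5 at Colon 0.5, Colon 0.05/0.5/5.0
at Ileum 0.05 — simulating the full study per cell with a common seed and
choosing the pair that minimizes the worst-case fold error over AUC, Cmax
and Tmax (ties toward smaller scalars). The minimax criterion is our
formalization of what the original work did by visual comparison.

**Matched random streams.** When the "observed" study is itself virtual, a
12-subject study with ~35 % between-subject and 10 % residual CV leaves
metric-mean sampling noise (and the Cmax/Tmax biases that sparse, noisy
sampling induces) larger than the 1–2 % systematic differences between
neighbouring grid cells, so selection on independent draws is noise-
dominated. The scan therefore replays the virtual study's subject draws,
sampling schedule and residual-error stream on every candidate cell — the
simulation-native analogue of matching the virtual population to the actual
study subjects, and a standard common-random-numbers variance reduction.
Under matched streams the generating pair is recovered exactly; with real
data the same code runs with independent streams and inherits the
corresponding sampling uncertainty.

**Directional behaviour.** In this parameterization, raising the Ileum
scalar raises AUC and Tmax slightly (more ileal dissolution increases the
fraction absorbed, outweighing the higher ileal CYP3A first pass), whereas
the original sensitivity table shows both falling; the colon scalar's strong
positive AUC effect is reproduced. The direction of the ileal trend depends
on unpublished regional CYP3A abundances and permeabilities, so the package
reports it (test suite and analysis 04) without asserting it.

## Synthetic data

Dissolution curves follow `F(t) = fmax·(1 − exp(−(t/td)^β))` with additive
Gaussian noise made monotone again by isotonic regression (real cumulative
data are monotone by construction). Presets pin only the two published
landmarks — the reference product releasing ≈ 50 % at the 6-h end of the
run, the test product complete by ≈ 2.5 h — and the qualitative ordering of
the eight screening formulations (pH-responsive polymer → sigmoidal,
complete, β > 1; ethylcellulose → plateauing, incomplete; intra-granular
surfactant faster than extra-granular). The numeric preset values are
illustrative. Virtual studies are 12 subjects, one 5-mg dose, whole-blood
sampling at 21 times over 144 h, log-normal between-subject CVs
(CLint 35 %, Vc 25 %, Peff 20 %, Q 15 %) and 10 % multiplicative residual
error — chosen once to reproduce the observed-study dispersion scale
(AUC CV ≈ 45 %).

What passing these tests shows: the estimation, extrapolation and selection
machinery is internally consistent, conservative, and recovers known inputs
under its own generating assumptions. What it does not show: predictive
accuracy for real formulations, because the synthetic generator shares the
model family with the analysis (no model misspecification beyond the
Weibull-vs-DLM shape mismatch), the disposition defaults are illustrative,
and analytical error structure (e.g. HPLC) is not emulated.

## Problem sizes

Test and analysis runs use 12-subject studies, 10-min dissolution grids,
20 random draws for the recovery suite, and the 6-cell sensitivity grid —
the sizes of the emulated study itself, which also keep the whole suite in
the minutes range on one core.
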