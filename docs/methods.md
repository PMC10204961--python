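# Methods

This note documents the models, algorithms and numerical choices behind
`ecflux`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Stoichiometric core

Models are plain steady-state networks: `S v = 0`, `lb ≤ v ≤ ub`, fluxes
in mmol/gDCW/h, "unbounded" meaning ±1000. Uptake is a negative flux on
exchange reactions; reports convert to positive uptake rates. The native
serialisation is a versioned JSON dialect (`ecflux-model v1`) with
metabolite, reaction and enzyme-annotation arrays; SBML Level 3 import
and export go through COBRApy/libsbml, dropping constructs the dialect
does not represent (with a logged warning). All LPs are solved with HiGHS
at primal/dual feasibility tolerances of 1e-9 (recorded in run
manifests), which makes repeated runs deterministic.

`fba_brute_force` is an independent validation routine: for bounded
problems with at most 14 reactions it enumerates every basis and
lower/upper-bound assignment of the nonbasic variables, solves the
resulting linear systems, and takes the best feasible vertex. It shares
no code with the HiGHS path and is used to certify FBA optima on randomly
generated small models; COBRApy/GLPK serves as a second independent
solver route in the test suite.

## Enzyme constraints (GECKO formalism)

Reversible reactions are split into forward/reverse copies (reverse ids
carry the suffix `_REV`), and reactions with N ≥ 2 isozymes become N
copies behind an arm reaction through an intermediate pseudo-metabolite,
so copy fluxes sum to the arm flux and each copy carries one isozyme.
Both mappings are retained in model metadata so sampled fluxes can be
mapped back to the base formalism (forward − reverse; copies summed; arm,
usage and pool reactions dropped). Note that medians of sampled rows are
not themselves flux vectors — steady-state identities are asserted per
row, never on the median.

Each enzyme used by a constrained reaction gets a pseudo-metabolite
`prot_<enzyme>` consumed with coefficient −1/(k_cat·3600) (k_cat stored
in s⁻¹, fluxes hourly) and produced by a usage reaction in mmol/gDCW.
Enzyme complexes (AND within an isozyme) give every subunit its own
pseudo-metabolite with the same k_cat unless per-subunit values are
supplied, so each subunit independently caps the flux and drains the
pool. Unmeasured usage reactions consume `MW` gram of the shared pool per
mmol; the pool exchange is bounded by σ·f·P_tot (g/gDCW).

k_cat matching relaxes stringency stepwise: (1) EC + substrate +
organism, (2) EC + substrate, (3) EC + organism, (4) EC, (5) EC with the
last field wildcarded. Substrates are compared by metabolite name,
case-insensitively. Within a level the maximum is taken (median available
as an option). The ordering of levels 2 and 3 (substrate before organism)
and the max aggregation are this package's choices; both are exposed as
configuration. An enzyme with no hit at any level is left unconstrained
and logged.

The sensitivity loop for limiting k_cat values solves max growth, ranks
enzymes by |shadow price of their pseudo-metabolite balance| / k_cat
(ties broken lexicographically by enzyme id), replaces the top enzyme's
k_cat with the database maximum for its EC class (first three fields),
and repeats until the target growth is reached or no candidate remains.
Manual curation entries (TSV) apply the same coefficient update and mark
provenance as `curated`; curating a built model is equivalent to building
from a curated database.

## Proteome quantification and integration

TPA quantification reconstructs light-channel intensities as
iBAQ-heavy / (H/L ratio), normalises by the mean internal-standard
abundance, adjusts for 80 % sample recovery, and converts to shares of
10⁶ µg per g total protein. Both the normalisation constant and the
recovery factor cancel in the share, which the tests assert as scale
invariance; they are kept in the computation for interpretability of the
intermediate intensities. Molar abundances are
conc × P_tot / MW (mmol/gDCW). Differential expression is a Welch t-test
on log2 concentrations with Benjamini–Hochberg correction (statsmodels)
after excluding proteins whose replicate SD exceeds the replicate mean;
at n = 2 replicates per condition the test is underpowered and should be
read as a screen, not an inference. GO-group allocation counts a protein
in every group containing it, so overlapping groups need not sum to
100 %. The per-ribosome translation rate is
(µ·P_tot / m_aa) / N_rib / 3600 aa/s with m_aa = 110 g/mol (configurable)
and N_rib estimated as the median molar abundance of detected ribosomal
proteins (mean and min available; the median is robust to missing
subunits).

## Condition integration

The f-factor is the mass share of the quantified proteome belonging to
model enzymes, computed before any record filtering. Measured enzymes
receive a usage upper bound equal to their molar concentration and stop
draining the pool; the pool bound becomes σ·f·(P_tot + P_tot,SD) minus
the summed mass of the measured enzymes, so the identity
Σ(measured·MW) + pool = σ·f·P_tot,rescaled holds exactly. Because the
saturation-discounted budget σ·f·P_tot is smaller than the enzymes' full
proteome mass f·P_tot, direct bounds cannot be granted to every
quantified enzyme: the pipeline grants them most-abundant-first while
their summed mass stays within half of the budget (configurable), leaving
the remainder pool-allocated. Callers of `constrain_enzymes` with an
over-budget set get an explicit error instructing a P_tot rescale or a σ
increase.

Automatic flexibilization relaxes measured bounds greedily while maximal
growth is below the measured rate: for each measured enzyme the growth
gain of raising its bound to concentration + SD is probed first; if that
stage is exhausted or gains nothing, full release to the pool (which also
returns the bound's mass to the pool, preserving the mass identity) is
probed. The largest gain wins, ties broken by enzyme id, and the
procedure stops when the target is reached, everything is released, or no
single relaxation helps (gap logged). The greedy trace is minimal in the
sense that removing the last relaxation makes the target infeasible.

Sampling windows fix measured quantities to ±1 % (growth, substrate
uptake, NGAM) or ±10 % (CO₂, O₂, byproducts, protein pool) of their
values, never crossing zero for positive rates. When the measured gas
rates are inconsistent with the growth/uptake windows (a real failure
mode of off-gas measurements), the pipeline falls back to
model-simulated gas rates for the gas windows and records that in the
manifest.

GAM (growth-associated maintenance, the ATP coefficient of the biomass
reaction, mmol ATP per mmol biomass = per gDCW) is fitted by bisection on
[0, 300] with 40 steps at fixed NGAM, exploiting that predicted maximal
growth decreases monotonically in GAM; the fit matches the measured rate
to 0.1 % relative. The default maintenance windows shipped with the
package are GAM 124.4–140.0 mmol/gDCW and NGAM 0–3.65 mmol/gDCW/h,
typical fitted values for *R. toruloides* batch cultivations.

## Biomass rescaling

The biomass reaction consumes protein, lipid and carbohydrate
pseudo-components of unit mass 1 g/mmol, so coefficients are g/gDCW and
the biomass molar mass is their sum; the carbohydrate component absorbs
the residual so the total stays exactly 1 g/mmol (the residual absorber
is configurable). The lipid pseudo-reaction follows the SLIME idea: one
glycerol backbone pseudo-metabolite (92.09 g/mol, fixed 10 % of lipid
mass — a triacylglycerol-like backbone share) plus acyl-chain species
whose molar coefficients come from the measured chain mass fractions and
an internal chain-mass table (C16:0 256.43, C18:0 284.48, C18:1 282.47,
C18:2 280.45, C18:3 278.44 g/mol). Rescaling is idempotent and
composition-driven only.

## Flux sampling

Per iteration, three distinct interior reactions (exchanges, usage
reactions and the pool drain are ineligible — objectives should probe the
metabolic interior; arm and biomass reactions are eligible) get i.i.d.
uniform (0, 1] weights; the weighted sum is maximised and then, holding
that objective within 1e-6 relative, the total flux of the irreversible
model is minimised (equivalent to minimising Σ|v| of the net model).
Weights are positive and maximisation-only by default; signed weights are
a configuration option. One master seed spawns a deterministic stream per
iteration, so identical seeds give identical matrices; a failed iteration
is retried once with fresh draws, then skipped with a log entry. The
summary reports median, sample SD (ddof = 1) and variability
100·SD/|median| per reaction, with variability undefined (NaN, never
infinity) when |median| < 1e-9.

## Derived quantities

Normalised flux is mole-based: 100·v/uptake. A carbon-mole weighting
would differ for substrates of unequal chain length; the mole-based form
is the default and the substrate exchange itself always normalises to
100 %. k_app = v/(E·3600) s⁻¹ from base-mapped median fluxes and measured
molar abundances; pairs without a positive abundance are excluded with a
reason. Cofactor turnover is the production half-sum Σ max(0, s·v) over
every reaction carrying any compartment instance of the metabolite
(per-compartment breakdown available); at steady state it equals the
consumption half-sum, which avoids double counting. Yield is
turnover/uptake. The trade-off table extracts named consumers'
shares of NADPH turnover per condition and flags when the dominant
consumer switches between conditions.

## Synthetic data generator

The generator defines the study conditions. The toy networks (57–67
reactions) contain the organism's characteristic motifs with lumped
stoichiometry: single cofactor species (no ADP/NAD⁺/NADP⁺ mirrors, no
water/proton balancing) and carbon balanced in every non-pseudo reaction,
so C-mol bookkeeping of the emitted rates closes exactly at zero noise.
Fatty-acid synthesis spends 1 ATP and 2 NADPH per C2 elongation;
desaturation consumes O₂ and NADH; the electron transport chain is one
lumped reaction at P/O 2.5. Six conditions are emulated (glucose, xylose,
acetate × exponential/nitrogen-limited) with uptake rates, protein and
lipid contents, acyl profiles, GAM/NGAM and planted per-ribosome
translation rates chosen to sit in the physiological ranges of batch
bioreactor data for this organism (growth 0.06–0.38 h⁻¹, protein content
0.16–0.45 g/gDCW, lipid up to 0.40 g/gDCW, translation 0.8–3.5 aa/s); the
nitrogen-limited toggle lowers protein and raises lipid. The xylose
exponential phase excretes xylitol and D-arabinitol (32 % of uptake,
combined), and the acetate exponential phase excretes a small citrate
flux.

Ground-truth enzyme concentrations are planted from the parsimonious
reference flux as demand/saturation with a saturation ceiling of 0.15
(apparent activities then sit near 10–15 % of k_cat, within the 0.1–100
s⁻¹ range expected for in-vivo turnover), a floor of 1 % of the largest
demand for silent enzymes, and a uniform scale-up so model enzymes hold
20 % of the proteome (f_target); concentrations never drop below demand,
so the truth satisfies every capacity constraint by construction. The
subset of enzymes that receives direct bounds is chosen
most-abundant-first under the constraint that the σ-discounted budget
keeps covering the unmeasured demand with a 10 % margin — this mirrors
the practical situation where only part of the quantified enzyme mass can
be bounded directly without starving the shared pool. The k_cat table
contains exact-organism records at the true values plus higher
cross-organism decoys (to exercise the level ordering), and one planted
pathology: the strictest fructose-bisphosphatase match yields 0.002 s⁻¹
while the enzyme's actual capacity (127 s⁻¹) is only available
cross-organism, so gluconeogenic conditions over-constrain until the
sensitivity/curation loop raises it.

MS-level proteomics gives every protein a fixed heavy-standard intensity
(lognormal across proteins) and light intensities proportional to the
true concentrations with multiplicative lognormal noise (mean-one
parameterisation), in duplicate; H/L ratios are the exact quotient, so
zero-noise TPA recovery is exact to machine precision. The proteome
contains a 40-protein ribosomal block sized to the planted translation
rate and a 60-protein background filling the remaining mass.

What passing on this generator shows: unit- and sign-correct
implementations of every stage, exact conservation properties, correct
recovery of planted parameters, and qualitative pathway behaviour
(phosphoketolase as the cytosolic acetyl-CoA source under pool
limitation; pyruvate-decarboxylase/citrate-lyase routes only under the
XPK block; growth on xylose without xylulokinase via the D-arabinitol
bypass). What it does not show: realism of genome-scale k_cat coverage,
peptide-level MS artefacts (missing values, shared peptides), byproduct
chemistry beyond the emulated excretions, thermodynamic feasibility of
the sampled cycles, or transferability of the sampling variability to a
full genome-scale network.

## Known limitations

- Differential expression at duplicate level is a screen; p-values at
  n = 2 are fragile.
- The vertex-enumeration reference is exponential and limited to ~14
  reactions; larger models rely on HiGHS plus the COBRApy cross-check.
- Oxidative-phosphorylation stoichiometry (P/O) is fixed, not fitted.
- The sampling scheme is objective-based, not a geometric (hit-and-run)
  sampler; medians are reproducible but are not guaranteed to be the
  polytope's geometric centre.
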