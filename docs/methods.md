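# Methods

## The partition

For a mixture of $N$ species with observed per-species yields $Y_{O,i}$ and
monoculture baselines $M_i$ (the mean biomass of species $i$ grown alone under
the matching treatment), define the relative yield $RY_i = Y_{O,i}/M_i$ and its
deviation from the planted expectation $\Delta RY_i = RY_i - 1/N$. The net
biodiversity effect and its additive components are

$$
\mathrm{NBE} = \sum_i Y_{O,i} - \sum_i p_i M_i,\qquad
\mathrm{CE} = N\,\overline{\Delta RY}\,\overline{M},\qquad
\mathrm{SE} = N\,\mathrm{cov}(\Delta RY_i,\, M_i),
$$

with $p_i$ the expected proportion of species $i$ (planted proportion $1/N$ by
default) and cov the **population** covariance (denominator $N$, not $N-1$).
Under planted proportions,

$$
\mathrm{CE} + \mathrm{SE}
 = N\,\overline{\Delta RY\cdot M}
 = \sum_i \Delta RY_i\,M_i
 = \sum_i Y_{O,i} - \tfrac{1}{N}\sum_i M_i = \mathrm{NBE}
$$

is an exact algebraic identity; only the population denominator makes it so,
which is why it is the package's fixed choice. Every `PartitionResult` carries
the floating-point residual of this identity as a certificate, and a residual
beyond $10^{-9}\cdot\max(1,|\mathrm{NBE}|)$ raises instead of passing
silently. Since $\Delta RY_i$ differs from $RY_i$ by the constant $1/N$,
$\mathrm{cov}(\Delta RY, M) = \mathrm{cov}(RY, M)$; either form of the
selection effect is the same number.

**Proportions.** `proportions="planted"` ($p_i = 1/N$; all mixtures are planted
evenly) is the default because the complementarity formula's
$\Delta RY_i = RY_i - 1/N$ presupposes an expected relative yield of $1/N$.
`proportions="observed"` uses realized relative abundances
$p_i = Y_{O,i}/\sum_j Y_{O,j}$ in the expected biomass; this reading is
implemented but documented as breaking the additivity identity, so no
certificate is enforced in that mode.

**Baselines.** `baseline="matched"` (default) compares each mixture against
monocultures of its own treatment, so treatment main effects cancel inside the
partition and only diversity structure remains; `baseline="control"` is a
sensitivity mode in which treatment effects load onto the partition.
A mixture whose species lacks a monoculture baseline under the required
treatment is skipped with a logged reason, never imputed. A species that died
in mixture enters with $RY_i = 0$; a fully empty mixture pot is skipped.
The partition is undefined for monocultures ($N = 1$) by construction.

## Design construction

The design crosses richness levels × the four drought × biochar treatment
combinations × replicate communities. Within one richness level the replicate
compositions are drawn once and reused across all four treatments, so
diversity × treatment contrasts compare identical communities. Selection is
rejection sampling over seeded shuffles of a balanced species multiset,
chunked into richness-sized groups; a draw is accepted when every chunk holds
distinct species and chunks are pairwise distinct. This enforces the stricter
reading of "equal representation": occurrence counts across one level's
mixtures differ by at most one, exactly equal whenever
`count × richness` divides the pool size. The retry cap (10,000) turns
combinatorially impossible requests into an explicit infeasibility error.
Watering volumes and biochar dose are carried as annotations only.

## Traits

SLA = leaf area / leaf dry mass (mm² mg⁻¹), SRL = root length / root dry mass
(cm g⁻¹), RSR = root dry mass / shoot dry mass (dimensionless), per
individual; leaf area and mass are each the mean over the sampled leaves, so
SLA is the arithmetic mean per-leaf ratio. "Total biomass" defaults to
shoot + root dry mass summed per species per pot (`biomass="aboveground"`
restricts to shoot mass, since partition baselines are sometimes computed on
aboveground yield only). Missing measurements propagate as missing and are
excluded from that trait's pot mean only — no imputation. Non-positive
measurements are domain errors, not data.

## Synthetic experiments

Species-level pot yield:

$$
Y_{O,i} = \frac{1}{N}\,\mu_i\, d^{\,\mathrm{drought}}\, b^{\,\mathrm{biochar}}
          \,\gamma(N)\, w_i(s)\,\varepsilon_i ,
$$

where $\mu_i$ is the species' monoculture pot biomass baseline, $d \le 1$ and
$b \ge 1$ multiplicative treatment effects, $\gamma(N)$ a per-richness
complementarity boost ($\gamma(1)=1$), $w_i(s) \propto \exp(s z_i)$ dominance
weights ($z_i$ the standardized rank of $\mu_i$ within the composition,
normalized to mean 1), and $\varepsilon_i$ lognormal noise with mean 1 and
coefficient of variation `cv`. Because mixture yields and treatment-matched
baselines share the factors $d$ and $b$, the true per-mixture effects reduce
to $\mathrm{CE} = (\gamma-1)\,\bar M$ and
$\mathrm{SE} = \gamma\,\mathrm{cov}(w, M)$: $s=0$ gives pure complementarity,
$s<0$ a negative selection effect (low-baseline species overperform), $s>0$ a
positive one. Lognormal noise was chosen because biomass is positive and
right-skewed; the CV parameterization is scale-free.

Defaults (illustrative — chosen once to produce the qualitative regime of an
arid-greenhouse diversity experiment, not fitted to any dataset):
$\mu = (14, 11, 9, 7, 5)$ g, $d = 0.6$ (drought watering at one-third volume
cutting yield to 60%), $b = 1.3$, $\gamma = \{1{:}\,1.0,\ 2{:}\,1.2,\
4{:}\,1.4\}$, $s = -0.4$, $\mathrm{cv} = 0.15$. Under these defaults mixtures
overyield (CE > 0, NBE > 0) while no species dominates (SE < 0), drought
lowers and biochar raises every pot's expected biomass, and the root-to-shoot
ratio is inflated ×1.35 under drought. Traits are species-level constants
under the same multiplicative noise and do not feed back into yields.
Individuals split their species' pot yield evenly; shoot/root masses are
reconstructed from the (noisy) RSR so that they resum to the species yield
exactly.

**Ground truth** is computed by running the partition itself on the noiseless
yields (cv = 0, same compositions) — a self-oracle that avoids duplicating the
derivation; the independent check is the hand-derived two-species closed form
kept in the tests ($\gamma(2)=1.2$, $\mu=(10,20)$ ⇒ CE $= 0.2 \cdot 15 = 3$,
SE $= 0$). At cv = 0 the pipeline's estimates equal truth to $10^{-9}$;
identical seeds reproduce byte-identical tables.

**What passing recovery tests do and do not show.** The generator matches the
analysis' assumptions by construction (multiplicative structure, lognormal
noise, evenly planted mixtures, no species interactions beyond $\gamma$ and
$w$). Recovery under it demonstrates the estimator and pipeline are correct,
not that real greenhouse data meet those assumptions; real data add
pot-position effects, mortality, trait–yield feedbacks and non-multiplicative
stress responses that the generator deliberately omits.

**Replicate-mixture Monte Carlo.** `monte_carlo_recovery` runs independent
mini-experiments: each replicate estimates its own baselines as means of five
noisy monoculture pots per species (the design's replication level) and
partitions one noisy mixture. Replicates are therefore iid and the reported
Monte-Carlo standard error is valid. Estimating baselines induces a small
positive bias in CE of order $\bar M\,\mathrm{cv}^2/n_{\mathrm{mono}}$
(≈ 0.01 g at cv = 0.1 — an order of magnitude below the Monte-Carlo error at
200 replicates), the price of testing the full estimation path rather than
plugging in true baselines.

## Summaries and uncertainty

Group summaries report mean, sample SD (ddof = 1) and a bootstrap CI over the
pots in each group (default 2,000 resamples). The plain percentile interval
is known to undercover for means of small samples — it behaves like a
z-interval built on the ddof-0 standard deviation, giving ≈ 93% actual
coverage at n = 20 — so the default applies the *expanded* percentile
correction (Hesterberg): the quantile levels are widened from $\alpha/2$ to
$\Phi\!\left(-\sqrt{n/(n-1)}\; t_{1-\alpha/2,\,n-1}\right)$, which restores
near-nominal coverage while remaining a pure percentile of the bootstrap
distribution. `expand=False` recovers the classical interval. Each group's
resampling stream is seeded independently of other groups' sizes, so
summaries are deterministic and stable under group addition or removal.

Percent changes are plain $100(\bar x_{\mathrm{cmp}} -
\bar x_{\mathrm{ref}})/\bar x_{\mathrm{ref}}$ between explicitly named
groups; the package never guesses which contrast is meant. Mixed-model
fitting is intentionally out of scope: `export_model_table` writes the tidy
long-format table (pot id as grouping unit, richness and treatment factors,
one row per pot × response) that external mixed-model software consumes
directly.

## Numerical and interface choices

- Additivity tolerance: $10^{-9}$ relative — loose enough for accumulated
  rounding over $N \le 8$ species, tight enough to catch any formula error.
- Degenerate inputs: empty pots, monoculture partitions, zero reference means
  and infeasible balance requests raise typed errors; schema validation
  reports per-row/column findings, with unknown columns as warnings (forward
  compatibility), never errors.
- CSV interchange: UTF-8, comma-delimited, "." decimals, mandatory header;
  files written by the package carry `#`-prefixed provenance comments
  (version, seed, config hash) that readers skip.
- Ties in the dominance ranks use average ranks, so equal baselines give unit
  weights and a zero injected selection effect.

## Problem sizes used in validation

The randomized identity checks use 10,000 mixtures (additivity) and 1,000
mixtures (oracle equivalence) at $N \in 2..8$; recovery uses 200 replicate
mixtures at cv = 0.1; sign-fidelity uses 20 seeded full-pipeline runs of the
60-pot design; bootstrap coverage uses 1,000 simulations of n = 20 at 2,000
resamples. These sizes give Monte-Carlo errors comfortably below the effects
being measured.

## Known limitations

- The generator's complementarity boost is a single per-richness multiplier;
  it cannot express species-pair-specific interactions or
  facilitation asymmetries.
- Dominance weights act through baseline *ranks*, so selection-effect
  magnitude is not directly controlled in grams; it scales with the spread of
  baselines in the drawn composition.
- The expected-proportions ambiguity (planted vs realized abundances in the
  expected biomass) is documented and exposed as an option rather than
  resolved; the identity-preserving planted mode is the default.
- Balance is enforced at the ≤1-occurrence-spread level per richness level;
  no blocking, spatial randomization or unequal replication.
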