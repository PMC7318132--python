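# Methods

## The near-attack-conformation criterion

Hydrogen abstraction by Compound I requires the substrate hydrogen to sit
close to the oxo atom with the H–oxo–Fe arrangement bent toward the
transition-state geometry of the HAT step.  A frame is classified as a
near-attack conformation (NAC) for a site when any of the site's hydrogens
satisfies

- H–oxo distance within `[d_min, d_max]` = [2.0, 3.5] Å, **inclusive** on
  both ends ("in the range of"), and
- H–oxo–Fe angle strictly above `theta_min` = 120° ("above" is read as
  strict).

The angle's vertex is the oxo atom.  Both thresholds are configurable
(`NacCriterion`); widening any bound can only add events (a tested
monotonicity property).  The criterion is evaluated per hydrogen, not per
site carbon, because the geometry that matters is that of the specific
abstractable hydrogen.

## Sites, stereochemistry, and counting

A site map assigns each SOM label its candidate hydrogens and a stereo
class (`alpha`, `beta`, `methyl`, `other`).  Stereo-distinct hydrogens on
one carbon (6α vs 6β) are *separate sites*: the α/β assignment is chemistry
knowledge supplied by the user, not derived from coordinates — automatic
prochirality perception is deliberately out of scope.  A methyl site owns
its three equivalent hydrogens but contributes **at most one event per
frame** (the accessible hydrogen with the smallest H–oxo distance, ties to
the lowest atom index); otherwise sites 18/19 would be triple-counted.
Distinct sites may each log an event in the same frame.

### The percentage denominator

The profile percentage divides a site's event count by the total number of
(frame, site) access events, so a frame exposing two sites contributes two
to the denominator and percentages always sum to 100 — the convention that
makes stacked per-site percentages coherent.  The alternative reading
(divide by frames with ≥1 access) is available as `denominator="frames"` /
`--denominator frames`; its percentages can total more than 100.  Events is
the default.

No equilibration trimming happens by default; `skip_frames` /
`--skip-frames N` drops leading frames when the input includes an
unequilibrated prefix.  Every provided frame counts as one snapshot — no
stride resampling.

## Structure input

Trajectories are multi-model PDB v3.3 files (MODEL/ENDMDL delimited; a
plain single-model file is a 1-frame trajectory).  Only
ATOM/HETATM/MODEL/ENDMDL records are interpreted — a minimal, predictable
dialect.  The topology comes from the first model; later models must match
its atom order exactly or the reader raises a format error naming the
offending model.  Altloc groups collapse to the highest-occupancy location,
ties keeping the first encountered (crystal inputs need a rule; any is
defensible, this one is conventional).  Hydrogens must be present
explicitly: the criterion is defined on hydrogen positions and no hydrogen
building is attempted.  Coordinates are Å throughout; atom indices are
0-based internally with PDB serials preserved for reporting.

## RMSF

Ensemble flexibility is summarized per residue by one designated atom
(default `CA` — standard practice, one unambiguous value per residue).
Residues missing that atom in any structure are dropped from fitting and
reporting with a logged warning, since crystal ensembles differ in
unresolved loops.  All structures are superposed onto the first by Kabsch
superposition (SVD with reflection correction, determinant +1) in a single
pass — no iterative mean-structure refinement.  RMSF of a residue is the
RMS deviation of its atom from the ensemble-mean position.  `superpose=False`
skips the fit for pre-aligned ensembles; note that least-squares fitting
redistributes a strictly local displacement over all residues slightly, so
exact closed-form checks (one atom at mean ± d/2 ⇒ RMSF d/2) use the
unfitted path.  The TSV output flags residues with RMSF ≥ 1.0 Å as
flexible.

## Reactivity and the selectivity synthesis

Activation barriers for the eleven candidate testosterone sites ship as a
versioned TSV fixture (columns `site`, `dft_kcalmol`, `d3_kcalmol`: plain
B3LYP and dispersion-corrected B3LYP-D3 values for a truncated Compound I
model).  Dihydrotestosterone shares the steroid scaffold, so its sites
reuse the corresponding testosterone barriers.  Computing barriers (DFT,
QM/MM) is out of scope; the table is consumed as data.

Barriers become Boltzmann weights w_s = exp(−ΔE‡_s/RT)/Σ_t exp(−ΔE‡_t/RT)
with R fixed at 1.987204×10⁻³ kcal mol⁻¹ K⁻¹ and default T = 298.15 K.
The max-shift trick keeps the exponentials finite for arbitrary barrier
spreads.  Weights are invariant under adding a constant to all barriers and
order inversely to the barriers (both tested).

The combined score is score_s ∝ pct(s) · w_s, renormalized to sum 1.  This
product rule is an explicit modeling extension: nothing in the barrier data
dictates how accessibility and reactivity merge quantitatively.  It was
chosen because it is scale-invariant in both factors, reduces to the
Boltzmann ranking under uniform accessibility, and lets zero accessibility
gate even the most reactive site (the physically required behavior).  The
raw factors are always reported next to the score.  Sites with
accessibility but no barrier entry are *excluded* from the normalization
with a warning rather than silently zeroed — silent dropping would hide
data mismatches.

Rank agreement between a reactivity ordering and measured turnover rates is
quantified by Spearman's ρ (average ranks for ties; scipy implementation,
cross-checked in tests against a brute-force rank computation over all
permutations of n ≤ 5).  For the four experimentally observed β sites the
packaged dispersion-corrected barriers order exactly inversely to the
printed turnover rates, giving ρ = −1.

## The synthetic generator

The generator emulates the *statistical* structure of an active-site MD
trajectory: per frame a categorical draw (background p₀ = 1 − Σp_s, or
site s with probability p_s) decides which site, if any, is exposed.  One
uniformly chosen hydrogen of the hit site is placed inside the criterion
window (distance uniform in [2.1, 3.4] Å, angle uniform in [125°, 175°],
azimuth isotropic about the oxo→Fe axis); every other site hydrogen gets an
isotropic direction at a distance uniform in [4.5, 6.5] Å, which violates
the criterion on distance alone.  The toy topology puts Fe at the origin
and the oxo at (0, 0, 1.62) Å with one dummy carbon per site.

Ground truth is closed-form: expected percentage 100·p_s/Σp_t and expected
frames-with-access fraction Σp_s.  The reference condition used throughout
the tests and the acceptance script is the two-site competition
{site 19: p = 0.45 (methyl, 3 H), site 6β: p = 0.05 (β, 1 H)} at
n = 10,000 frames — truth 90 %/10 % with access fraction 0.5 — mirroring
the methyl-over-β dominance regime of aromatase-like binding.  Recovery is
asserted within 3 binomial standard errors across 10 seeds.

Co-accessible frames (needed to distinguish the two percentage
denominators) come from an explicit `coaccess = (site_a, site_b, p)` flag
that hits both named sites jointly with probability p; the closed-form
truth accounts for the extra event mass.

A single seeded `numpy` generator drives all draws in a fixed documented
order (category → hit hydrogen/distance/angle/azimuth → miss geometries in
topology order), so trajectories are bit-reproducible for a given spec and
seed.

**What the generator does not emulate:** bonded geometry, rigid-body
substrate motion, protein environment, autocorrelation between frames.
Hydrogens are placed independently per frame.  Passing parameter-recovery
tests therefore validates the counting statistics and the classifier, not
any physical realism; profiles of real MD data inherit all the caveats of
the underlying simulation.

## Numerical choices and degenerate inputs

- Angles are computed via arccos of a clipped cosine; points closer than
  10⁻⁶ Å to the vertex raise a value error.
- Kabsch requires ≥3 non-collinear points; rank < 2 configurations raise.
- An all-miss trajectory yields a valid all-zero profile with a logged
  warning, not an error.
- A Fe–oxo distance outside (1.4, 2.2) Å in any frame logs a warning
  (probably a misselected center) but does not stop profiling.
- Profile TSV rows are ordered by descending percentage, ties broken
  lexicographically by site label; all data files are written atomically
  (temp file + rename) so failed runs leave no partial outputs.

## Problem sizes

Default test and acceptance runs use 10,000-frame synthetic trajectories
(and 10 seeds for the recovery property), ~15-atom toy topologies, and the
11-site barrier table; these sizes give 3σ binomial bounds of roughly ±1
percentage point on the recovered percentages, tight enough to catch
counting errors while keeping the full suite under a minute of compute for
everything except the multi-seed recovery test.

## Known limitations

- No binary trajectory formats (DCD/XTC/TRR) or topology formats
  (PSF/PRMTOP); convert to multi-model PDB first.
- No hydrogen placement, protonation assignment, bond perception, or
  prochirality (α/β) perception — the site map is authoritative.
- The accessibility × Boltzmann product is one defensible synthesis rule,
  not a validated kinetic model; treat the combined ranking as a screening
  statistic.
- Per-residue RMSF only (one atom per residue); no per-atom RMSF or
  B-factor analysis.
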