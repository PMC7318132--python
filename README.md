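# p450nac

Near-attack-conformation (NAC) accessibility analysis for cytochrome P450
site-of-metabolism (SOM) selectivity.

## The problem

Cytochrome P450s hydroxylate C−H bonds via their Compound I species: a
ferryl (Fe(IV)=O) porphyrin radical that abstracts a substrate hydrogen
(the rate-limiting hydrogen-atom-transfer, HAT, step) and rebounds OH.
Which of a substrate's many candidate hydrogens gets abstracted — the
regio- and stereoselectivity — is set by two competing factors:

1. **Accessibility** — how often the enzyme's dynamics place a given site's
   hydrogen in a reactive geometry relative to the oxo atom; and
2. **Intrinsic reactivity** — the activation barrier ΔE‡ of the HAT step
   for that site.

`p450nac` quantifies both for ensemble data.  A frame of a trajectory puts
site *s* in a *near-attack conformation* when one of its hydrogens H
satisfies

    2.0 Å ≤ d(H–oxo) ≤ 3.5 Å   and   ∠(H–oxo–Fe) > 120°

(distance bounds inclusive, angle strict).  The per-site accessibility over
a trajectory is

    pct(s) = 100 · n_events(s) / Σ_t n_events(t)

where `n_events(s)` counts frames in which site *s* is in a NAC (at most one
event per site per frame, so the three equivalent hydrogens of an angular
methyl group are never triple-counted).  Intrinsic reactivity enters through
a packaged table of HAT activation barriers for the eleven candidate
testosterone sites (plain and dispersion-corrected DFT), converted to
Boltzmann weights w_s ∝ exp(−ΔE‡_s/RT) and combined multiplicatively with
accessibility into a selectivity ranking — accessibility gates what the
chemistry can deliver.

The package also provides rigid-body (Kabsch) superposition with
per-residue RMSF for ensemble flexibility analysis, and a synthetic
trajectory generator with closed-form ground truth for validating the whole
statistics pipeline.

## Worked example

Simulate a two-site competition (an angular methyl site drawing 45 % of
frames, a β-face site drawing 5 %, background 50 %), profile it, and rank:

```
$ cat spec.yaml
sites:
  "19": {probability: 0.45, class: methyl, n_hydrogens: 3}
  "6β": {probability: 0.05, class: beta}
n_frames: 500
seed: 3

$ p450nac simulate --spec spec.yaml --out sim
simulated 500 frames over 2 site(s); wrote sim/trajectory.pdb, sim/sitemap.yaml, sim/truth.json

$ p450nac profile --trajectory sim/trajectory.pdb --sitemap sim/sitemap.yaml --out prof
profiled 500 frames: 253 events over 2 site(s); outputs in prof

$ head -3 prof/profile.tsv
site    event_count     percentage      stereo_class
19      217     85.77   methyl
6β      36      14.23   beta

$ p450nac selectivity --profile prof/profile.json --out sel
selectivity ranking over 11 sites (column d3, T = 298.15 K): top site 6β; outputs in sel
```

Reading the numbers: of the 253 access events in 500 frames, 85.77 % went
to the methyl site 19 and 14.23 % to 6β — close to the 90/10 ground truth
of the generating probabilities (0.45 vs 0.05), with binomial sampling
noise at n = 253 events.  The selectivity step then combines these
percentages with the barrier table: 6β has by far the lowest
dispersion-corrected barrier (5.3 kcal/mol, Boltzmann weight > 0.99 at
298.15 K), so it tops the combined ranking despite its six-fold lower
accessibility.

The same `profile` command runs unchanged on any multi-model PDB ensemble
with explicit hydrogens plus a site-map YAML assigning hydrogens to SOM
labels; `p450nac rmsf --structures a.pdb --structures b.pdb ...` reports
per-residue flexibility of a superposed ensemble.

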