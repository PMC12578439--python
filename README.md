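# mtoligo

Coordinate-space geometric analysis of protein oligomer chains on
microtubules, for cryo-ET subtomogram metadata.

When a microtubule-binding protein such as LRRK2 decorates filaments, the
refined subtomogram coordinates and orientations already contain the
answer to a structural question no single map can settle: do the bound
dimers polymerize into long helices wrapping the microtubule, or into
short, sparse, ring-like oligomers? `mtoligo` answers it from metadata
alone — particle tables (Dynamo table or STAR dialect) plus traced filament
centerlines — with a fully synthetic, ground-truthed data generator so that
every stage is testable without any experimental download.

## What it computes

For each same-filament particle pair within a distance cutoff, the
**θ (helical) angle** between the oriented pair displacement and the
filament growth axis:

    θ = ∠( d_ab , t̂ )  ∈ [0°, 180°]

where `d_ab` points from the member whose own y-axis lies along it (a bound
dimer's y-axis can point with or against the growth direction, hence the
full 0–180° range), and `t̂` is the filament tangent at the pair midpoint.
θ ≈ 90° means circumferential, ring-like decoration; small θ means an
axially pitched helix (≈33° for the active-like LRRK2 filaments).

Perpendicular pairs at one dimer footprint are then linked into **chains**
(connected components), giving the oligomer copy-number distribution, each
chain's azimuthal extent around the tube, and the decoration density in
particles per nm of filament.

The package also reproduces the upstream picking geometry (oversampled
rings of 18 seeds at 23 nm radius every 7 nm, azimuth randomization,
distance deduplication, 0.32 score filter, polarity flipping) and generates
synthetic tubulin lattices (11–16 protofilaments; 13-pf: twist −27.7°,
rise 9.4 Å) with an estimator that recovers twist/rise from coordinates.

## Worked example

```python
import mtoligo as m

# synthetic dataset: 20 filaments of 500 nm, sparse ring-like decoration
fx = m.make_fixture("paper-like", n_filaments=20, rng_seed=42)

model = m.OligomerChainModel(fx.table, fx.paths)
res = model.fit()
print(res.summary())
```

```
Oligomer chain analysis
=======================================================
particles                   922
filaments                    20
pairs (<= 16 nm)           667
chains                      605
theta mode [deg]           90.0
max copy number               6
max angular extent [deg]     98.5
pooled density [1/nm]    0.0928
```

The θ distribution peaks in the 90° bin (rings, not helices); the longest
chain holds six dimers and no chain wraps more than half a turn
(angular extent ≤ 180°); decoration is sparse at ~0.09 particles/nm. The
recovered copy-number distribution for this fixture is
`{1: 415, 2: 112, 3: 43, 4: 23, 5: 10, 6: 2}` — short oligomers dominated
by individual dimers. `res.pairs_frame()`, `res.chains_frame()` and
`res.density_frame()` expose the tidy per-pair / per-chain / per-filament
tables; `res.plot_theta()` and `res.plot_chain_lengths()` draw the
frequency plots.

The same analysis runs from files and from the shell:

```sh
mtoligo simulate --preset paper-like --n-filaments 20 --rng-seed 42 --out-dir fixture
mtoligo report fixture/particles.tbl fixture/traces.txt
mtoligo run -c config.yaml        # full pipeline: tables + histograms + report
```

A run config is one YAML document (see `mtoligo.pipeline.RunConfig`);
identical config + seed reproduces byte-identical outputs.

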