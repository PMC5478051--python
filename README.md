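# riverscape

Isolation-by-distance analysis for riverine and semiaquatic species, built
around the question: *does genetic structure track the river network or the
overland landscape?*

Semiaquatic animals such as desmans, water shrews or platypuses can disperse
along rivers, across land, or both. Given mitochondrial sequences, sample
coordinates and GIS layers, this package compares how well three geographic
distances explain genetic divergence:

* **great-circle (Euclidean)** distance on the sphere,
* **altitude least-cost-path (LCP)** distance over an elevation raster, where
  higher terrain conducts less and cell-to-cell conductances are
  geo-corrected by the true inter-cell distance,
* **river-network distance** along the dendritic drainage, with samples
  snapped to the nearest river and pairs in disconnected basins treated as
  missing data.

Genetic distance is the **patristic distance** d<sub>ij</sub> — the sum of
branch lengths separating samples *i* and *j* in a phylogenetic tree (a
user-supplied Newick tree, or a neighbor-joining tree built from the
alignment). Each geographic matrix **G** is compared with the genetic matrix
**D** by a **Mantel permutation test**: the Pearson correlation *r* over
valid off-diagonal pairs, with a two-tailed add-one p-value from joint
row/column permutations (so the smallest attainable p at 9,999 permutations
is 2/10,000 = .0002). Among-basin structure is quantified by a one-way
**AMOVA**: the squared-distance sums decompose as

SSD<sub>total</sub> = SSD<sub>among</sub> + SSD<sub>within</sub>,  σ²<sub>w</sub> = MSD<sub>within</sub>,  σ²<sub>a</sub> = (MSD<sub>among</sub> − MSD<sub>within</sub>)/n′,  Φ<sub>ST</sub> = σ²<sub>a</sub>/(σ²<sub>a</sub> + σ²<sub>w</sub>),

with n′ the unequal-group-size coefficient. Spatial variation of diversity is
mapped by computing nucleotide diversity π over every sample within 10 km of
each sampling point and interpolating the values onto a 1 km grid by inverse
distance weighting.

Because real studies of this kind need deposited sequences and national GIS
layers, the package ships a **synthetic riverscape generator**: dendritic
binary-tree networks (one per basin), altitude surfaces rising toward the
headwaters with a ridge between basins, samples placed length-uniformly on
the rivers, and HKY-simulated sequences whose divergence tracks a chosen
geographic distance with tunable noise. The generator makes the whole
pipeline testable end-to-end, including whether the analysis recovers the
distance model that generated the data.

## Worked example

Run the full analysis on a synthetic two-basin riverscape whose sequences
were generated from **river** distances (40 samples, 1,066-site alignment,
α = 10⁻⁶ substitutions/site per meter, σ = 0.2):

```python
import riverscape as rs

cfg = rs.AnalysisConfig(simulation=rs.SimulationConfig(seed=1), seed=1)
report = rs.run_full_analysis(cfg)
for name in ("euclidean", "lcp", "river"):
    m = report.mantel[name]
    print(f"{name:10s} r = {m.r:+.3f}   p = {m.p:.4f}   pairs = {m.n_pairs_used}")
a = report.amova
print(f"AMOVA: {a.pct_among:.1f}% of variance among basins "
      f"(phi_ST = {a.phi_st:.3f}, p = {a.p:.3f})")
```

prints

```
euclidean  r = +0.828   p = 0.0002   pairs = 780
lcp        r = +0.945   p = 0.0002   pairs = 780
river      r = +0.959   p = 0.0002   pairs = 381
AMOVA: 92.3% of variance among basins (phi_ST = 0.923, p = 0.001)
```

Read this as: all three geographic distances correlate with genetic
divergence (every p sits at the .0002 permutation floor), but the river
distance — the model that actually generated the data — correlates best
(r = 0.959 over the 381 within-basin pairs; inter-basin pairs are missing
for river distance because the basins are disconnected). The AMOVA assigns
92.3% of the molecular variance to the between-basin partition, as expected
when basins are linked only through their distant outlets.

The same analysis is available from the shell:

```bash
riverscape simulate --seed 1 --out sim/           # network, raster, samples, FASTA
riverscape distances --samples sim/samples.csv \
    --network sim/network.geojson --raster sim/altitude.asc --out dist/
riverscape mantel dist/river.csv dist/euclidean.csv
riverscape run --config analysis.yaml --out results/
riverscape recover --seed 0 --reps 20             # parameter-recovery table
```

`riverscape recover` replicates the simulate→analyze loop and tabulates, per
replicate, the Mantel r of each geographic model against the re-inferred
genetic distances and which model wins — the package's own check that river-
and land-generated data are distinguishable at the default study scale.

## Layout

```
src/riverscape/core.py          shared containers (DistanceMatrix, SampleSet,
                                RiverNetwork, rasters) + haversine geodesy
src/riverscape/genetics.py      FASTA alignments, haplotypes, p-distances,
                                neighbor joining, patristic distances, pi
src/riverscape/geodist.py       snapping, river-network, least-cost-path and
                                great-circle distance matrices
src/riverscape/spatialstats.py  Mantel test, one-way AMOVA, windowed pi, IDW
src/riverscape/synthetic.py     dendritic riverscape + HKY sequence generator
src/riverscape/pipeline.py      end-to-end analysis and recovery experiment
src/riverscape/cli.py           click CLI (simulate/distances/mantel/amova/
                                diversity-map/run/recover)
docs/methods.md                 model assumptions, parameter choices, limits
```
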