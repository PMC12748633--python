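# phasedig

Semi-automatic digitization of binary surfactant–water phase diagrams.

Published phase diagrams for surfactants — maps of phase state versus
temperature and composition — exist almost exclusively as figures in papers
and books. `phasedig` turns a raster image of such a diagram (a scan or
screen capture, fully enclosed by its plot frame) into a gridded,
*probabilistic* phase-state dataset: every (temperature, wt%) lattice point
receives a normalized probability over the phase states present in the
diagram, with single-phase regions (micellar L1, hexagonal H1, lamellar Lα,
…) and two-phase coexistence regions (L1+W cloud regions, narrow biphasic
gaps) treated on the same footing. The output is a validated JSON record
format ("PhDat") designed for machine-learning work on surfactant phase
behavior.

It is a library plus a `phasedig` command line for people who curate phase
data: formulation scientists, soft-matter physicists, and ML practitioners
building phase-prediction training sets.

## The method

1. **Segment.** The image is binarized on normalized darkness; the largest
   closed contour identifies the plot frame; a skewed frame (book scans) is
   projectively rectified onto a rectangle; nuisance ink (labels, tick
   marks, stray text) is discarded by keeping only the *n* largest
   connected ink components; manual edit primitives add missing isotherms,
   draw or erase segments, and extend open boundaries along their local
   slope. Boundary lines are then thinned to one pixel by removing ink
   pixels in order of their adjacency to white pixels, *never changing the
   number of enclosed areas*, and the phase domains are labeled 1..n by
   connected-component analysis (`scipy.ndimage.label`).
2. **Trace (optional).** For cluttered figures, individual boundary curves
   are reconstructed from user guide points: each point snaps to the
   nearest ink pixel and consecutive points are joined by a fewest-steps
   path (up/down/left/right moves, white pixels are walls) through that
   curve's own pixels, so the trace always recovers part of the original
   curve. Overlaying all curves with the frame rebuilds the diagram.
3. **Sample.** With an axis calibration (pixel ↔ data mapping, linear or
   log), every grid point — default spacing 1 °C × 1 wt% — is mapped to its
   test pixel. For each phase *i* the minimum Euclidean distance *dᵢ* is
   measured in data units (1 °C ≡ 1 wt%), and the soft assignment is

   &nbsp;&nbsp;&nbsp;&nbsp;*Pᵢ = exp(−dᵢ / 2)*,

   with raw weights below 10⁻³ set to exactly zero and the rest normalized
   to one. A point inside a phase far from all others gets probability 1; a
   point on a one-pixel boundary between two phases gets 0.5 / 0.5.
4. **Record.** The table plus compound metadata (SMILES, name, source,
   measurement method, charge type, …) becomes one PhDat JSON record;
   records are indexed, queryable, and validated against a controlled
   vocabulary of 118 canonical phase states.

A synthetic-diagram generator (`phasedig.synth`) rasterizes known vector
geometry — polygonal regions, isotherms, dashed segments, text-like blobs,
sheared frames — so the whole pipeline is testable against exact
point-to-polygon distances without any external data.

## Worked example

```python
from phasedig import image as im, sampler as sp, synth

spec = synth.half_plane_spec(split_w=50.0, height=401, width=401,
                             line_width=1, text_blobs=4, seed=7)
diagram, truth = synth.generate(spec)

mask = im.keep_largest(im.binarize(diagram), 1)
labeled = im.label_regions(im.thin(mask))
print("regions found:", labeled.n)

states = synth.region_state_map(labeled, truth.calibration, truth)
print("region -> state:", states)

table = sp.sample_grid(labeled, truth.calibration,
                       sp.GridSpec(0, 100, 0, 100, 1, 1), states)
print("grid points sampled:", len(table))
print(table[(table.temperature == 50) & (table.composition.isin([40, 50, 60]))])
```

prints

```
regions found: 2
region -> state: {1: 'L1', 2: 'La'}
grid points sampled: 10201
      temperature  composition        L1        La
5090           50           40  0.994089  0.005911
5100           50           50  0.500000  0.500000
5110           50           60  0.005911  0.994089
```

The diagram is an L1 | Lα half-plane split at 50 wt% with four text-blob
nuisance marks; cleaning removes the blobs, segmentation finds the two
regions, and the 101 × 101 unit grid yields 10201 points. Ten wt% away from
the boundary the point is nearly certain (the other phase is 10 data units
away, exp(−5) ≈ 0.006 after normalization); exactly on the boundary pixel
both phases are equidistant and the probabilities are exactly 50 % / 50 %.

The same flow runs from the shell:

```sh
phasedig synth spec.json --seed 7 -o diagram.png --truth truth.json
phasedig segment diagram.png --keep 1 -o labeled.npz
phasedig sample labeled.npz --cal cal.json --grid 1,1 --states states.json -o table.csv
phasedig record table.csv --meta meta.json -o phdat.json
phasedig validate phdat.json
phasedig query phdat.json --type anionic --drop-u -o out.csv
phasedig stats phdat.json --floor 0.01 -o freq.csv
```

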