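# aggflux

Quantifying the aggregation flux of huntingtin exon 1 (Httex1) in cell
populations. Expansion of Httex1's polyglutamine (polyQ) tract beyond ~36
glutamines drives its aggregation from monomers through dispersed
oligomers into micrometre-scale inclusion bodies — the hallmark of
Huntington disease — and relating those states to cell death requires
measuring them in the same experiment. `aggflux` implements that platform
as a tested, reusable pipeline, exercised end to end on a synthetic
cell-population and instrument simulator with known ground truth:

* **Pulse-shape flow cytometry (PulSA).** Fluorescence concentrated in an
  inclusion raises a cytometer pulse's height and narrows its width at
  fixed area, so cells with inclusions (**i**) separate from cells with
  dispersed Httex1 (**ni**). A bicistronic membrane reporter (mKate2-F)
  marks transfected cells independently of Httex1's fate, which also
  reveals dead-cell ghosts that leached their cytosol (**L**) and
  free-inclusion debris (**D**) next to the intact **M** population; a
  tetracysteine/FlAsH biosensor that binds only monomeric Httex1 flags
  cells whose dispersed protein is already self-aggregated (**PFR,ni**).
* **A defined death-rate statistic.** Dead cells are counted as
  `|SYTOX+| + |SYTOX−, L| + |SYTOX−, D|` over transfected events, each D
  event taken as the remnant of one cell — capturing deaths that
  membrane-permeability staining alone misses.
* **Molecular partitioning.** Gel filtration on an S1000-type column
  quantitates monomer and oligomer pools (inclusions are occluded), while
  low-speed sedimentation velocity in 2 M sucrose quantitates the
  inclusion share and total abundance via an `ls-g*(s)` least-squares
  boundary analysis; combining the two gives the fractions of Httex1
  molecules as monomer / oligomer / inclusion:
  `p_mono = (1−p_inc)·m/(m+o)`, `p_olig = (1−p_inc)·o/(m+o)`.

The simulator covers chaperone co-expression arms (hsp40/DNAJB1,
hsp70/HSPA1A, and their combination) as multiplicative hazard modifiers,
so the pipeline's ability to resolve chaperone-sized effects on
aggregation and death is itself under test. See `docs/methods.md` for the
model, every tunable parameter, and what passing tests do and do not show.

## Worked example

Simulate a 72Q population for 46 h, acquire cytometry events, derive the
gate set from untransfected/unstained/diffuse-control references, and
compute the headline statistics; then pool the same cells into a lysate
and recover its molecular partition from simulated chromatogram and
sucrose-run scans:

```python
import aggflux as ag
from aggflux import metrics, sva
from aggflux.pipeline import _reference_events
from aggflux.instrument import (SUCROSE_SCAN_TIMES, simulate_chromatogram,
                                simulate_radial_scans)
from aggflux.gel_filtration import decompose_pools
from aggflux.partitioning import combine_partition

panel = ag.PanelConfig()
cfg = ag.SimConfig(polyq_length=72, n_cells=10000, seed=1,
                   time_points=(46.0,))
cells = ag.simulate_population(cfg).at(46.0)
events = ag.cells_to_events(cells, panel, seed=2)
untransfected = _reference_events(panel, 3000, 3)
control = ag.make_diffuse_control(panel, 3000, 4)
gates = ag.derive_gateset(events, untransfected, untransfected)
labels = ag.apply_gates(events, gates, control, control)

n_tr = int(labels["transfected"].sum())
print(f"transfected events: {n_tr}")
print(f"inclusion (i) fraction: {(labels['pulsa'] == 'i').sum() / n_tr:.3f}")
for scope in ("all", "i", "ni"):
    print(f"death rate [{scope}]: {metrics.death_rate(labels, scope).rate:.3f}")

lysate = ag.pool_lysate(cells)
chrom = simulate_chromatogram(lysate, noise_sd=0.05, seed=5)
pools = decompose_pools(chrom, 18.0, 11.0)
scans = simulate_radial_scans(
    [(0.0, 1 - lysate.p_inc), (900.0, lysate.p_inc)],
    scan_times=SUCROSE_SCAN_TIMES, noise_sd=0.02, seed=6)
inc = sva.inclusion_fraction(scans)
part = combine_partition(pools, inc.p_inc, inc.total_loading * 1000)
print(f"partition mono/olig/inc: {part.p_mono:.3f} / {part.p_olig:.3f} "
      f"/ {part.p_inc:.3f}")
print(f"truth     mono/olig/inc: {lysate.p_mono:.3f} / {lysate.p_olig:.3f} "
      f"/ {lysate.p_inc:.3f}")
```

Output:

```
transfected events: 20340
inclusion (i) fraction: 0.109
death rate [all]: 0.376
death rate [i]: 0.561
death rate [ni]: 0.230
partition mono/olig/inc: 0.600 / 0.019 / 0.381
truth     mono/olig/inc: 0.595 / 0.019 / 0.386
```

At 46 h, 10.9 % of transfected events are inclusion-bearing; 56 % of the
inclusion-bearing population is dead against 23 % of the dispersed
population — inclusion formation tracks death. The recovered molecular
partition matches the pooled-lysate truth to well under one percentage
point per class.

A `aggflux` console command wraps each stage
(`simulate`, `gate`, `metrics`, `sva-fit`, `sva-inclusions`, `gf`,
`partition`, `stats`, `demo`, `report`); `aggflux demo --seed 0 --outdir
run/` executes the whole workflow and writes tidy CSVs plus a run
manifest whose fixed-seed reruns are byte-identical.

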