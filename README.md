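# colonytrack

Quantitative analysis of collective cell migration on aligned-fiber
substrates, aimed at the leader–follower structure of epithelial colonies
undergoing partial EMT: a minority of highly migratory mesenchymal
("leader") cells mixed into a cohesive epithelial ("follower") population at
a controlled percentage N. The package is written for experimentalists who
track nuclei with Fiji/TrackMate and binarize colony images upstream, and
for modelers who want a tested, reproducible pipeline from track tables to
condition-level statistics.

Collective migration is measured from two perspectives:

* **the colony** — area S, perimeter P, circularity 4πS/P² (1 for a circle,
  → 0 as the colony elongates), its time course and a paired 0 h vs 24 h
  comparison, and the center-of-mass path (1/n)Σᵢ(xᵢ, yᵢ) rebased to (0, 0);
* **the single cells** — straightness d_euclid/d_total ∈ (0, 1], mean speed
  d_total/elapsed time (µm/h), and per-step direction angles in [0°, 180°]
  measured from the axis perpendicular to the fibers, so 90° is motion
  along the fiber (rose-plot binning, 10° bins).

Because the motivating experiments' time-lapse data are not public, the
package ships an agent-based simulator of mixed leader/follower colonies on
a fiber-aligned substrate (persistent biased random walks + adhesion springs
+ crowding-diluted leader alignment) whose defaults reproduce the
characteristic mixing-ratio effects: follower speed peaks at intermediate N,
straightness and the 90° angle peak decay as N grows, and low-N colonies
elongate along the fibers. See `docs/methods.md` for the model and its
assumptions.

## Worked example

Simulate one colony at N = 40 (40% leaders), compute per-cell metrics and
group summaries:

```python
import numpy as np
import colonytrack as ct

out = ct.simulate_colony(ct.default_params(leader_fraction=0.4, seed=7))
table = ct.metrics_table(out.trackset)
print(ct.summarize_group(table).round(3).to_string(index=False))
```

```
 condition_N phenotype  n_cells  mean_straightness  sd_straightness  n_undefined_straightness  mean_mean_speed_um_h  sd_mean_speed_um_h  n_undefined_mean_speed_um_h
          40  follower       30              0.445            0.202                         0                12.880               2.244                            0
          40    leader       20              0.206            0.101                         0                25.989               0.008                            0
```

The 30 followers migrate at 12.9 ± 2.2 µm/h — well above the ≈ 8 µm/h of a
follower-only colony, the leader-enhancement effect — while the 20 leaders
sprint at their intrinsic ≈ 26 µm/h with low straightness (0.21): fast but
weakly guided wandering. Pooling the step angles and rendering the colony
masks:

```python
hist = ct.angle_histogram(np.concatenate(list(table["step_angles_deg"])))
print(hist["mean_deg"], hist["sd_deg"])        # 94.2 44.1

from colonytrack.cohort import largest_component_records
recs = [r for r in largest_component_records(out.mask_stack) if r]
print(recs[0].circularity, recs[-1].circularity)  # 0.710 0.569
```

The mean direction angle sits near 90° (fiber-aligned motion) with a broad
spread at this high mixing ratio, and colony circularity falls from 0.71 at
0 h to 0.57 at 24 h as the colony elongates along the fibers.

## Command line

The same pipeline is scriptable from the shell:

```bash
colonytrack simulate --leader-percent 40 --seed 7 --out runs/sim40     # tracks.csv + masks.tif
colonytrack sweep --fractions 0,20,40,60,80,100 --seeds 0,1,2 --out runs/cohort
colonytrack analyze --tracks my_colony.csv --condition 20 --frame-interval 15 --out runs/mine
colonytrack contrast --run runs/cohort --metric mean_speed_um_h --g1 40 --g2 0 --phenotype follower
```

`analyze` accepts CSV track tables (`cell_id,frame,x_um,y_um[,phenotype]`,
TrackMate-spot-export compatible) and optional multi-page TIFF mask stacks;
a reduced TrackMate XML subset is supported through
`colonytrack.read_trackmate_xml`. Every run directory contains delimited-
text tables (per-cell metrics, group summaries, pooled angle histograms,
shape and centroid time-series, circularity comparisons) plus a flat-text
manifest; rerunning the same manifest reproduces every table byte for byte.

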