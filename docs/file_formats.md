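# File formats

Exact dialects of every file `leafdissect` reads or writes.

## features.csv (long format)

One row per (leaf, unit); written by `leafdissect process` or
`leafdissect.features.write_feature_table`. Stable column order:

| column | unit | rows | meaning |
| --- | --- | --- | --- |
| `leaf_id` | — | all | identifier (file stem) |
| `unit` | — | all | `leaf` (whole-leaf row) or `leaflet` |
| `rank` | — | leaflet | 0 = terminal, 1.. = per-side distance from the terminal leaflet |
| `side` | — | leaflet | `terminal`, `left`, `right` |
| `area_px2` | px² | all | pixel count of the unit |
| `perimeter_px` | px | all | weighted outline-chain length |
| `major_axis_px`, `minor_axis_px` | px | leaflet | moment-equivalent ellipse axes (full lengths) |
| `eccentricity` | — | leaflet | √(1 − b²/a²) ∈ [0, 1) |
| `equivalent_diameter_px` | px | leaflet | √(4·area/π) |
| `petiolule_length_px` | px | leaflet | branching→cut weighted chain length |
| `petiolule_node_count` | nodes | leaflet | same path, raw skeleton-node count |
| `base_to_branching_px` | px | leaflet | base→branching weighted chain length |
| `inter_rachis_px` | px | leaflet | branching→next same-side branching toward the apex |
| `rachis_length_px` | px | leaf | base→terminal-cut weighted chain length |
| `rachis_node_count` | nodes | leaf | same path, raw node count |
| `petiole_length_px` | px | leaf | base→first-branching weighted chain length |
| `n_leaflets` | — | leaf | separated leaflet count |
| `area_mm2`, `perimeter_mm` | mm², mm | all | conversions at effective dpi (scanner dpi × scale factor); empty if dpi unknown |
| `dpi`, `scale_factor`, `source` | — | all | provenance metadata |

Missing values (e.g. inter-rachis on a single-pair leaf) are empty
cells, never 0. Floats are printed with `%.10g`.

## landmarks.tps

Standard TPS landmark records, one per leaf:

```
LM=8
<x> <y>          (8 lines; x = column, y = image_height − row,
                  i.e. Cartesian y-up so shapes import upright)
ID=<leaf_id>
```

Point 1 is the terminal-leaflet apex; points follow clockwise (in the
upright view). Coordinates are `%.6f`.

## outlines.txt

One block per leaf, blocks separated by a single blank line:

```
ID=<leaf_id>
<x>,<y>          (n_points lines, default 100; Cartesian y-up)
```

Points are resampled at equal arc-length spacing around the closed
terminal-leaflet outline, starting at the apex, clockwise; the final
point does not repeat the first. Suitable for Eigenshape-style outline
analysis or the R `shapes` workflow after a trivial reshape.

## markers.json

```json
{"<leaf_id>": {"group": "<label or empty>",
               "points": {"leaflet_center": [[x, y], ...],
                           "cut": ..., "branching": ...,
                           "base": [[0,0]], "top": [[0,1]]}}}
```

Coordinates are in the normalized leaf frame (base at the origin, top
at (0,1), x to the leaf's right).

## qc_report.csv

Columns `file,error,detail`: one row per failed image (`error` = the
exception class) or per non-fatal per-leaflet warning
(`error` = `warning`). An empty report has only the header.

## run_summary.json

Config echo (scale factor, pruning threshold, dpi, orientation, seed),
package version, input/success/QC counts and per-image wall times.

## Synthetic ground truth sidecar (`leafdissect synth`)

Per PNG, a JSON with `n_leaflets`, `unit_lengths` (petiole, rachis,
petiolule_i, inter_rachis_i, all geometric px), `cut_positions`,
`branch_positions`, `landmark_axis` (base and terminal-tip, row/col),
per-leaflet side/pair/center/semi-axes, and the generating parameters.
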