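"""Scan a grid of truncation cutoffs and map the "consistent" region.

The verdict of the crackling-relation test depends on where the
distributions are truncated before fitting.  Scanning (size cutoff x
duration cutoff) pairs exposes a connected region of cutoffs at which a
non-critical system is classified as consistent with criticality.
"""

from avacrit import (
    SurrogateParams,
    bin_spikes,
    default_bin_width,
    extract_avalanches,
    scan_cutoff_grid,
    simulate_surrogate,
)

reps = []
for k in range(14):
    raster = simulate_surrogate(SurrogateParams(), 60_000.0, seed=100 + k)
    reps.append(extract_avalanches(bin_spikes(raster, default_bin_width(raster))))

s_grid = [25, 50, 100, 200]
d_grid = [5, 10, 15, 20, 25]
grid = scan_cutoff_grid(reps, s_grid, d_grid, alpha=0.05, seed=0)

print("consistent (#) / rejected (.) / unusable (x); rows: s_max, cols: d_max")
print("        " + " ".join(f"{d:>3d}" for d in d_grid))
for i, s_max in enumerate(s_grid):
    cells = []
    for j in range(len(d_grid)):
        v = grid.consistent_mask[i, j]
        cells.append("  #" if v == 1.0 else ("  ." if v == 0.0 else "  x"))
    print(f"s={s_max:>4d} " + " ".join(cells))
print(f"largest 4-connected consistent region: {grid.largest_component_size} cells")
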