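"""The 30-2 stimulus grid and its eccentricity zones.

The 30-2 pattern tests 76 locations on a 6-degree lattice within the
central 30 degrees. The two points adjacent to the physiological blind
spot are excluded from analysis, leaving 74 analysable locations split
into three concentric zones: inner (30 points), middle (20) and outer
(24). Everything downstream - zonal RMSE, severity rules - is built on
this split.

Run: python examples/01_grid_and_zones.py
"""

import numpy as np

from perimsim import GRID_30_2, assign_zone

print(f"locations: {len(GRID_30_2)}, analysable: {GRID_30_2.n_analysable}")
for zone in ("inner", "middle", "outer"):
    mask = GRID_30_2.zone_mask(zone)
    ecc = GRID_30_2.eccentricity[mask]
    print(
        f"  {zone:6s}: {mask.sum():2d} points, "
        f"eccentricity {ecc.min():.1f} - {ecc.max():.1f} deg"
    )

# zone of an individual coordinate (right-eye convention: x > 0 temporal)
for x, y in ((3, 3), (9, 21), (27, 9), (15, 3)):
    print(f"  ({x:2d}, {y:2d}) -> {assign_zone(x, y).value}")

# a quick text map of the grid (T = temporal side, rows superior to inferior)
ys = sorted(set(GRID_30_2.y.tolist()), reverse=True)
xs = sorted(set(GRID_30_2.x.tolist()))
coords = {(p.x, p.y): p.zone.value[0].upper() for p in GRID_30_2}
print("\n        " + " ".join(f"{int(x):+3d}" for x in xs))
for y in ys:
    row = [coords.get((x, y), " ") for x in xs]
    print(f"  y{int(y):+3d}  " + "   ".join(row))

GRID_30_2.to_csv("grid_30_2.csv")
print("\nwrote grid_30_2.csv")
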