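"""Generate a synthetic karst mining-city scene and write it to disk.

Builds the default 60 km x 60 km scene — six land-use epochs, DEM, POP/GDP
surfaces, 66 mine points in two mining belts, carbonate mask — and exports
everything as ESRI ASCII grids and GeoJSON under ./scene_out/.
"""

import pathlib

import numpy as np

from karsthealth import SceneParams, generate_scene
from karsthealth.raster import write_points_geojson

out = pathlib.Path("scene_out")
out.mkdir(exist_ok=True)

scene = generate_scene(SceneParams(seed=42))

for epoch, lu in zip(scene.params.epochs, scene.landuse_series):
    lu.write_ascii(out / f"landuse_{epoch}.asc")
scene.dem.write_ascii(out / "dem.asc")
scene.carbonate_mask.with_data(
    scene.carbonate_mask.data.astype(float), nodata=-9999.0
).write_ascii(out / "carbonate.asc")
write_points_geojson(scene.mines, out / "mines.geojson")

print(f"scene extent: {scene.params.extent} m, "
      f"{scene.landuse_series[0].shape} pixels at "
      f"{scene.params.cell_size_m:.0f} m")
for epoch, lu in zip(scene.params.epochs, scene.landuse_series):
    counts = np.bincount(lu.data.ravel(), minlength=10)
    print(f"  {epoch}: built-up {counts[9]:4d} km^2, "
          f"farmland {counts[1]:4d} km^2, forest {counts[2]:4d} km^2")
print(f"mines: {len(scene.mines)}, "
      f"karst fraction: {scene.carbonate_mask.data.mean():.3f}")
# Built-up area should rise monotonically (urban expansion) while farmland
# declines, mirroring a rapidly urbanising mining prefecture.
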