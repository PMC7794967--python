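"""Land-use transition analysis: transfer matrix, dynamic degree and the
ecological change-direction score.

The change-direction score is positive when land converts toward
ecologically higher-valued classes (e.g. farmland returning to forest) and
negative when it degrades (e.g. conversion to construction land).
"""

from karsthealth import SceneParams, generate_scene, lcdm, transition_matrix
from karsthealth.lulc import single_dynamic_degree

scene = generate_scene(SceneParams(seed=42))
epochs = scene.params.epochs

for (t0, t1) in [(1990, 2000), (2000, 2015)]:
    lu0 = scene.landuse_series[epochs.index(t0)]
    lu1 = scene.landuse_series[epochs.index(t1)]
    tm = transition_matrix(lu0, lu1, interval=(t0, t1))
    changed = tm.area.sum() - tm.area.trace()
    score = lcdm(tm)
    k_built = single_dynamic_degree(tm, "built-up", t1 - t0)
    print(f"{t0}-{t1}: changed area {changed:7.0f} km^2, "
          f"change-direction score {score:+6.2f}%, "
          f"built-up dynamic degree {k_built:+5.2f}%/yr")
# A negative score in the early interval (urban expansion onto farmland)
# turning less negative or positive later reflects restoration policies
# (farmland converting to forest/grassland) outweighing degradation.
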