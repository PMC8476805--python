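"""Generate one example of every synthetic input the pipeline consumes.

Writes a lectin-channel vessel scene (with its ground-truth band mask),
a labelled leukocyte track set, a dye-leakage time-lapse index table and a
syndecan-1 cohort under results/simulated/.
"""

from pathlib import Path

from glycovivo import (
    LeakSpec,
    SceneSpec,
    TrackSpec,
    permeability_index,
    render_vessel_scene,
    simulate_cohort,
    simulate_leak_series,
    simulate_tracks,
)
from glycovivo.config import COHORT_DEFAULTS
from glycovivo.io import write_cohort, write_scene, write_tracks
from glycovivo.synthetic import CohortSpec

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
OUT.mkdir(parents=True, exist_ok=True)

frame, gt = render_vessel_scene(SceneSpec(noise_sd=5.0, seed=1))
write_scene(frame, gt, OUT / "scene")
print(f"scene: {frame.shape[0]}x{frame.shape[1]} px, "
      f"band {gt.band_thickness_px:.1f} px on each wall")

tracks, labels = simulate_tracks(TrackSpec(seed=1))
write_tracks(tracks, OUT / "tracks.csv", labels=labels)
print(f"tracks: {len(tracks)} cells "
      f"({labels.count('adhering')} adhering, {labels.count('rolling')} "
      f"rolling, {labels.count('flowing')} flowing), 31 samples each")

series, rate = simulate_leak_series(LeakSpec(leak_rate=0.3, noise_sd=2.0,
                                             seed=1))
idx = permeability_index(series)
idx.to_csv(OUT / "leak_index.csv", index=False, float_format="%.10g")
print(f"leak series: true rate {rate} gray levels/min, "
      f"{len(series.rois)} ROIs x {len(series.frames)} frames")

c = COHORT_DEFAULTS["sdc1"]
table = simulate_cohort(CohortSpec(
    variable="sdc1", schedule=tuple(c["schedule"]), group_means=c["means"],
    group_sds=c["sds"], n_per_time=c["n_per_time"], units=c["units"], seed=1))
write_cohort(table, OUT / "sdc1.csv")
print(f"cohort: syndecan-1, {len(table.data)} measurements over "
      f"hours {c['schedule']}")
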