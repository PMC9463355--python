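# torsoscan

Photogrammetric reconstruction of a patient's thorax surface and the
positions of an EIT electrode belt from handheld video.

Electrical impedance tomography (EIT) reconstructs intra-thoracic
impedance changes from currents injected through a belt of skin
electrodes. The reconstruction model needs the patient's actual chest
shape and electrode positions: with a 32-electrode belt, displacing an
electrode by one place (30–40 mm on an adult thorax) corrupts the
left/right localization that decides where a pneumothorax drain goes.
`torsoscan` turns a handheld video sweep of the chest into that missing
geometry:

1. frames are extracted from the video at 2 frames/s;
2. surface features are detected, matched pairwise (ratio test,
   cross-check, robust epipolar fit) and chained into tracks;
3. incremental structure from motion recovers camera poses and a sparse
   point cloud (essential-matrix seeding with cheirality voting,
   perspective-n-point registration, bundle adjustment);
4. each electrode carries a square binary fiducial (4×4 code grid, 50-id
   dictionary, 17 × 17 mm); detections of the same marker id in adjacent
   frames are harmonized and each corner is triangulated by the direct
   linear transform (DLT), the homogeneous least-squares intersection of
   the two viewing rays;
5. per-pair estimates are filtered and merged so every marker ends up
   with **exactly four** unique 3D vertices; the electrode center is the
   centroid of its corners;
6. the reconstruction is scaled to metric units with tape-measured
   inter-electrode distances, the cloud is densified by all-pairs track
   fusion and meshed on a cylindrical grid;
7. validation registers the result to a reference mesh (closed-form
   similarity + iterative closest point) and reports mean / standard
   deviation / maximum distances in millimeters, plus a clinical
   one-place-shift check against the inter-electrode spacing.

A first-class synthetic-scene module (`torsoscan.scene`) generates
superellipse torso phantoms, belts, camera orbits, noisy observations and
rendered frames with drawable marker patterns, so every stage is testable
against exact ground truth.

## Worked example

End-to-end electrode localization on a synthetic 1 m-circumference
phantom, recorded over a 100° arc at 0.70 m with 1 px observation noise
(the protocol geometry):

```python
import numpy as np

from torsoscan import (BeltSpec, CameraIntrinsics, TorsoPhantom,
                       TrajectorySpec, make_scene, project_scene,
                       align_point_pairs, clinical_threshold_check,
                       electrode_error, estimate_scale)
from torsoscan.electrodes import (MarkerDetection, assemble_electrodes,
                                  merge_corner_vertices,
                                  triangulate_marker_corners)
from torsoscan.features import (corner_tracks_from_observations,
                                tracks_from_observations)
from torsoscan.geometry import SimilarityTransform
from torsoscan.sfm import SfmSettings, run_incremental_sfm

phantom = TorsoPhantom(1.0 / (2 * np.pi), 1.0 / (2 * np.pi), 2.0, 0.4)
scene = make_scene(phantom, BeltSpec(belt_height_z=0.2),
                   TrajectorySpec(arc_degrees=100, distance=0.70, n_frames=21))
camera = CameraIntrinsics(1400, 1400, 800, 450, 1600, 900)
observations = project_scene(scene, camera, pixel_noise_sigma=1.0, seed=0)

tracks = (tracks_from_observations(observations)
          + corner_tracks_from_observations(observations))
cloud = run_incremental_sfm(tracks, camera, SfmSettings(seed=0))

detections = {o.frame_index: [MarkerDetection(o.frame_index, mid, c)
                              for mid, c in o.marker_corners.items()]
              for o in observations}
estimates = triangulate_marker_corners(detections, cloud.poses, camera)
electrodes = assemble_electrodes(merge_corner_vertices(estimates), scene.belt)

scale = estimate_scale(electrodes, scene.adjacent_center_distances())
electrodes = electrodes.transformed(SimilarityTransform(scale=scale))

centers = electrodes.centers()
common = sorted(set(centers) & set(scene.marker_centers))
rigid = align_point_pairs([centers[i] for i in common],
                          [scene.marker_centers[i] for i in common],
                          with_scale=False)
report = electrode_error({i: rigid.apply(centers[i]) for i in common},
                         scene.marker_centers)
check = clinical_threshold_check(report, scene.belt,
                                 circumference_m=phantom.perimeter)
print(f"electrodes recovered : {report.n} of {scene.belt.n_electrodes}")
print(f"mean / std / max (mm): {report.mean_signed:.2f} / "
      f"{report.std_signed:.2f} / {report.max_abs:.2f}")
print(f"one-place-shift check: {'pass' if check.passed else 'FAIL'} "
      f"(spacing {check.spacing_mm:.2f} mm, margin {check.margin_mm:.2f} mm)")
```

prints

```
electrodes recovered : 23 of 32
mean / std / max (mm): 1.35 / 0.52 / 2.65
one-place-shift check: pass (spacing 31.25 mm, margin 28.60 mm)
```

23 of 32 electrodes are recovered because a 100° sweep never images the
back of the belt; the recovered centers are localized to 1.35 mm on
average — well below the 31.25 mm spacing at which side information
would be lost. A full-orbit sweep recovers all 32 (see below).

There is also a CLI (`torsoscan simulate / reconstruct /
locate-electrodes / mesh / validate / report`) over the same library;
`torsoscan simulate --render --out scene/` writes ground truth JSON,
a phantom mesh and rendered PNG frames that `torsoscan reconstruct`
consumes.

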