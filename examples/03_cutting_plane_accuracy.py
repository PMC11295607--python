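"""Planned-vs-achieved cutting-plane accuracy in the XZ and YZ projections.

The planned main/side osteotomy planes are placed on a synthetic tibia.  An
"achieved" cut is emulated by a small registration error (0.8 degrees about
an oblique axis): the angle differences of the projected normals are the
accuracy statistic a sawbone trial reports per cut.
"""

import htonav as hn

tibia = hn.make_synthetic_tibia(hn.PatientShapeParams(seed=7))
planned = hn.make_cutting_planes(tibia)

nav_error = hn.RigidTransform.from_axis_angle([1, 0.5, 0.2], angle_deg=0.8)
achieved_main = hn.transform_plane(nav_error, planned.main)
achieved_side = hn.transform_plane(nav_error, planned.side)

for report in hn.angle_reports(planned, achieved_main, achieved_side):
    print(f"{report.role:>4} cut, {report.projection} projection: "
          f"{report.angle_deg:6.3f} deg")
# Each row is the tilt of the executed cut relative to the plan, seen in the
# sagittal (XZ) or coronal (YZ) projection; a perfect cut reads 0 deg in both.
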