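# Baseline configuration of the 2D neonatal brachial plexus model.
#
# Root dimensions (mm): averaged intra-operative measurements from 23
# infants; cranial-caudal diameters are the in-plane strip widths.
# Trunk lengths (mm): cord-to-distal-trunk path totals minus the summed
# root segment lengths (upper 41.4-30.5, middle 38.3-33.5, lower
# 30.8-20.0, the lower trunk measured along C8).
#
# RECONSTRUCTED values: the source anatomy shows root angles and cord
# dimensions only graphically.  The angles below (degrees between the
# root centreline and the caudal cord direction; <90 descends), the cord
# strip dimensions and the attachment spacing were calibrated during
# implementation so that (a) the path totals hold exactly and (b) the
# baseline quasistatic C5 junction stress approximates the reference
# 0.246 MPa.  They are model reconstructions, not measurements.

root_dimensions:
  C5: {d_cranial_caudal: 3.0, d_transverse: 1.1, len_spinal_to_drg: 7.5,
       len_drg_to_foramen: 9.0, len_foramen_to_trunk: 14.0}
  C6: {d_cranial_caudal: 3.1, d_transverse: 1.3, len_spinal_to_drg: 7.5,
       len_drg_to_foramen: 8.0, len_foramen_to_trunk: 15.5}
  C7: {d_cranial_caudal: 3.8, d_transverse: 1.6, len_spinal_to_drg: 7.5,
       len_drg_to_foramen: 7.0, len_foramen_to_trunk: 19.0}
  C8: {d_cranial_caudal: 2.7, d_transverse: 1.4, len_spinal_to_drg: 7.5,
       len_drg_to_foramen: 5.5, len_foramen_to_trunk: 7.0}
  T1: {d_cranial_caudal: 2.5, d_transverse: 1.4, len_spinal_to_drg: 7.5,
       len_drg_to_foramen: null, len_foramen_to_trunk: 6.0}

cord:
  width: 7.4
  length: 42.7
  # axial positions (mm) of the root attachments, measured caudally from
  # the cranial end of the cord strip
  attachment_positions: [6.0, 11.7, 19.4, 28.6, 36.2]

root_angles:   # reconstructed, see header
  C5: 77.5
  C6: 84.4
  C7: 87.2
  C8: 76.1
  T1: 85.6

# trunk axis angles (same convention); null = bisector of the member
# root directions.  Fixed axes stay put when root angles are perturbed.
trunk_angles:
  upper: 85.0
  middle: null
  lower: 69.0

trunk_lengths:
  upper: 10.9
  middle: 4.8
  lower: 10.8

load_cases:
  # quasistatic stretch, 0.01 mm/s
  case1: {loading_rate: 0.01, rupture_load: 1.08, load_multiplier: 5.0,
          youngs_modulus: 1.48, poisson_ratio: 0.4, applied_pressure: 0.332}
  # dynamic stretch, 10 mm/s
  case2: {loading_rate: 10.0, rupture_load: 2.12, load_multiplier: 5.0,
          youngs_modulus: 2.02, poisson_ratio: 0.4, applied_pressure: 0.653}

mesh:
  h_max: 2.0
  h_min: 0.2

study:
  angle_deltas: [-6, -3, 0, 3, 6]
  seed: 20240514
  integration_scheme: full_2x2
  # junction stress sampling: contour-style nodal average at the
  # root-cord interface (see plexusfem.postprocess.max_junction_stress)
  stress_measure: nodal_avg
  # distal portion of the outermost lateral edges carrying the guided
  # (symmetry-type) supports
  guided_edge_fraction: 0.5
  max_angle_delta: 10.0
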