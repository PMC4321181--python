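# Demonstration pipeline: simulate a small phantom acquisition, then run
# every analysis stage over the on-disk artifacts.
#   fibgold run --config examples/pipeline.yaml --outdir out/
seed: 21
simulate:
  shape: [50, 96, 96]
  voxel_size: [25.0, 5.0, 5.0]        # dz, dy, dx in nm
  cell_semiaxes: [1300.0, 230.0, 230.0]
  nucleus_diameter: 380.0
  nucleolus_diameter: 120.0
  nucleolus_offset: [0.0, 40.0, 40.0]
  heterochromatin_thickness: 40.0
segment:
  # operator seed voxels (slice, row, col) per compartment; 0 = resin background
  seeds:
    0: [2, 4, 4]
    1: [24, 89, 47]
    2: [24, 27, 47]
    3: [24, 55, 55]
    4: [24, 83, 47]
  min_object_voxels: 30
quantify:
  d: 20.0          # amplified bead diameter (nm)
  t: 25.0          # slice thickness (nm)
  p: 0.0           # BSE penetration depth in the counting model (nm)
  nucleus_diameter_um: 14.0
  assumed_total: 330000
spatial:
  compartment: nucleus
  radius_nm: 200.0
  n_reps: 199
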