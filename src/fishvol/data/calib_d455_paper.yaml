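# Overhead Intel RealSense D455 rig calibration (vendor Dynamic Calibrator
# output).  Units: focal lengths and principal points in pixels,
# translations in millimetres; R is row-major.
depth:
  fx: 648.890
  fy: 648.890
  cx: 637.205
  cy: 365.610
  width: 1280
  height: 720
color:
  fx: 639.446
  fy: 638.697
  cx: 649.125
  cy: 372.294
  width: 1280
  height: 800
depth_to_color:
  R: [1.000, 0.001, 0.002,
      -0.001, 1.000, 0.0004,
      -0.002, -0.0004, 1.000]
  T: [-59.157, -0.039, 0.0004]
# Right IR camera relative to the left (depth reference) camera; the stereo
# baseline pair that synthesizes depth.  Not used by the pipeline.
right_to_left:
  R: [1.000, 0.002, -0.013,
      -0.002, 1.000, -0.004,
      0.013, 0.004, 1.000]
  T: [-95.074, 0.171, -0.521]
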