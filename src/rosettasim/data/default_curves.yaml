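# Default rosette growth/shape curves (control points for monotone
# piecewise-cubic interpolation).  Units: f_lmax in model length units;
# f_l and f_lw unitless; f_ang in degrees of pitch from the vertical.
f_lmax:
- [0.0, 0.35]
- [0.25, 0.78]
- [0.45, 1.0]
- [0.7, 0.88]
- [1.0, 0.5]
f_l:
- [0.0, 0.0]
- [0.2, 0.06]
- [0.4, 0.28]
- [0.6, 0.68]
- [0.8, 0.93]
- [1.0, 1.0]
f_lw:
- [0.0, 0.0]
- [0.3, 0.42]
- [0.55, 0.55]
- [0.8, 0.38]
- [1.0, 0.0]
f_ang:
- [0.0, 82.0]
- [0.35, 72.0]
- [0.65, 55.0]
- [1.0, 32.0]
petiole_length_fraction: 0.5
petiole_width: 0.02
max_node: 20.0
maturation_plastochrons: 8.0
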