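"""Round trip: synthesise a helical track, recover its parameters.

Builds a noiseless helix with the measured population means (diameter
1.7 µm, pitch 5.3 µm, period 46 ms), adds 50 nm localisation noise, and
runs the helix extractor.  The printed numbers should match the inputs to
within a few percent; V_t is the speed along the path, V_z the effective
advance along the helix axis.
"""
from mcswim import fit_helix, make_helix_track

track = make_helix_track(diameter=1.7, pitch=5.3, period=0.046,
                         axis=(0.2, -0.3, 0.93), duration=0.5, fps=1640,
                         noise=0.05, seed=1)
fit = fit_helix(track)
print(f"diameter : {fit.diameter:6.3f} um   (input 1.700)")
print(f"pitch    : {fit.pitch:6.3f} um   (input 5.300)")
print(f"period   : {fit.period_ms:6.2f} ms   (input 46.00)")
print(f"V_z      : {fit.v_z:6.1f} um/s")
print(f"V_t      : {fit.v_t:6.1f} um/s")
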