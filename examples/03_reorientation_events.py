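"""Detect abrupt re-orientation events in a synthetic track.

Two helix segments with identical parameters but axes 90 degrees apart are
joined by a 4 ms axis rotation, mimicking the millisecond turns of
bilophotrichous cocci.  The detector reports the event time, its duration
and the turning angle between the stable pre/post axes.
"""
from mcswim import detect_reorientations, make_reorientation_track

helix = {"diameter": 1.7, "pitch": 5.3, "period": 0.046, "axis": (0, 0, 1)}
turned = dict(helix, axis=(1, 0, 0))
track = make_reorientation_track([(helix, 0.25), (turned, 0.25)],
                                 event_durations=[0.004], fps=1640, seed=5)
for ev in detect_reorientations(track):
    print(f"event at t = {ev.time*1e3:.1f} ms: "
          f"turn {ev.angle:.1f} deg in {ev.duration*1e3:.1f} ms")
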