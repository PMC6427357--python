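"""Blink-phase budgets and the camera frame-rate requirement.

Computes, for the published mean phase durations of voluntary and spontaneous
blinks, the total blink duration and each phase's share of it, then derives
the minimum camera rate that never skips the shortest phase (the spontaneous
pause).  A 30 fps webcam samples every ~33 ms — longer than the 13.7 ms pause
— so it can miss the fully-closed eye entirely; ~73 fps is the floor.
"""

from blinkflow import phase_breakdown, required_fps, spontaneous_defaults, voluntary_defaults
from blinkflow.evaluate import frame_period_ms

for label, kin in (("voluntary", voluntary_defaults()), ("spontaneous", spontaneous_defaults())):
    pb = phase_breakdown(kin)
    print(f"{label} blink: total {pb.total_ms:.1f} ms")
    print(f"  closing   {pb.closing_ms:6.1f} ms  ({pb.closing_pct:4.1f}%)")
    print(f"  pause     {pb.pause_ms:6.1f} ms  ({pb.pause_pct:4.1f}%)")
    print(f"  reopening {pb.reopening_ms:6.1f} ms  ({pb.reopening_pct:4.1f}%)")

print(f"\nframe period at 30 fps: {frame_period_ms(30):.1f} ms "
      f"(> {spontaneous_defaults().pause_ms} ms pause: too slow)")
print(f"required capture rate for the spontaneous pause: "
      f"{required_fps(spontaneous_defaults().pause_ms)} fps")
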