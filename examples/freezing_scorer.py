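"""Scoring freezing behavior from a synthetic video.

Builds a video that is still only during the 30-60 s baseline silence
window and during a late interval, then scores per-period freezing by
frame differencing. Fractions are the share of each period covered by
immobility bouts of at least one second.
"""

import chromodyn as cd

video, schedule = cd.simulate_behavior_video(
    duration_s=120,
    fps=10,
    motion_schedule=[(0, 30, True), (60, 90, True)],  # moving outside 30-60 & 90-120 s
    seed=3,
    periods=[("baseline (30-60 s)", 30, 60), ("CS period", 90, 120), ("whole session", 0, 120)],
)
report = cd.score_freezing(video)
for label, fraction in report.fractions.items():
    print(f"{label:20s} freezing = {fraction:.3f}")
print(f"{len(report.bouts)} freezing bouts:", [(round(a, 1), round(b, 1)) for a, b in report.bouts])
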