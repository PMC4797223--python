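"""Run the placebo moving-notch filter and inspect its random walk.

The placebo notch has the treatment's bandwidth but its center jumps
1/18 octave every 5 s, reversing at the 1-16 kHz borders, so no fixed
frequency region is spared for long — the intended inert control.
"""

import numpy as np

import notchkit as nk

probe = nk.make_probe("flat_noise", duration_s=60.0, seed=3)
out, trace = nk.process_placebo(probe, seed=42)

times = np.array([t for t, _, _ in trace])
centers = np.array([c for _, c, _ in trace])
jumps = np.nonzero(np.diff(centers) != 0)[0] + 1
steps_oct = np.log2(centers[jumps] / centers[jumps - 1])

print(f"processed {probe.duration_s:.0f} s; notch started at "
      f"{centers[0]:.0f} Hz and jumped {len(jumps)} times")
print(f"inter-jump intervals: {np.diff(times[jumps]).mean():.3f} s on average "
      "(design: 5 s)")
print(f"step sizes: all {np.abs(steps_oct).mean():.5f} octaves "
      f"(design: 1/18 = {1 / 18:.5f})")
reversals = int(np.sum(np.diff(np.sign(steps_oct)) != 0))
print(f"direction reversals at borders: {reversals}; "
      f"center range visited {centers.min():.0f}-{centers.max():.0f} Hz")
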