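"""Spectral arc length: smoothness of single vs fragmented movements.

SPARC is the negative arc length of the normalized magnitude spectrum of a
speed profile: a single smooth reach has a compact spectrum (value near
-1.4); breaking the same displacement into sub-movements spreads the
spectrum and makes the value more negative.
"""

import numpy as np

from reachkin.metrics import sparc
from reachkin.synthetic import minimum_jerk_velocity

rate = 100.0
t = np.arange(101) / rate
single = np.abs(minimum_jerk_velocity(0.25, 1.0, t))

print(f"single reach:          SPARC {sparc(single, rate):.3f}")
for gap_s in (0.2, 0.5, 1.0):
    double = np.concatenate([single, np.zeros(int(gap_s * rate)), single])
    print(f"two reaches, {gap_s:.1f} s apart: SPARC "
          f"{sparc(double, rate):.3f}")
print(f"amplitude invariance: SPARC(3v) - SPARC(v) = "
      f"{sparc(3 * single, rate) - sparc(single, rate):.1e}")
# longer pauses fragment the movement further: the value keeps dropping,
# which is why SPARC separates impaired (corrective, segmented) reaching
# from smooth reaching
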