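"""The variable-span supersmoother on a signal with mixed structure.

Smooths a curve that is flat on the left and has a sharp bump on the right —
the situation a fixed-bandwidth smoother handles badly. The supersmoother
picks a wide window where the curve is flat and a narrow one around the
bump, so it flattens the noise without smearing the feature.
"""

import numpy as np

from rbrid import SmootherConfig, fixed_span_smooth, supersmooth

rng = np.random.default_rng(0)
n = 400
x = np.arange(1.0, n + 1)
signal = np.where((x > 280) & (x < 320), 5.0, 0.0)
y = signal + rng.normal(0, 0.6, n)

adaptive = supersmooth(x, y)
woofer = fixed_span_smooth(x, y, span=0.5).fitted  # one wide fixed window

flat = slice(20, 250)
bump = slice(284, 315)
print("root-mean-square error against the noise-free signal:")
print(f"  flat region : supersmoother {np.sqrt(np.mean((adaptive[flat]-signal[flat])**2)):.3f}"
      f"  vs fixed wide span {np.sqrt(np.mean((woofer[flat]-signal[flat])**2)):.3f}")
print(f"  bump region : supersmoother {np.sqrt(np.mean((adaptive[bump]-signal[bump])**2)):.3f}"
      f"  vs fixed wide span {np.sqrt(np.mean((woofer[bump]-signal[bump])**2)):.3f}")
print(f"bump peak height: supersmoother {adaptive[bump].max():.2f}, "
      f"fixed wide span {woofer[bump].max():.2f} (truth 5.00)")
print()
print("The wide fixed span wins nothing on the flat part but crushes the")
print("bump; the supersmoother keeps the bump near full height because its")
print("cross-validated span choice narrows locally. bass > 0 in")
print(f"SmootherConfig (here bass={SmootherConfig().bass}) trades that")
print("sharpness for extra smoothness.")
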