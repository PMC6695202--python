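"""Transfer entropy on binary spike trains, with the scramble correction.

Builds an echo channel (output = input delayed by two 3 ms bins, plus
independent contamination), then estimates TE_raw, the scrambled noise floor
and the corrected TE, scanning the frame shift.
"""

import numpy as np

from stellate import BinarySequence, TEConfig, estimate_te

rng = np.random.default_rng(0)
n = 41_666  # 125 s at 3 ms bins
x = (rng.random(n) < 0.013).astype(np.uint8)  # ~4.3 Hz input
y = np.roll(x, 2) | (rng.random(n) < 0.01).astype(np.uint8)  # delayed + noise

res = estimate_te(
    BinarySequence(x, 3.0),
    BinarySequence(y, 3.0),
    TEConfig(k=10, u_max=10, n_scrambles=30, seed=1),
)
print(f"TE_raw   = {res.te_raw:.2f} bits/s at frame shift u* = {res.u_star}")
print(f"TE_noise = {res.te_noise:.2f} +- {res.te_noise_sd:.2f} bits/s (30 scrambles)")
print(f"TE       = {res.te:.2f} bits/s")

# With 10-bin words, every small frame shift that keeps the delayed bin inside
# the source word scores essentially the same, so u* lands in {0, 1, 2}; a
# k = 1 estimator pinpoints the delay exactly (see the frame-shift tests).
# TE_noise is what word-length-10 counting bias alone produces; subtracting it
# leaves the directed information carried through the echo.
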