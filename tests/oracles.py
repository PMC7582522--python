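"""Independent brute-force oracles, kept deliberately naive.

These re-derive the anisotropy ratio with explicit per-cell loops and
trigonometric sector tests, independently of the vectorised library path.
"""

import math


def brute_force_sector_ratio(patched, cells, theta_deg):
    """Anisotropy ratio by explicit looping: rotate each cell vector into
    the scanned frame, classify its angle into the four 90° sectors, then
    form the count-normalised quotient of sum-vector magnitudes."""
    sums = {s: [0.0, 0.0] for s in ("1A", "1B", "2A", "2B")}
    counts = {s: 0 for s in ("1A", "1B", "2A", "2B")}
    for c in cells:
        vx, vy = c[0] - patched[0], c[1] - patched[1]
        ang = math.degrees(math.atan2(vy, vx)) - theta_deg
        ang %= 360.0
        if 45.0 <= ang < 135.0:
            s = "1A"
        elif 225.0 <= ang < 315.0:
            s = "1B"
        elif ang >= 315.0 or ang < 45.0:
            s = "2A"
        else:
            s = "2B"
        sums[s][0] += vx
        sums[s][1] += vy
        counts[s] += 1

    def term(s):
        if counts[s] == 0:
            return 0.0
        return math.hypot(*sums[s]) / counts[s]

    num = term("1A") + term("1B")
    den = term("2A") + term("2B")
    if den == 0.0:
        return float("nan")
    return num / den
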