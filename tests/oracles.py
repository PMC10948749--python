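"""Independent brute-force reference implementations.

Pure-Python re-derivations of the glycemic indices used only to check the
vectorized engine.  They deliberately share no code with
``cgmetrics.indices``: risks are computed with ``math``, extrema by direct
neighbor comparison, and aggregations with explicit loops.

The extrema-based oracles assume no two consecutive readings are exactly
equal (randomized fixtures are generated accordingly); the engine itself
also handles plateaus.
"""

import math
import statistics

RISK_A, RISK_B, RISK_C = 1.509, 1.084, 5.381


def risk_low_high(bg: float):
    f = RISK_A * (math.log(bg) ** RISK_B - RISK_C)
    r = 10.0 * f * f
    if f < 0:
        return r, 0.0
    if f > 0:
        return 0.0, r
    return 0.0, 0.0


def _finite(vals):
    return [float(v) for v in vals if v == v]


def mage_oracle(vals, threshold=None):
    vals = _finite(vals)
    n = len(vals)
    if n < 3:
        return float("nan")
    if threshold is None:
        threshold = statistics.stdev(vals)
    extrema = [
        i
        for i in range(1, n - 1)
        if (vals[i] > vals[i - 1] and vals[i] > vals[i + 1])
        or (vals[i] < vals[i - 1] and vals[i] < vals[i + 1])
    ]
    if not extrema:
        return 0.0
    nodes = [0] + extrema + [n - 1]
    amplitudes = [abs(vals[b] - vals[a]) for a, b in zip(nodes, nodes[1:])]
    qualifying = [a for a in amplitudes if a > threshold]
    return sum(qualifying) / len(qualifying) if qualifying else 0.0


def lbgi_hbgi_oracle(vals):
    vals = _finite(vals)
    lows, highs = [], []
    for v in vals:
        rl, rh = risk_low_high(v)
        lows.append(rl)
        highs.append(rh)
    return sum(lows) / len(lows), sum(highs) / len(highs)


def adrr_oracle(days):
    ranges = []
    for day in days:
        vals = _finite(day)
        if not vals:
            continue
        max_rl = max(risk_low_high(v)[0] for v in vals)
        max_rh = max(risk_low_high(v)[1] for v in vals)
        ranges.append(max_rl + max_rh)
    return sum(ranges) / len(ranges) if ranges else float("nan")


def modd_oracle(days):
    diffs = []
    for a, b in zip(days, days[1:]):
        for x, y in zip(a, b):
            if x == x and y == y:
                diffs.append(abs(y - x))
    return sum(diffs) / len(diffs) if diffs else float("nan")


def conga_oracle(day, lag_steps):
    diffs = []
    for t in range(lag_steps, len(day)):
        x, y = day[t - lag_steps], day[t]
        if x == x and y == y:
            diffs.append(y - x)
    if len(diffs) < 2:
        return float("nan")
    return statistics.stdev(diffs)
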