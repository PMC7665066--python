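"""Literal brute-force reference implementations used as independent oracles.

Each function re-states its definition as directly as possible (explicit
loops, no vectorization) so agreement with the library is meaningful.
"""

from __future__ import annotations

import numpy as np

WET = 0.1


def onset_brute_force(precip, lo: int, hi: int):
    """First day d in [lo, hi] satisfying, checked literally day by day:
    (i) >= 25 mm total over d..d+5, (ii) day d wet and >= 2 other wet days in
    d..d+5, (iii) no run of >= 10 consecutive dry days within d+1..d+40."""
    precip = list(precip)
    for d in range(lo, hi + 1):
        window = precip[d : d + 6]
        if sum(window) < 25.0:
            continue
        if not window[0] > WET:
            continue
        if sum(1 for v in window[1:] if v > WET) < 2:
            continue
        run, bad = 0, False
        for v in precip[d + 1 : d + 41]:
            run = run + 1 if v <= WET else 0
            if run >= 10:
                bad = True
                break
        if bad:
            continue
        return d
    return None


def gdd_split_scan(tas, t_base: float, t_cap: float) -> int:
    """Cumulative-sum scan for the first day reaching half the GDD total."""
    gdd = [max(0.0, min(t, t_cap) - t_base) for t in tas]
    total = sum(gdd)
    half = 0.5 * total
    cum = 0.0
    for i, g in enumerate(gdd):
        cum += g
        if cum >= half:
            return i + 1
    return len(gdd)


def median_low_oracle(values) -> int:
    vs = sorted(values)
    return int(round(vs[(len(vs) - 1) // 2]))


def percentile_oracle(values, q: float) -> float:
    """Sort + linear interpolation at rank q/100 * (n-1)."""
    vs = sorted(float(v) for v in values)
    pos = q / 100.0 * (len(vs) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return vs[lo] * (1 - frac) + vs[hi] * frac


def count_above_oracle(values, threshold) -> int:
    return sum(1 for v in values if v > threshold)


def count_below_oracle(values, threshold) -> int:
    return sum(1 for v in values if v < threshold)


def dry_spell_oracle(precip, min_len: int) -> int:
    """Count maximal dry runs strictly longer than min_len by explicit scan."""
    runs = []
    run = 0
    for v in precip:
        if v <= WET:
            run += 1
        else:
            if run:
                runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return sum(1 for r in runs if r > min_len)


def median_oracle(values) -> float:
    vs = sorted(float(v) for v in values)
    n = len(vs)
    mid = n // 2
    return vs[mid] if n % 2 else 0.5 * (vs[mid - 1] + vs[mid])


def pearson_oracle(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x - x.mean(), y - y.mean()
    denom = np.sqrt((xm**2).sum() * (ym**2).sum())
    return float((xm * ym).sum() / denom) if denom > 0 else 0.0


def greedy_collinearity_oracle(df, y, threshold=0.7):
    """Literal restatement of the pair-resolution rule: enumerate all pairs
    with |r| > threshold, order by (-|r|, name, name), and walk the list
    dropping the member less correlated with y (tie: later name)."""
    cols = list(df.columns)
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = abs(pearson_oracle(df[a], df[b]))
            if r > threshold:
                pairs.append((r, a, b))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    alive = set(cols)
    ry = {c: abs(pearson_oracle(df[c], y)) for c in cols}
    for _, a, b in pairs:
        if a in alive and b in alive:
            if ry[a] > ry[b]:
                alive.discard(b)
            elif ry[b] > ry[a]:
                alive.discard(a)
            else:
                alive.discard(max(a, b))
    return [c for c in cols if c in alive]


def nse_oracle(obs, pred) -> float:
    obs = list(map(float, obs))
    pred = list(map(float, pred))
    m = sum(obs) / len(obs)
    sse = sum((o - p) ** 2 for o, p in zip(obs, pred))
    sst = sum((o - m) ** 2 for o in obs)
    return 1.0 - sse / sst


def rmse_oracle(obs, pred) -> float:
    return float(np.sqrt(sum((o - p) ** 2 for o, p in zip(obs, pred)) / len(obs)))


def bernoulli_gamma_series(rng, n_days: int, p_wet: float = 0.35, shape: float = 0.8, scale: float = 9.0):
    """Simple wet/dry daily rainfall series for oracle comparisons."""
    occ = rng.random(n_days) < p_wet
    amt = rng.gamma(shape, scale, n_days)
    return np.where(occ, amt, 0.0)
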