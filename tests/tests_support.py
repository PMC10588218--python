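"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately avoid the package's own code paths: run-length scanning,
per-pixel window evaluation, explicit product over risk sets, and the raw
step-up rule.
"""

import numpy as np
from skimage.morphology import disk


def bout_oracle(counts, min_len=5):
    """(start, length) of maximal zero runs >= min_len, by linear scan."""
    out, run = [], 0
    for i, c in enumerate(counts):
        if c == 0:
            run += 1
        else:
            if run >= min_len:
                out.append((i - run, run))
            run = 0
    if run >= min_len:
        out.append((len(counts) - run, run))
    return out


def bernsen_oracle(img, radius, c_thr, bright_background=False):
    """Per-pixel circular-window Bernsen rule with nearest-edge padding."""
    fp = disk(radius).astype(bool)
    h, w = img.shape
    out = np.zeros((h, w), bool)
    gmid = (img.max() + img.min()) / 2
    r = radius
    for y in range(h):
        for x in range(w):
            vals = []
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if not fp[dy + r, dx + r]:
                        continue
                    yy = min(max(y + dy, 0), h - 1)
                    xx = min(max(x + dx, 0), w - 1)
                    vals.append(img[yy, xx])
            mx, mn = max(vals), min(vals)
            mid = (mx + mn) / 2
            if mx - mn < c_thr:
                out[y, x] = (mid < gmid) if bright_background else (mid >= gmid)
            else:
                out[y, x] = img[y, x] >= mid
    return out


def km_oracle(times, events):
    """{t: S(t)}: explicit product over risk sets, deaths before censorings."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in sorted(set(times)):
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        if at_risk > 0:
            s *= 1 - d / at_risk
        out[t] = s
    return out


def bh_bruteforce(p):
    """Step-up rule applied literally: p_adj(i) = min over p_(k) >= p_(i) of
    p_(k) * n / rank(k), capped at 1."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(n)
    for i, pi in enumerate(p):
        cands = [
            p[idx] * n / rank
            for rank, idx in enumerate(order, start=1)
            if p[idx] >= pi
        ]
        out[i] = min(1.0, min(cands))
    return out
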