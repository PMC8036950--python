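"""Independent brute-force oracles used to check the package's computations.

Everything here is deliberately written with plain loops and explicit
formulas, separate from the implementation paths it checks.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# per-channel statistics


def oracle_channel_features(v, rate_hz):
    v = [float(x) for x in v]
    n = len(v)
    mean = sum(v) / n
    dev = [x - mean for x in v]
    var = sum(d * d for d in dev) / (n - 1)
    sd = math.sqrt(var)
    m2 = sum(d * d for d in dev) / n
    m3 = sum(d**3 for d in dev) / n
    m4 = sum(d**4 for d in dev) / n
    vmin, vmax = min(v), max(v)
    q75 = float(np.percentile(v, 75))
    q25 = float(np.percentile(v, 25))
    power = sum(x * x for x in v) / n
    degenerate = var < 1e-12 * max(1.0, mean * mean)

    out = {
        "mean": mean,
        "sum": sum(v),
        "sd": sd,
        "variance": var,
        "cv": 0.0 if abs(mean) < 1e-12 else min(sd / abs(mean), 100.0),
        "min": vmin,
        "max": vmax,
        "amp": vmax - vmin,
        "iqr": q75 - q25,
        "skewness": 0.0 if degenerate else m3 / m2**1.5,
        "kurtosis": 0.0 if degenerate else m4 / m2**2 - 3.0,
        "power": power,
        "rms": math.sqrt(power),
        "autocorr_lag1": 0.0 if degenerate else oracle_pearson(v[:-1], v[1:]),
    }

    # explicit DFT of the mean-removed signal, zero bin excluded
    nbins = n // 2
    spec = []
    for k in range(1, nbins + 1):
        re = sum(dev[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = sum(dev[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        spec.append(re * re + im * im)
    total = sum(spec)
    if degenerate or total < 1e-12:
        out["dominant_frequency"] = 0.0
        out["spectral_entropy"] = 0.0
    else:
        kmax = max(range(nbins), key=lambda k: spec[k])
        out["dominant_frequency"] = (kmax + 1) * rate_hz / n
        ps = [s / total for s in spec]
        ent = -sum(p * math.log(p) for p in ps if p > 0)
        out["spectral_entropy"] = ent / math.log(nbins)
    return out


def oracle_pearson(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    num = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    da = math.sqrt(sum((x - ma) ** 2 for x in a))
    db = math.sqrt(sum((y - mb) ** 2 for y in b))
    if da * db < 1e-12:
        return 0.0
    return num / (da * db)


# ---------------------------------------------------------------------------
# greedy correlation pruning


def oracle_correlation_prune(X, names, cutoff=0.95):
    """Naive restatement of the greedy rule: recompute everything each pass."""
    alive = list(range(len(names)))

    def absr(i, j):
        r = oracle_pearson(list(X[:, i]), list(X[:, j]))
        return abs(r)

    while len(alive) >= 2:
        worst, wi, wj = -1.0, None, None
        for ii in range(len(alive)):
            for jj in range(ii + 1, len(alive)):
                r = absr(alive[ii], alive[jj])
                if r > worst:
                    worst, wi, wj = r, alive[ii], alive[jj]
        if worst <= cutoff:
            break
        mean_i = sum(absr(wi, k) for k in alive if k != wi) / (len(alive) - 1)
        mean_j = sum(absr(wj, k) for k in alive if k != wj) / (len(alive) - 1)
        victim = wj if mean_j >= mean_i else wi
        alive.remove(victim)
    return [names[k] for k in alive]


# ---------------------------------------------------------------------------
# two-way within-subject ANOVA (textbook mean formulas, plain loops)


def oracle_rm_anova(y):
    """y: dict (subject, a_level, b_level) -> value, fully crossed."""
    subs = sorted({k[0] for k in y})
    la = sorted({k[1] for k in y})
    lb = sorted({k[2] for k in y})
    n, a, b = len(subs), len(la), len(lb)
    g = sum(y.values()) / (n * a * b)
    ma = {f: np.mean([y[(s, f, r)] for s in subs for r in lb]) for f in la}
    mb = {r: np.mean([y[(s, f, r)] for s in subs for f in la]) for r in lb}
    ms = {s: np.mean([y[(s, f, r)] for f in la for r in lb]) for s in subs}
    mab = {(f, r): np.mean([y[(s, f, r)] for s in subs]) for f in la for r in lb}
    msa = {(s, f): np.mean([y[(s, f, r)] for r in lb]) for s in subs for f in la}
    msb = {(s, r): np.mean([y[(s, f, r)] for f in la]) for s in subs for r in lb}
    ss_a = n * b * sum((ma[f] - g) ** 2 for f in la)
    ss_b = n * a * sum((mb[r] - g) ** 2 for r in lb)
    ss_ab = n * sum((mab[(f, r)] - ma[f] - mb[r] + g) ** 2 for f in la for r in lb)
    err_a = b * sum((msa[(s, f)] - ms[s] - ma[f] + g) ** 2 for s in subs for f in la)
    err_b = a * sum((msb[(s, r)] - ms[s] - mb[r] + g) ** 2 for s in subs for r in lb)
    err_ab = sum(
        (y[(s, f, r)] - msa[(s, f)] - msb[(s, r)] - mab[(f, r)] + ms[s] + ma[f] + mb[r] - g) ** 2
        for s in subs
        for f in la
        for r in lb
    )
    ss_subj = a * b * sum((ms[s] - g) ** 2 for s in subs)
    ss_tot = sum((v - g) ** 2 for v in y.values())
    F_a = (ss_a / (a - 1)) / (err_a / ((a - 1) * (n - 1)))
    F_b = (ss_b / (b - 1)) / (err_b / ((b - 1) * (n - 1)))
    F_ab = (ss_ab / ((a - 1) * (b - 1))) / (err_ab / ((a - 1) * (b - 1) * (n - 1)))
    return {
        "ss_a": ss_a,
        "ss_b": ss_b,
        "ss_ab": ss_ab,
        "err_a": err_a,
        "err_b": err_b,
        "err_ab": err_ab,
        "ss_subj": ss_subj,
        "ss_tot": ss_tot,
        "F_a": F_a,
        "F_b": F_b,
        "F_ab": F_ab,
    }
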