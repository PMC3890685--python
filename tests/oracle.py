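"""Independent brute-force reference implementation used only by tests.

Everything here is written in plain Python over characters and dicts, with
no reliance on the package's vectorized code paths: distances are recomputed
site by site, best matches by exhaustive enumeration, and the error metrics
straight from their defining formulas.
"""

import math

PURINES = {"A", "G"}
BASES = {"A", "C", "G", "T"}


def pair_counts(a, b):
    assert len(a) == len(b)
    comp = ts = tv = 0
    for x, y in zip(a, b):
        if x in BASES and y in BASES:
            comp += 1
            if x != y:
                if (x in PURINES) == (y in PURINES):
                    ts += 1
                else:
                    tv += 1
    return comp, ts, tv


def distance(a, b, model):
    comp, ts, tv = pair_counts(a, b)
    if comp == 0:
        return math.nan
    if model == "p":
        return (ts + tv) / comp
    if model == "jc69":
        p = (ts + tv) / comp
        arg = 1 - 4 * p / 3
        return -0.75 * math.log(arg) if arg > 0 else math.nan
    if model == "k2p":
        P, Q = ts / comp, tv / comp
        a1, a2 = 1 - 2 * P - Q, 1 - 2 * Q
        if a1 > 0 and a2 > 0:
            return -0.5 * math.log(a1) - 0.25 * math.log(a2)
        return math.nan
    raise ValueError(model)


def best_match(records, i, model, tol=1e-12):
    """(bm_distance, tied ids, tied species) for query i; NaN/empty if none."""
    dists = []
    for j, rec in enumerate(records):
        if j == i:
            continue
        d = distance(records[i][2], rec[2], model)
        if not math.isnan(d):
            dists.append((d, rec[0], rec[1]))
    if not dists:
        return math.nan, set(), set()
    dmin = min(d for d, _, _ in dists)
    ties = [(rid, sp) for d, rid, sp in dists if d <= dmin + tol]
    return dmin, {rid for rid, _ in ties}, {sp for _, sp in ties}


def bm_label(query_species, match_species):
    if not match_species:
        return "undefined"
    if query_species not in match_species:
        return "FP"
    if len(match_species) > 1:
        return "FP_ambiguous"
    return "TP"


def bcm_label(query_species, dmin, match_species, t):
    if not match_species:
        return "undefined"
    if dmin <= t:
        return bm_label(query_species, match_species)
    return "FN" if query_species in match_species else "TN"


def classify_all(records, model, t):
    """records: list of (id, species, residues) -> label per record at t."""
    labels = []
    for i, (_, sp, _) in enumerate(records):
        dmin, _, msp = best_match(records, i, model)
        labels.append(bcm_label(sp, dmin, msp, t))
    return labels


def metrics(labels, mode="incorrect"):
    c = {k: labels.count(k) for k in ("TP", "FP", "FP_ambiguous", "TN", "FN")}
    tp, fp, fpa, tn, fn = c["TP"], c["FP"], c["FP_ambiguous"], c["TN"], c["FN"]
    if mode == "incorrect":
        tp_e, fp_e, n = tp, fp + fpa, tp + fp + fpa + tn + fn
    elif mode == "correct":
        tp_e, fp_e, n = tp + fpa, fp, tp + fp + fpa + tn + fn
    else:
        tp_e, fp_e, n = tp, fp, tp + fp + tn + fn
    re = fp_e / (tp_e + fp_e) if tp_e + fp_e else math.nan
    prec = tp_e / (tp_e + fp_e) if tp_e + fp_e else math.nan
    oe = (fp_e + fn) / n if n else math.nan
    acc = (tp_e + tn) / n if n else math.nan
    return re, oe, acc, prec
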