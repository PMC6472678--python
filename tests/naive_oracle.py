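"""Literal, deliberately slow re-derivation of the agreement index.

Pure-Python enumeration with ``itertools`` and ``statistics`` only —
independent of the optimized paths in ``eoa.core`` (no shared helpers, no
numpy, no sorted-array tricks).  Used as the oracle in equivalence tests.
"""

import itertools
import statistics


def _aggregate(values, method):
    if method == "median":
        return statistics.median(values)
    return statistics.fmean(values)


def _fulfils(value, threshold, direction):
    return value > threshold if direction == "greater" else value < threshold


def naive_eoa(values, threshold=0.0, direction="greater", method="median"):
    """Enumerate every subset of every size and re-derive ES, AF and EOA.

    Returns a dict with keys ``es`` (int or None), ``af``, ``eoa``.
    """
    values = list(values)
    n = len(values)

    per_size = {
        i: [_aggregate(c, method) for c in itertools.combinations(values, i)]
        for i in range(1, n + 1)
    }

    es = None
    for i in range(1, n + 1):
        if all(_fulfils(v, threshold, direction) for v in per_size[i]):
            es = i
            break
    if es is None:
        return {"es": None, "af": 0.0, "eoa": 0.0}

    if es == 1:
        af = 0.0
    else:
        my = {}
        mn = {}
        for i in range(1, es):
            yes = [abs(v - threshold) for v in per_size[i]
                   if _fulfils(v, threshold, direction)]
            no = [abs(v - threshold) for v in per_size[i]
                  if not _fulfils(v, threshold, direction)]
            my[i] = sum(yes) / len(yes) if yes else 0.0
            mn[i] = sum(no) / len(no) if no else None

        defined = [my[i] / mn[i] for i in range(1, es)
                   if mn[i] is not None and mn[i] > 0]
        if not defined:
            af = 1.0
        else:
            fallback = max(defined)
            ratios = [
                my[i] / mn[i] if (mn[i] is not None and mn[i] > 0) else fallback
                for i in range(1, es)
            ]
            total = sum(ratios)
            af = 0.0 if total == 0 else max(1.0 - (es - 1) / total, 0.0)
            af = min(af, 1.0)

    eoa = (1.0 - (es - af) / (n + 1.0)) / (1.0 - 1.0 / (n + 1.0))
    return {"es": es, "af": af, "eoa": eoa}
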