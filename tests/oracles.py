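"""Independent brute-force oracles for cross-checking the implementation.

These deliberately avoid the package's own code paths: plain-dict
arithmetic and explicit sorts only.
"""

from __future__ import annotations


def bruteforce_top_orders(counts: dict[str, dict[str, int]],
                          subset: list[str], top_k: int,
                          min_fraction: float) -> list[str]:
    """Naive group-sum + sort + boundary-tie + floor selection.

    ``counts`` maps order -> {sample -> reads}. Zero-read samples in the
    subset contribute nothing; orders with zero pooled reads are excluded.
    Returns the selected order labels.
    """
    totals = {}
    for order, row in counts.items():
        t = sum(row.get(s, 0) for s in subset)
        if t > 0:
            totals[order] = t
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("empty pool")
    fractions = {o: t / grand for o, t in totals.items()}
    ranked = sorted(fractions, key=lambda o: (-fractions[o], o))
    if top_k <= 0:
        return []
    selected = ranked[:top_k]
    if len(ranked) > top_k and selected:
        boundary = fractions[selected[-1]]
        for o in ranked[top_k:]:
            if fractions[o] == boundary:
                selected.append(o)
            else:
                break
    return [o for o in selected if fractions[o] >= min_fraction]


def bruteforce_label_fractions(order_fractions: dict[str, float],
                               laboratory: set[str], seawater: set[str],
                               threshold: float,
                               unassigned_label: str) -> dict[str, float]:
    """Re-derive per-label read fractions by direct enumeration."""
    out = {"potential_contaminant": 0.0, "seawater_influenced": 0.0,
           "endemic": 0.0, "below_threshold": 0.0, "unassigned": 0.0}
    for order, frac in order_fractions.items():
        if order == unassigned_label:
            out["unassigned"] += frac
        elif frac < threshold:
            out["below_threshold"] += frac
        elif order in laboratory:
            out["potential_contaminant"] += frac
        elif order in seawater:
            out["seawater_influenced"] += frac
        else:
            out["endemic"] += frac
    return out
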