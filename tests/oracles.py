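"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the library's span arithmetic: matching selection
is re-derived by repeated argmin over candidate tuples, and modifier
governance is decided by enumerating token indices and testing membership
directly, so agreement with the engine is a real check.
"""

from __future__ import annotations

from typing import Optional, Sequence


def oracle_select_matches(
    norms: Sequence[str], patterns: Sequence[Sequence[str]]
) -> list[tuple[int, int, int]]:
    """All (start, end, rule_index) survivors of longest/leftmost/first-rule
    overlap resolution, by naive repeated selection."""
    candidates = []
    for ri, pat in enumerate(patterns):
        n = len(pat)
        if n == 0:
            continue
        for s in range(len(norms) - n + 1):
            if all(p == "*" or p == norms[s + k] for k, p in enumerate(pat)):
                candidates.append((s, s + n, ri))
    selected: list[tuple[int, int, int]] = []
    remaining = list(candidates)
    while remaining:
        best = min(remaining, key=lambda c: (-(c[1] - c[0]), c[0], c[2]))
        selected.append(best)
        remaining = [
            c for c in remaining if c[1] <= best[0] or c[0] >= best[1]
        ]
    return sorted(selected)


def governed_token_indices(
    n_tokens: int,
    mod_range: tuple[int, int],
    direction: str,
    max_scope: Optional[int],
    terminator_ranges: Sequence[tuple[int, int]],
) -> set[int]:
    """Token indices a modifier governs, enumerated one index at a time."""
    m_first, m_last = mod_range
    starts = sorted(s for s, _ in terminator_ranges)
    ends = sorted(e for _, e in terminator_ranges)

    fwd_hi = n_tokens
    for s in starts:
        if s >= m_last:
            fwd_hi = min(fwd_hi, s)
            break
    if max_scope is not None:
        fwd_hi = min(fwd_hi, m_last + max_scope)
    bwd_lo = 0
    for e in reversed(ends):
        if e <= m_first:
            bwd_lo = max(bwd_lo, e)
            break
    if max_scope is not None:
        bwd_lo = max(bwd_lo, m_first - max_scope)

    if direction == "FORWARD":
        return {i for i in range(n_tokens) if m_last <= i < fwd_hi}
    if direction == "BACKWARD":
        return {i for i in range(n_tokens) if bwd_lo <= i < m_first}
    # BIDIRECTIONAL: the contiguous window spanning both reaches, cue included
    return {i for i in range(n_tokens) if min(bwd_lo, m_first) <= i < max(fwd_hi, m_last)}


def textbook_metrics(preds: Sequence[int], golds: Sequence[int]) -> dict:
    """Plain-formula metrics on raw percentages, no rounding."""
    tp = sum(p and g for p, g in zip(preds, golds))
    fp = sum(p and not g for p, g in zip(preds, golds))
    fn = sum((not p) and g for p, g in zip(preds, golds))
    tn = sum((not p) and (not g) for p, g in zip(preds, golds))

    def frac(num, den):
        return None if den == 0 else 100.0 * num / den

    sens = frac(tp, tp + fn)
    prec = frac(tp, tp + fp)
    f1 = (
        None
        if sens is None or prec is None or sens + prec == 0
        else 2 * prec * sens / (prec + sens)
    )
    return {
        "sensitivity_recall": sens,
        "specificity": frac(tn, tn + fp),
        "precision_ppv": prec,
        "npv": frac(tn, tn + fn),
        "f1": f1,
    }
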