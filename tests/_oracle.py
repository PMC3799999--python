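"""Independent brute-force oracles used to cross-check the engine.

The regimen oracle walks the episode day by day over explicit
drug-validity day sets, applying the 30-day lock, interim-combination,
validity-expiry and 30-day blank rules directly; it shares no code with
the event-driven engine.
"""

from __future__ import annotations


def oracle_validity(fills, grace=60):
    """Day-set of validity for one drug's (day, supply) fills."""
    days: set[int] = set()
    cur_start = cur_end = None
    for f, d in sorted(fills):
        if cur_end is not None and f <= cur_end + grace:
            cur_end = max(cur_end, f + d)
        else:
            if cur_start is not None:
                days.update(range(cur_start, cur_end))
            cur_start, cur_end = f, f + d
    if cur_start is not None:
        days.update(range(cur_start, cur_end))
    return days


def oracle_segment(exposures, ep_start, ep_end, lock=30, blank_after=30):
    """Day-by-day regimen segmentation.

    ``exposures`` maps drug -> list of [start, end) validity intervals.
    Returns a list of (drug_frozenset, start, end, is_blank) tuples.
    """
    valid: dict[int, set[str]] = {}
    for drug, ivs in exposures.items():
        for s, e in ivs:
            for d in range(max(s, ep_start), min(e, ep_end)):
                valid.setdefault(d, set()).add(drug)
    if not valid:
        return [(frozenset(), ep_start, ep_end, True)]

    regs = []
    t = min(valid)
    while t < ep_end:
        comp: set[str] = set()
        for d in range(t, min(t + lock + 1, ep_end)):
            comp |= valid.get(d, set())
        comp_f = frozenset(comp)
        u = t + lock
        while True:
            if u >= ep_end:
                regs.append((comp_f, t, ep_end, False))
                t = ep_end
                break
            s = valid.get(u, set())
            if s == comp:
                u += 1
                continue
            if s:
                regs.append((comp_f, t, u, False))
                t = u
                break
            # nothing valid on day u: walk back to when validity expired
            v = u
            while v > t and (v - 1) not in valid:
                v -= 1
            f = None
            for w in range(u + 1, ep_end):
                if w in valid:
                    f = w
                    break
            if f is not None and f <= v + blank_after:
                regs.append((comp_f, t, f, False))
                t = f
                break
            reg_end = min(v + blank_after, ep_end)
            regs.append((comp_f, t, reg_end, False))
            if f is None:
                if reg_end < ep_end:
                    regs.append((frozenset(), reg_end, ep_end, True))
                t = ep_end
            else:
                regs.append((frozenset(), reg_end, f, True))
                t = f
            break
    return regs


def random_fill_case(rng):
    """A small random episode: <= 4 drugs, <= 8 fills, assorted supplies."""
    n_drugs = int(rng.integers(1, 5))
    drugs = [f"D{i}" for i in range(n_drugs)]
    n_fills = int(rng.integers(1, 9))
    ep_end = int(rng.integers(120, 400))
    fills = []
    for _ in range(n_fills):
        fills.append(
            (
                int(rng.integers(0, ep_end)),
                str(rng.choice(drugs)),
                int(rng.integers(1, 91)),
            )
        )
    return fills, 0, ep_end
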