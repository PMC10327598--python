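"""Brute-force day-calendar oracles, independent of the interval arithmetic
in the package: everything here works on explicit per-day arrays."""

from __future__ import annotations

from datetime import date, timedelta


def oracle_coverage_days(claims) -> set[int]:
    """Every exposed day (as ordinal) implied by a set of claims."""
    days: set[int] = set()
    for c in claims:
        start = c.dispense_date.toordinal()
        days.update(range(start, start + c.days_supplied))
    return days


def oracle_episodes(claims, grace_days: int) -> list[tuple[date, date]]:
    """Mark every covered day, bridge gaps <= grace_days, read off maximal runs.

    Returns half-open (start, end) date intervals.
    """
    days = oracle_coverage_days(claims)
    if not days:
        return []
    ordered = sorted(days)
    # contiguous covered blocks
    blocks: list[list[int]] = [[ordered[0], ordered[0] + 1]]
    for d in ordered[1:]:
        if d == blocks[-1][1]:
            blocks[-1][1] = d + 1
        else:
            blocks.append([d, d + 1])
    # bridge: gap measured from block end (half-open) to next block start
    merged = [blocks[0]]
    for start, end in blocks[1:]:
        if start - merged[-1][1] <= grace_days:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(date.fromordinal(a), date.fromordinal(b)) for a, b in merged]


def oracle_daily_sets(episodes) -> dict[int, frozenset]:
    """Active class set per exposed day ordinal, from episode intervals."""
    out: dict[int, set] = {}
    for e in episodes:
        for d in range(e.start.toordinal(), e.end.toordinal()):
            out.setdefault(d, set()).add(e.drug_class)
    return {d: frozenset(s) for d, s in out.items()}


def oracle_patterns(episodes, min_days: int) -> list[tuple[frozenset, date, date]]:
    """Day-by-day pattern extraction: runs of constant class set within each
    contiguous exposed block; sub-threshold runs dropped, adjacent identical
    survivors merged spanning the transient."""
    daily = oracle_daily_sets(episodes)
    if not daily:
        return []
    days = sorted(daily)
    # contiguous exposed blocks
    blocks: list[list[int]] = [[days[0]]]
    for d in days[1:]:
        if d == blocks[-1][-1] + 1:
            blocks[-1].append(d)
        else:
            blocks.append([d])
    patterns: list[tuple[frozenset, date, date]] = []
    for block in blocks:
        runs: list[list] = []  # [classes, start, end)
        for d in block:
            if runs and runs[-1][0] == daily[d] and runs[-1][2] == d:
                runs[-1][2] = d + 1
            else:
                runs.append([daily[d], d, d + 1])
        surviving = [r for r in runs if r[2] - r[1] >= min_days]
        merged: list[list] = []
        for r in surviving:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(list(r))
        patterns.extend(
            (frozenset(c), date.fromordinal(a), date.fromordinal(b)) for c, a, b in merged
        )
    return patterns


def oracle_km(durations, events, t: float) -> float:
    """Textbook product-limit S(t): ties are events first, then censorings."""
    s = 1.0
    for u in sorted({d for d, e in zip(durations, events) if e and d <= t}):
        n_at_risk = sum(1 for d in durations if d >= u)
        d_events = sum(1 for d, e in zip(durations, events) if e and d == u)
        s *= 1.0 - d_events / n_at_risk
    return s
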