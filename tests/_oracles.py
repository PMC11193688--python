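"""Independent oracles used by the test suite.

``brute_force_segment`` enumerates every monotone assignment of
administrations to lines (including same-day splits) and keeps those
satisfying the segmentation rules stated declaratively — combination
window on each agent's first administration, maximum intra-line gap, and
justified boundaries (either a gap longer than the threshold, or a new
agent arriving beyond the combination window).  It shares no code with the
production segmenter.

``product_limit`` is a from-scratch Kaplan–Meier estimator.
"""

from __future__ import annotations

from itertools import combinations


def _valid(lines: list[list[tuple[int, str]]], window: int, gap: int) -> bool:
    for line in lines:
        if not line:
            return False
        days = sorted({d for d, _ in line})
        start = days[0]
        firsts: dict[str, int] = {}
        for d, a in sorted(line):
            firsts.setdefault(a, d)
        if any(f - start > window for f in firsts.values()):
            return False
        if any(b - a > gap for a, b in zip(days, days[1:])):
            return False
    for prev, nxt in zip(lines, lines[1:]):
        e = max(d for d, _ in prev)
        s = min(d for d, _ in nxt)
        if s < e:
            return False
        if s - e <= gap:
            prev_agents = {a for _, a in prev}
            start_prev = min(d for d, _ in prev)
            if s - start_prev <= window:
                return False
            if any(a in prev_agents for d, a in nxt if d == s):
                return False
    return True


def brute_force_segment(
    admins: list[tuple[int, str]], window: int = 90, gap: int = 120
) -> list[list[tuple[int, int, frozenset]]]:
    """All valid segmentations of ``admins`` = [(day, agent), ...].

    Returns a list of candidate segmentations, each a list of
    (start_day, last_day, agent_set) tuples; the rules should admit exactly
    one.
    """
    if not admins:
        return [[]]
    by_day: dict[int, list[tuple[int, str]]] = {}
    for d, a in sorted(set(admins)):
        by_day.setdefault(d, []).append((d, a))
    groups = [by_day[d] for d in sorted(by_day)]

    solutions: list[list[tuple[int, int, frozenset]]] = []

    def recurse(i: int, lines: list[list[tuple[int, str]]]) -> None:
        if i == len(groups):
            if _valid(lines, window, gap):
                solutions.append(
                    [
                        (
                            min(d for d, _ in line),
                            max(d for d, _ in line),
                            frozenset(a for _, a in line),
                        )
                        for line in lines
                    ]
                )
            return
        items = groups[i]
        if lines:
            # whole group continues the open line
            lines[-1].extend(items)
            recurse(i + 1, lines)
            del lines[-1][-len(items):]
            # group splits: part stays, part opens the next line
            for k in range(1, len(items)):
                for new_part in combinations(items, k):
                    stay = [x for x in items if x not in new_part]
                    lines[-1].extend(stay)
                    lines.append(list(new_part))
                    recurse(i + 1, lines)
                    lines.pop()
                    del lines[-1][-len(stay):]
        # whole group opens a new line
        lines.append(list(items))
        recurse(i + 1, lines)
        lines.pop()

    recurse(0, [])
    return solutions


def product_limit(
    observations: list[tuple[float, bool]],
) -> tuple[list[tuple[float, float]], float]:
    """From-scratch product-limit estimate.

    Returns ([(event_time, survival_just_after)], median) with median =
    inf when survival never drops to 0.5 or below.
    """
    times = [t for t, _ in observations]
    s = 1.0
    curve = []
    median = float("inf")
    for t in sorted({t for t, e in observations if e}):
        n_risk = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in observations if e and x == t)
        s *= 1.0 - d / n_risk
        curve.append((t, s))
        if median == float("inf") and s <= 0.5:
            median = t
    return curve, median
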