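"""Per-group majority-state summaries of significant windows.

An informative window is summarized by the majority chromatin state within
each sample group (e.g. "transcription in brain / heterochromatin in
others"), and the distribution of these change patterns across all detected
windows describes which epigenetic transitions dominate a dataset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mi import SampleClassification
from .windowing import Window, WindowProfile

__all__ = ["PatternSummary", "pattern_distribution", "group_majority",
           "distribution_to_frame"]

UNDEFINED = "undefined"


@dataclass(frozen=True)
class PatternSummary:
    """Majority state per group for one window."""

    window: Window
    group_state: Mapping[str, str]

    def key(self, group_order: Sequence[str]) -> tuple[str, ...]:
        return tuple(self.group_state[g] for g in group_order)

    def fully_defined(self, group_order: Sequence[str]) -> bool:
        return all(s != UNDEFINED for s in self.key(group_order))


def group_majority(profile: WindowProfile,
                   classification: SampleClassification) -> PatternSummary:
    """Most frequent non-undefined state among each group's samples.

    A group with no defined sample, or whose top two states tie, is recorded
    as undefined; sample order within a group never matters.
    """
    by_group: dict[str, Counter] = {g: Counter() for g in classification.groups}
    for sample, state in zip(profile.samples, profile.states):
        if state != UNDEFINED:
            by_group[classification.assignment[sample]][state] += 1
    summary: dict[str, str] = {}
    for g, counts in by_group.items():
        if not counts:
            summary[g] = UNDEFINED
            continue
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            summary[g] = UNDEFINED
        else:
            summary[g] = ranked[0][0]
    return PatternSummary(profile.window, summary)


def pattern_distribution(
    summaries: Iterable[PatternSummary],
    group_order: Sequence[str],
) -> tuple[dict[tuple[str, ...], float], dict[tuple[str, ...], int]]:
    """Proportion of windows per ordered change pattern.

    Windows with any undefined group entry are dropped from both numerator
    and denominator. Returns (proportions, counts), both ordered by
    descending proportion.
    """
    counts: Counter = Counter()
    for s in summaries:
        if s.fully_defined(group_order):
            counts[s.key(group_order)] += 1
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    props = {k: c / total for k, c in ordered} if total else {}
    return props, dict(ordered)


def distribution_to_frame(
    proportions: Mapping[tuple[str, ...], float],
    counts: Mapping[tuple[str, ...], int],
    group_order: Sequence[str],
) -> pd.DataFrame:
    rows = [
        {**{g: k[i] for i, g in enumerate(group_order)},
         "count": counts[k], "proportion": p}
        for k, p in proportions.items()
    ]
    return pd.DataFrame(rows, columns=[*group_order, "count", "proportion"])
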