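"""Genome windowing and the majority-state collapse.

The scan slides a window of fixed length along each chromosome (default:
consecutive non-overlapping 5 kb windows). Within a window, one sample's
segmentation is collapsed to a single state: the state covering the largest
number of bases, provided it reaches a minimum fraction (default 80%) of the
covered bases; otherwise the window is ``undefined`` for that sample.

Frequencies are base-pair weighted, so inputs need not sit on the 200 bp
ChromHMM grid; on grid-aligned input, bp weighting and segment counting give
identical answers. If less than the minimum fraction of the window is covered
by any interval at all, the window is undefined (assembly-gap rule); ties for
the top state are undefined as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np

from .state_io import GenomeLayout, StateTrack, StateVocabulary

__all__ = ["Window", "WindowingParams", "WindowProfile", "make_windows",
           "window_state", "build_profile"]


@dataclass(frozen=True, order=True)
class Window:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class WindowingParams:
    """Window length/step in bp and the majority threshold (default 80%)."""

    window_length: int = 5000
    step: int = 5000
    min_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.window_length < 200:
            raise ValueError("window_length must be >= 200 bp")
        if self.step < 1:
            raise ValueError("step must be >= 1 bp")
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")


@dataclass(frozen=True)
class WindowProfile:
    """Per-sample collapsed states of one window (the epigenetic profile S_i)."""

    window: Window
    samples: tuple[str, ...]
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.states):
            raise ValueError("profile: one state per sample required")

    def __len__(self) -> int:
        return len(self.states)


def make_windows(layout: GenomeLayout, params: WindowingParams) -> Iterator[Window]:
    """Enumerate windows chromosome by chromosome at starts 0, step, 2*step, ...

    Trailing windows that would extend past the chromosome end are dropped, so
    every emitted window has exactly ``params.window_length`` bases.
    """
    for chrom in layout.chromosomes:
        length = layout[chrom]
        for start in range(0, length - params.window_length + 1, params.step):
            yield Window(chrom, start, start + params.window_length)


def _coverage_by_state(
    track: StateTrack, window: Window
) -> np.ndarray:
    """bp of overlap of each vocabulary state with the window."""
    starts, ends, codes = track.chrom_arrays(window.chrom)
    m = len(track.vocabulary)
    if len(starts) == 0:
        return np.zeros(m)
    i = int(np.searchsorted(ends, window.start, side="right"))
    j = int(np.searchsorted(starts, window.end, side="left"))
    if i >= j:
        return np.zeros(m)
    ov = np.minimum(ends[i:j], window.end) - np.maximum(starts[i:j], window.start)
    return np.bincount(codes[i:j], weights=ov, minlength=m)


def window_state(track: StateTrack, window: Window, params: WindowingParams) -> str:
    """Collapse one sample's segmentation inside a window to a single state.

    Returns the maximal-coverage state when its share of the covered bases is
    at least ``min_fraction``; otherwise the vocabulary's undefined label.
    Undefined is also returned when total coverage is below ``min_fraction``
    of the window length, or when the top two states tie exactly.
    """
    vocab = track.vocabulary
    cover = _coverage_by_state(track, window)
    total = cover.sum()
    if total < params.min_fraction * window.length:
        return vocab.undefined
    top_code = int(np.argmax(cover))
    top = cover[top_code]
    if int((cover == top).sum()) > 1:  # tied winners
        return vocab.undefined
    if top / total >= params.min_fraction:
        return vocab.states[top_code]
    return vocab.undefined


def build_profile(
    tracks: Sequence[StateTrack] | Mapping[str, StateTrack],
    window: Window,
    params: WindowingParams,
    sample_order: Sequence[str],
) -> WindowProfile:
    """Collapse every sample's state for the window, in the given sample order."""
    if not isinstance(tracks, Mapping):
        tracks = {t.sample_id: t for t in tracks}
    missing = [s for s in sample_order if s not in tracks]
    if missing:
        raise KeyError(f"no track for sample(s): {', '.join(missing)}")
    states = tuple(window_state(tracks[s], window, params) for s in sample_order)
    return WindowProfile(window=window, samples=tuple(sample_order), states=states)
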