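"""Reading, writing and reducing chromatin-state segmentations.

A chromatin-state segmentation assigns every genomic segment of a sample a
discrete label from a fixed vocabulary (e.g. the 15 Roadmap Epigenomics
"mnemonics" produced by ChromHMM: ``TssA``, ``Tx``, ``Enh``, ``Quies`` ...).
Segmentations travel as 4-column BED files (chrom, start, end, state), with
0-based half-open coordinates throughout this package.

Vocabularies can be *reduced* by a total surjection onto a coarser label set
(e.g. 15 states down to 5, or down to a binary active/inactive scheme); the
default reduction tables ship with the package as editable text files under
``episcan/data/``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "StateVocabulary",
    "StateReduction",
    "StateTrack",
    "GenomeLayout",
    "ROADMAP_15",
    "builtin_vocabulary",
    "builtin_reduction",
    "load_vocabulary",
    "load_reduction",
    "read_state_bed",
    "write_state_bed",
    "reduce_track",
    "read_chrom_sizes",
]

DEFAULT_UNDEFINED = "undefined"

#: The 15 consolidated-epigenome ChromHMM mnemonics (Roadmap core model).
ROADMAP_15 = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)


class StateIOError(ValueError):
    """Raised for malformed segmentation, vocabulary or reduction input."""


@dataclass(frozen=True)
class StateVocabulary:
    """An ordered set of chromatin-state labels.

    ``undefined`` is the reserved label assigned to windows where no state
    reaches the majority threshold; it is never a member of ``states``.
    """

    name: str
    states: tuple[str, ...]
    undefined: str = DEFAULT_UNDEFINED

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(set(self.states)) != len(self.states):
            raise StateIOError(f"vocabulary {self.name!r}: duplicate state labels")
        if any(not s for s in self.states):
            raise StateIOError(f"vocabulary {self.name!r}: empty state label")
        if self.undefined in self.states:
            raise StateIOError(
                f"vocabulary {self.name!r}: reserved undefined label "
                f"{self.undefined!r} collides with a state"
            )

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, label: str) -> bool:
        return label in self.states

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise StateIOError(
                f"unknown state {label!r} for vocabulary {self.name!r}"
            ) from None

    @property
    def codes(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}


@dataclass(frozen=True)
class StateReduction:
    """A total map from a source vocabulary onto a coarser target vocabulary."""

    source_vocab: StateVocabulary
    target_vocab: StateVocabulary
    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.source_vocab.states if s not in self.mapping]
        if missing:
            raise StateIOError(f"reduction: uncovered states: {', '.join(missing)}")
        extra = [s for s in self.mapping if s not in self.source_vocab]
        if extra:
            raise StateIOError(
                f"reduction: mapped states not in source vocabulary: {', '.join(extra)}"
            )
        bad = [t for t in self.mapping.values() if t not in self.target_vocab]
        if bad:
            raise StateIOError(
                f"reduction: targets not in target vocabulary: {', '.join(sorted(set(bad)))}"
            )
        object.__setattr__(self, "mapping", dict(self.mapping))

    def code_table(self) -> np.ndarray:
        """Source-state code -> target-state code lookup array."""
        tgt = self.target_vocab.codes
        return np.array(
            [tgt[self.mapping[s]] for s in self.source_vocab.states], dtype=np.int16
        )


@dataclass
class StateTrack:
    """One sample's chromatin-state segmentation.

    Intervals are held per chromosome as parallel numpy arrays
    (start, end, state code), sorted and non-overlapping. Adjacent intervals
    sharing a state are kept as given — never merged.
    """

    sample_id: str
    vocabulary: StateVocabulary
    _chroms: list[str] = field(default_factory=list)
    _data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_intervals(
        cls,
        sample_id: str,
        vocabulary: StateVocabulary,
        intervals: Iterable[tuple[str, int, int, str]],
    ) -> "StateTrack":
        by_chrom: dict[str, list[tuple[int, int, int]]] = {}
        chroms: list[str] = []
        codes = vocabulary.codes
        for lineno, (chrom, start, end, state) in enumerate(intervals, start=1):
            if state not in codes:
                raise StateIOError(
                    f"unknown state {state!r} at interval {lineno} (sample {sample_id})"
                )
            if not (0 <= start < end):
                raise StateIOError(
                    f"malformed coordinates {chrom}:{start}-{end} at interval {lineno}"
                )
            if chrom not in by_chrom:
                by_chrom[chrom] = []
                chroms.append(chrom)
            by_chrom[chrom].append((int(start), int(end), codes[state]))
        track = cls(sample_id=sample_id, vocabulary=vocabulary)
        for chrom in chroms:
            rows = sorted(by_chrom[chrom])
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            st = np.array([r[2] for r in rows], dtype=np.int16)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise StateIOError(
                    f"overlapping intervals on {chrom} near position {starts[i + 1]} "
                    f"(sample {sample_id})"
                )
            track._chroms.append(chrom)
            track._data[chrom] = (starts, ends, st)
        return track

    @classmethod
    def from_arrays(
        cls,
        sample_id: str,
        vocabulary: StateVocabulary,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> "StateTrack":
        """Trusted constructor from per-chromosome (starts, ends, codes) arrays."""
        track = cls(sample_id=sample_id, vocabulary=vocabulary)
        for chrom, (starts, ends, codes) in data.items():
            track._chroms.append(chrom)
            track._data[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
                np.asarray(codes, dtype=np.int16),
            )
        return track

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._chroms)

    @property
    def n_intervals(self) -> int:
        return sum(len(d[0]) for d in self._data.values())

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = (
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int16),
        )
        return self._data.get(chrom, empty)

    def intervals(self) -> Iterator[tuple[str, int, int, str]]:
        states = self.vocabulary.states
        for chrom in self._chroms:
            starts, ends, codes = self._data[chrom]
            for s, e, c in zip(starts, ends, codes):
                yield chrom, int(s), int(e), states[c]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths of the (toy or real) genome scanned."""

    lengths: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lengths.values()):
            raise StateIOError("chromosome lengths must be positive")
        object.__setattr__(self, "lengths", dict(self.lengths))

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.lengths)

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]


# ---------------------------------------------------------------------------
# file input / output
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_state_bed(
    path: str | Path,
    vocab: StateVocabulary,
    sample_id: str | None = None,
) -> StateTrack:
    """Parse a mnemonics BED (chrom, start, end, state; tab-separated, no header).

    Gzip-compressed input (``*.gz``) is accepted. Rows are validated against
    *vocab*; unknown labels, malformed coordinates and overlapping intervals
    raise :class:`StateIOError` naming the offending line.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.split(".")[0]
    rows: list[tuple[str, int, int, str]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise StateIOError(f"{path.name}:{lineno}: expected >= 4 tab-separated columns")
            chrom, s, e, state = parts[0], parts[1], parts[2], parts[3]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise StateIOError(
                    f"{path.name}:{lineno}: malformed coordinates {s!r}, {e!r}"
                ) from None
            if state not in vocab:
                raise StateIOError(f"{path.name}:{lineno}: unknown state {state!r}")
            if not (0 <= start < end):
                raise StateIOError(f"{path.name}:{lineno}: require 0 <= start < end")
            rows.append((chrom, start, end, state))
    return StateTrack.from_intervals(sample_id, vocab, rows)


def write_state_bed(track: StateTrack, path: str | Path) -> None:
    """Write a track back out as a 4-column mnemonics BED."""
    with open(path, "wt") as fh:
        for chrom, start, end, state in track.intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{state}\n")


def reduce_track(track: StateTrack, reduction: StateReduction) -> StateTrack:
    """Relabel every interval through the reduction map; coordinates unchanged."""
    if track.vocabulary.states != reduction.source_vocab.states:
        unknown = [s for s in track.vocabulary.states if s not in reduction.source_vocab]
        if unknown:
            raise StateIOError(
                f"track states not covered by reduction source: {', '.join(unknown)}"
            )
    table = reduction.code_table()
    # track codes index the track's own vocabulary; translate through labels
    # in case track vocab ordering differs from reduction source ordering
    src_codes = reduction.source_vocab.codes
    relabel = np.array(
        [table[src_codes[s]] for s in track.vocabulary.states], dtype=np.int16
    )
    data = {
        chrom: (starts, ends, relabel[codes])
        for chrom, (starts, ends, codes) in track._data.items()
    }
    return StateTrack.from_arrays(track.sample_id, reduction.target_vocab, data)


def load_vocabulary(
    path: str | Path, name: str | None = None, undefined: str = DEFAULT_UNDEFINED
) -> StateVocabulary:
    """Read a vocabulary: one state label per line (blank/# lines ignored)."""
    path = Path(path)
    states = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                states.append(line.split("\t")[0])
    return StateVocabulary(name or path.stem, tuple(states), undefined)


def load_reduction(
    path: str | Path,
    source_vocab: StateVocabulary,
    target_vocab: StateVocabulary | None = None,
    target_name: str | None = None,
) -> StateReduction:
    """Read a two-column ``source<TAB>target`` reduction table.

    The mapping must cover every state of *source_vocab* exactly once. If
    *target_vocab* is omitted it is built from the distinct targets in order
    of first appearance.
    """
    path = Path(path)
    mapping: dict[str, str] = {}
    order: list[str] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise StateIOError(f"{path.name}:{lineno}: expected two tab-separated columns")
            src, tgt = parts[0], parts[1]
            if src in mapping and mapping[src] != tgt:
                raise StateIOError(
                    f"{path.name}:{lineno}: conflicting targets for source state {src!r}"
                )
            mapping[src] = tgt
            if tgt not in order:
                order.append(tgt)
    if target_vocab is None:
        target_vocab = StateVocabulary(
            target_name or f"{path.stem}_targets", tuple(order), source_vocab.undefined
        )
    return StateReduction(source_vocab, target_vocab, mapping)


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    """Read a UCSC-style ``name<TAB>length`` chrom.sizes file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": np.int64}, comment="#")
    if df["chrom"].duplicated().any():
        raise StateIOError("duplicate chromosome names in chrom.sizes")
    return GenomeLayout(dict(zip(df["chrom"], df["length"])))


# ---------------------------------------------------------------------------
# packaged defaults (15-state Roadmap vocabulary and its 5/2-state reductions)
# ---------------------------------------------------------------------------

def _data_path(fname: str):
    return resources.files("episcan").joinpath("data", fname)


def builtin_vocabulary(n_states: int = 15) -> StateVocabulary:
    """The shipped 15-, 5- or 2-state vocabulary."""
    fname = {15: "vocab_15.txt", 5: "vocab_5.txt", 2: "vocab_2.txt"}[n_states]
    with resources.as_file(_data_path(fname)) as p:
        return load_vocabulary(p, name=f"states_{n_states}")


def builtin_reduction(n_target: int) -> StateReduction:
    """The shipped 15->5 or 15->2 reduction (editable approximations)."""
    fname = {5: "reduce_15to5.tsv", 2: "reduce_15to2.tsv"}[n_target]
    with resources.as_file(_data_path(fname)) as p:
        return load_reduction(p, builtin_vocabulary(15), builtin_vocabulary(n_target))
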