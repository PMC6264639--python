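"""Synthetic multi-sample chromatin-state datasets with planted signal.

The generator emulates a set of ChromHMM-style segmentations on a toy
genome: background segments are drawn independently per sample and segment
from a configurable state distribution, while *planted* windows receive a
group-correlated state — each sample of group g gets its group's target
state with probability equal to the association ``strength``, otherwise a
random other state. A configurable ``undefined_rate`` instead fills a
sample's planted window with an alternating 50/50 mix of two states,
guaranteeing the window collapses to undefined for that sample under the
80% majority rule. Ground truth is returned alongside the tracks so
detection performance can be scored exactly.

A matching toy gene annotation and gene->GO table can also be generated
(one gene per planted window plus background genes, and one "positive" term
collecting the planted genes) so the annotation, enrichment and
downsampling stages run end-to-end with known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneAnnotation, TermAnnotation
from .mi import SampleClassification, WindowResult
from .state_io import GenomeLayout, StateTrack, StateVocabulary
from .windowing import Window

__all__ = ["PlantedWindow", "SyntheticSpec", "generate", "generate_annotation",
           "truth_eval", "default_spec"]


@dataclass(frozen=True)
class PlantedWindow:
    window: Window
    group_states: Mapping[str, str]  # group label -> target state
    strength: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("strength must be in [0, 1]")
        object.__setattr__(self, "group_states", dict(self.group_states))


@dataclass(frozen=True)
class SyntheticSpec:
    layout: GenomeLayout
    vocabulary: StateVocabulary
    samples_per_group: Mapping[str, int]          # >= 2 groups
    planted: tuple[PlantedWindow, ...] = ()
    background_probs: Mapping[str, float] | None = None  # default: uniform
    segment_length: int = 200
    undefined_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples_per_group", dict(self.samples_per_group))
        object.__setattr__(self, "planted", tuple(self.planted))
        if len(self.samples_per_group) < 2:
            raise ValueError("need at least 2 groups")
        if any(n < 1 for n in self.samples_per_group.values()):
            raise ValueError("each group needs at least one sample")
        if not (0.0 <= self.undefined_rate <= 1.0):
            raise ValueError("undefined_rate must be in [0, 1]")
        if self.segment_length < 1:
            raise ValueError("segment_length must be positive")
        probs = self.background_probs
        if probs is not None:
            object.__setattr__(self, "background_probs", dict(probs))
            if set(probs) - set(self.vocabulary.states):
                raise ValueError("background_probs keys must be vocabulary states")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("background_probs must sum to 1")
        for p in self.planted:
            if p.window.chrom not in self.layout.chromosomes:
                raise ValueError(f"planted window {p.window} outside layout")
            if p.window.end > self.layout[p.window.chrom]:
                raise ValueError(f"planted window {p.window} beyond chromosome end")
            if p.window.start % self.segment_length or p.window.end % self.segment_length:
                raise ValueError(
                    f"planted window {p.window} must align to the segment grid")
            for g in self.samples_per_group:
                if g not in p.group_states:
                    raise ValueError(f"planted window {p.window}: no target for group {g!r}")
                if p.group_states[g] not in self.vocabulary:
                    raise ValueError(
                        f"planted window {p.window}: unknown target state "
                        f"{p.group_states[g]!r}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(
            f"{g}_{i + 1:02d}"
            for g in self.samples_per_group
            for i in range(self.samples_per_group[g])
        )

    def classification(self) -> SampleClassification:
        return SampleClassification({
            f"{g}_{i + 1:02d}": g
            for g in self.samples_per_group
            for i in range(self.samples_per_group[g])
        })

    def _prob_vector(self) -> np.ndarray:
        m = len(self.vocabulary)
        if self.background_probs is None:
            return np.full(m, 1.0 / m)
        return np.array([self.background_probs.get(s, 0.0)
                         for s in self.vocabulary.states])


def generate(spec: SyntheticSpec) -> tuple[list[StateTrack], pd.DataFrame]:
    """Draw the tracks and return them with the planted-truth table.

    Deterministic given ``spec.seed``. Tracks are emitted one 200 bp-style
    segment per interval (no merging), exactly as mnemonic BEDs arrive.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed & 0x7FFFFFFF]))
    vocab = spec.vocabulary
    m = len(vocab)
    probs = spec._prob_vector()
    seg = spec.segment_length
    classification = spec.classification()

    tracks: list[StateTrack] = []
    for sample in spec.sample_ids:
        group = classification.assignment[sample]
        data = {}
        for chrom in spec.layout.chromosomes:
            n_seg = spec.layout[chrom] // seg
            codes = rng.choice(m, size=n_seg, p=probs).astype(np.int16)
            for planted in spec.planted:
                if planted.window.chrom != chrom:
                    continue
                lo, hi = planted.window.start // seg, planted.window.end // seg
                u = rng.random()
                if u < spec.undefined_rate:
                    # alternate two states -> 50/50 mix, majority rule fails
                    a, b = rng.choice(m, size=2, replace=False)
                    fill = np.where(np.arange(hi - lo) % 2 == 0, a, b)
                elif rng.random() < planted.strength:
                    fill = vocab.index(planted.group_states[group])
                else:
                    target = vocab.index(planted.group_states[group])
                    others = [c for c in range(m) if c != target]
                    fill = int(rng.choice(others))
                codes[lo:hi] = fill
            starts = np.arange(n_seg, dtype=np.int64) * seg
            data[chrom] = (starts, starts + seg, codes)
        tracks.append(StateTrack.from_arrays(sample, vocab, data))

    truth = pd.DataFrame([
        {"chrom": p.window.chrom, "start": p.window.start, "end": p.window.end,
         "strength": p.strength,
         **{f"target:{g}": s for g, s in sorted(p.group_states.items())}}
        for p in spec.planted
    ])
    return tracks, truth


def generate_annotation(
    spec: SyntheticSpec,
    genes_per_chrom: int = 20,
    positive_term_name: str = "brain development",
    n_background_terms: int = 10,
) -> tuple[list[GeneAnnotation], list[TermAnnotation]]:
    """Toy gene + GO annotation matched to the spec's planted windows.

    One gene covers each planted window ("planted genes"); additional
    background genes are tiled evenly over each chromosome. A single
    positive term (name chosen to contain an evaluation keyword, e.g.
    "brain") collects exactly the planted genes; background terms take
    deterministic slices of the background genes.
    """
    genes: list[GeneAnnotation] = []
    planted_ids: list[str] = []
    for i, p in enumerate(spec.planted):
        gid = f"PLANT{i + 1:03d}"
        planted_ids.append(gid)
        genes.append(GeneAnnotation(gid, gid, p.window.chrom,
                                    p.window.start, p.window.end, "+"))
    planted_spans = {(p.window.chrom, p.window.start, p.window.end)
                     for p in spec.planted}
    k = 0
    for chrom in spec.layout.chromosomes:
        length = spec.layout[chrom]
        span = length // genes_per_chrom
        for j in range(genes_per_chrom):
            start = j * span
            end = min(start + max(span // 2, 1), length)
            # skip background genes that would sit on a planted window
            if any(c == chrom and start < pe and pa < end
                   for c, pa, pe in planted_spans):
                continue
            k += 1
            gid = f"BG{k:04d}"
            genes.append(GeneAnnotation(gid, gid, chrom, start, end,
                                        "+" if j % 2 == 0 else "-"))

    terms = [TermAnnotation("GO:9000001", positive_term_name, "BP",
                            set(planted_ids))]
    bg_ids = [g.gene_id for g in genes if g.gene_id.startswith("BG")]
    for t in range(n_background_terms):
        members = set(bg_ids[t::n_background_terms])
        if members:
            terms.append(TermAnnotation(f"GO:9100{t + 1:03d}",
                                        f"background process {t + 1}", "BP",
                                        members))
    return genes, terms


def truth_eval(
    significant: Sequence[WindowResult],
    truth: pd.DataFrame,
    all_results: Sequence[WindowResult] | None = None,
) -> dict[str, float]:
    """Score a scan against the planted truth.

    A planted window is recovered when it appears in the significant set;
    any surviving non-planted window is a false positive. When the full
    result list is supplied, specificity over background windows and the
    mean MI rank of planted windows are also reported.
    """
    planted = {(r.chrom, r.start, r.end) for r in truth.itertuples()} \
        if len(truth) else set()
    detected = {(r.window.chrom, r.window.start, r.window.end)
                for r in significant}
    tp = len(planted & detected)
    fp = len(detected - planted)
    out = {
        "n_planted": float(len(planted)),
        "n_detected": float(len(detected)),
        "true_positives": float(tp),
        "false_positives": float(fp),
        "sensitivity": tp / len(planted) if planted else float("nan"),
    }
    if all_results is not None:
        n_bg = sum(1 for r in all_results
                   if (r.window.chrom, r.window.start, r.window.end) not in planted)
        out["specificity"] = (n_bg - fp) / n_bg if n_bg else float("nan")
        by_mi = sorted(all_results, key=lambda r: -r.mi)
        ranks = [i + 1 for i, r in enumerate(by_mi)
                 if (r.window.chrom, r.window.start, r.window.end) in planted]
        out["mean_planted_rank"] = float(np.mean(ranks)) if ranks else float("nan")
    return out


def default_spec(
    seed: int = 0,
    vocabulary: StateVocabulary | None = None,
    n_planted: int = 10,
    strength: float = 1.0,
    undefined_rate: float = 0.0,
    samples_per_group: int = 10,
) -> SyntheticSpec:
    """The standard benchmark dataset: 2 chromosomes x 1 Mb, two groups of
    10 samples, 10 planted 5 kb windows (group A transcribed, group B
    heterochromatic), heterochromatin-dominated background distribution."""
    from .state_io import builtin_vocabulary

    vocab = vocabulary or builtin_vocabulary(5)
    layout = GenomeLayout({"chr1": 1_000_000, "chr2": 1_000_000})
    chroms = layout.chromosomes
    planted = []
    for i in range(n_planted):
        chrom = chroms[i % len(chroms)]
        # spread planted windows along the chromosome, on the 5 kb grid
        start = (10 + 17 * (i // len(chroms))) * 5000
        planted.append(PlantedWindow(
            Window(chrom, start, start + 5000),
            {"groupA": "transcription", "groupB": "heterochromatin"},
            strength=strength,
        ))
    background = None
    if vocab.states == ("tss", "transcription", "enhancer", "bivalent",
                        "heterochromatin"):
        # genomes are mostly quiescent/heterochromatic; keep the rest rare
        background = {"heterochromatin": 0.6, "transcription": 0.1,
                      "tss": 0.1, "enhancer": 0.1, "bivalent": 0.1}
    return SyntheticSpec(
        layout=layout,
        vocabulary=vocab,
        samples_per_group={"groupA": samples_per_group,
                           "groupB": samples_per_group},
        planted=tuple(planted),
        background_probs=background,
        undefined_rate=undefined_rate,
        seed=seed,
    )
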