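"""Downsampling robustness experiment.

How many epigenomes does the scan need? Increasing proportions of the input
samples are removed uniformly at random (default 20%-80%, five replicates
each), the full scan -> gene retrieval -> GO enrichment pipeline is rerun on
each reduced dataset, and performance is scored as the negative log10 of the
enrichment p-value of "positive" GO terms — terms whose names contain
keywords unambiguously tied to the classification (for a brain-vs-other
dataset: "brain", "neuron", "nerve", "axon", ...). A replicate that loses an
entire classification group yields no result and is excluded from the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import (EnrichmentResult, GeneAnnotation, TermAnnotation,
                       fisher_enrichment, overlap_genes)
from .mi import (MIParams, SampleClassification, WindowResult, filter_significant,
                 scan)
from .state_io import GenomeLayout, StateTrack
from .windowing import WindowingParams

__all__ = ["DownsampleSpec", "positive_terms", "downsample_performance",
           "run_enrichment_pipeline"]

DEFAULT_KEYWORDS = ("brain", "neuron", "nerve", "axon", "synap", "glia")


@dataclass(frozen=True)
class DownsampleSpec:
    fractions: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)
    replicates: int = 5
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "fractions", tuple(self.fractions))
        object.__setattr__(self, "keywords",
                           tuple(k.lower() for k in self.keywords))
        if any(not (0 < f < 1) for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def positive_terms(enrichment: Sequence[EnrichmentResult],
                   keywords: Sequence[str]) -> list[EnrichmentResult]:
    """Enrichment results whose term name contains any keyword
    (case-insensitive substring match)."""
    kws = [k.lower() for k in keywords]
    return [r for r in enrichment if any(k in r.term_name.lower() for k in kws)]


def run_enrichment_pipeline(
    tracks: Mapping[str, StateTrack] | Sequence[StateTrack],
    classification: SampleClassification,
    layout: GenomeLayout,
    genes: Sequence[GeneAnnotation],
    terms: Sequence[TermAnnotation],
    windowing_params: WindowingParams | None = None,
    mi_params: MIParams | None = None,
    min_term_size: int = 1,
) -> tuple[list[WindowResult], list[EnrichmentResult]]:
    """Scan, keep significant windows, retrieve genes, test enrichment."""
    results = scan(tracks, classification, layout, windowing_params, mi_params)
    significant = filter_significant(results, mi_params)
    overlap = overlap_genes([r.window for r in significant], genes)
    background = {g.gene_id for g in genes}
    enrichment = fisher_enrichment(overlap.gene_ids, background, terms,
                                   min_term_size=min_term_size)
    return significant, enrichment


def _performance(enrichment: Sequence[EnrichmentResult],
                 keywords: Sequence[str]) -> tuple[float, float]:
    """(mean, best) of -log10 p_fisher over keyword-matched positive terms.

    Zero when no positive term was matched: with no informative windows the
    study set is empty and every term's p is 1, so 0 is the natural floor.
    """
    matched = positive_terms(enrichment, keywords)
    if not matched:
        return 0.0, 0.0
    scores = [-np.log10(max(r.p_fisher, 1e-300)) for r in matched]
    return float(np.mean(scores)), float(np.max(scores))


def downsample_performance(
    tracks: Mapping[str, StateTrack] | Sequence[StateTrack],
    classification: SampleClassification,
    layout: GenomeLayout,
    genes: Sequence[GeneAnnotation],
    terms: Sequence[TermAnnotation],
    spec: DownsampleSpec | None = None,
    windowing_params: WindowingParams | None = None,
    mi_params: MIParams | None = None,
    min_term_size: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove each fraction of samples (uniformly, seeded), rerun the full
    pipeline, and tabulate performance.

    Returns ``(per_replicate, summary)``. ``per_replicate`` has one row per
    (fraction, replicate) with the mean and best positive-term performance;
    replicates where a whole group was removed carry NaN and are excluded
    from the summary means. Identical seeds reproduce identical tables.
    """
    spec = spec or DownsampleSpec()
    if not isinstance(tracks, Mapping):
        tracks = {t.sample_id: t for t in tracks}
    samples = [s for s in classification.samples if s in tracks]
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed & 0x7FFFFFFF, 0x0D5]))

    rows = []
    for frac in spec.fractions:
        n_remove = int(round(frac * len(samples)))
        for rep in range(spec.replicates):
            removed = set(rng.choice(samples, size=n_remove, replace=False))
            kept = [s for s in samples if s not in removed]
            kept_groups = {classification.assignment[s] for s in kept}
            if kept_groups != set(classification.groups):
                rows.append({"fraction": frac, "replicate": rep,
                             "n_samples": len(kept),
                             "performance": np.nan, "best_term": np.nan,
                             "n_significant": 0, "note": "group removed"})
                continue
            sub_cls = classification.subset(kept)
            sub_tracks = {s: tracks[s] for s in kept}
            significant, enrichment = run_enrichment_pipeline(
                sub_tracks, sub_cls, layout, genes, terms,
                windowing_params, mi_params, min_term_size)
            mean_perf, best_perf = _performance(enrichment, spec.keywords)
            rows.append({"fraction": frac, "replicate": rep,
                         "n_samples": len(kept),
                         "performance": mean_perf, "best_term": best_perf,
                         "n_significant": len(significant), "note": ""})
    per_replicate = pd.DataFrame(rows)
    summary = (per_replicate
               .groupby("fraction", as_index=False)
               .agg(mean_performance=("performance", "mean"),
                    mean_best_term=("best_term", "mean"),
                    n_defined_replicates=("performance",
                                          lambda s: int(s.notna().sum()))))
    return per_replicate, summary
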