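"""Mutual-information scan engine: statistic, permutation null, FDR, scan.

For every genome window, the per-sample collapsed chromatin states (profile
``S_i``) are compared with the user-supplied grouping of the samples (``G``,
e.g. cancer vs. healthy) through their mutual information

    MI(G : S_i) = sum_k sum_l P(G_k, S_il) * log2( P(G_k, S_il)
                                                   / (P(G_k) * P(S_il)) )

in bits. Samples whose window state is undefined are dropped *before* any
frequency is computed, so the group marginal P(G_k) is window-specific;
zero-probability terms are skipped. Significance comes from a permutation
null: the profile vector — including its undefined entries, so its
composition is preserved — is shuffled against the fixed classification
(10,000 times by default) and the empirical p-value is the fraction of
shuffles with MI greater than or equal to the observed score (it can be
exactly 0). Benjamini–Hochberg FDR correction is applied genome-wide across
all scanned windows; windows are deemed informative when MI >= 0.3 and
adjusted p <= 1e-4 (the defaults used throughout).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .state_io import GenomeLayout, StateTrack
from .windowing import Window, WindowProfile, WindowingParams, build_profile, make_windows

__all__ = [
    "SampleClassification",
    "MIParams",
    "WindowResult",
    "mutual_information",
    "permutation_pvalue",
    "bh_adjust",
    "scan",
    "filter_significant",
    "results_to_frame",
]

_UNDEF_CODE = -1
_EPS = 1e-12  # float guard for >= comparisons of permuted vs observed MI


@dataclass(frozen=True)
class SampleClassification:
    """Sample ID -> group label map (the classification vector G)."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))
        if len(self.groups) < 2:
            raise ValueError("classification needs at least 2 distinct groups")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.assignment.values())))

    def group_codes(self, sample_order: Sequence[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.groups)}
        try:
            return np.array([idx[self.assignment[s]] for s in sample_order],
                            dtype=np.int64)
        except KeyError as e:
            raise KeyError(f"sample {e.args[0]!r} has no group assignment") from None

    def subset(self, samples: Iterable[str]) -> "SampleClassification":
        return SampleClassification({s: self.assignment[s] for s in samples})

    @classmethod
    def from_file(cls, path) -> "SampleClassification":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["sample", "group"], dtype=str)
        return cls(dict(zip(df["sample"], df["group"])))


@dataclass(frozen=True)
class MIParams:
    """Permutation-test and significance-filter settings.

    ``pseudocount=False`` gives the plain r/n empirical p-value (which can be
    exactly 0); ``True`` switches to the conservative (r+1)/(n+1) convention.
    """

    n_permutations: int = 10_000
    seed: int = 0
    mi_threshold: float = 0.3
    fdr_threshold: float = 1e-4
    pseudocount: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.mi_threshold < 0:
            raise ValueError("mi_threshold must be >= 0")
        if not (0 < self.fdr_threshold <= 1):
            raise ValueError("fdr_threshold must be in (0, 1]")


@dataclass
class WindowResult:
    """Scan output for one window."""

    window: Window
    mi: float
    p_raw: float
    p_adj: float
    n_defined: int
    n_states_observed: int
    states: tuple[str, ...] = field(default=(), repr=False)
    all_undefined: bool = False


# ---------------------------------------------------------------------------
# encoding and the MI statistic
# ---------------------------------------------------------------------------

def _encode_profile(profile: WindowProfile) -> np.ndarray:
    """State labels -> integer codes; undefined -> -1. Codes are local to the
    profile (order of first appearance), which leaves MI unchanged."""
    seen: dict[str, int] = {}
    out = np.empty(len(profile), dtype=np.int64)
    for i, s in enumerate(profile.states):
        if s == "undefined" or s is None:
            out[i] = _UNDEF_CODE
        else:
            out[i] = seen.setdefault(s, len(seen))
    return out


def _mi_rows(counts: np.ndarray) -> np.ndarray:
    """MI in bits for a stack of joint count tables, shape (r, n, m)."""
    tot = counts.sum(axis=(1, 2), keepdims=True).astype(float)
    safe_tot = np.where(tot > 0, tot, 1.0)
    p = counts / safe_tot
    pg = p.sum(axis=2, keepdims=True)
    ps = p.sum(axis=1, keepdims=True)
    denom = pg * ps
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(np.where(p > 0, p / np.where(denom > 0, denom, 1.0), 1.0))
    mi = np.where(terms != 0, terms, 0.0).sum(axis=(1, 2))
    return np.maximum(mi, 0.0)


def _joint_counts(group_codes: np.ndarray, state_codes: np.ndarray,
                  n_groups: int, n_states: int) -> np.ndarray:
    mask = state_codes != _UNDEF_CODE
    if n_states == 0 or not mask.any():
        return np.zeros((n_groups, max(n_states, 1)), dtype=np.int64)
    flat = group_codes[mask] * n_states + state_codes[mask]
    return np.bincount(flat, minlength=n_groups * n_states).reshape(n_groups, n_states)


def mutual_information(profile: WindowProfile,
                       classification: SampleClassification) -> float:
    """MI (bits) between the window profile and the sample classification.

    Undefined samples are excluded before all frequencies are computed.
    Returns 0.0 when fewer than two defined samples remain or when a marginal
    is degenerate (a single group or single state among the retained samples).
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    states = _encode_profile(profile)
    groups = classification.group_codes(profile.samples)
    mask = states != _UNDEF_CODE
    if mask.sum() < 2:
        return 0.0
    n_states = int(states.max()) + 1
    counts = _joint_counts(groups, states, len(classification.groups), n_states)
    return float(_mi_rows(counts[None, :, :])[0])


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def permutation_pvalue(
    profile: WindowProfile,
    classification: SampleClassification,
    params: MIParams,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Empirical p-value for a window's MI from a composition-preserving null.

    The full profile vector — undefined entries included — is shuffled
    ``n_permutations`` times against the fixed classification; each shuffle's
    MI re-applies the undefined-exclusion rule. Returns ``(p_raw, mi_obs)``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    states = _encode_profile(profile)
    groups = classification.group_codes(profile.samples)
    n = len(classification.groups)
    m = max(int(states.max()) + 1, 1)

    obs = mutual_information(profile, classification)

    r = params.n_permutations
    perm = np.tile(states, (r, 1))
    rng.permuted(perm, axis=1, out=perm)

    mask = perm != _UNDEF_CODE
    row_offset = (np.arange(r, dtype=np.int64) * (n * m))[:, None]
    flat = (groups[None, :] * m + perm + row_offset)[mask]
    counts = np.bincount(flat, minlength=r * n * m).reshape(r, n, m)
    null_mi = _mi_rows(counts)

    hits = int((null_mi >= obs - _EPS).sum())
    if params.pseudocount:
        p_raw = (hits + 1) / (r + 1)
    else:
        p_raw = hits / r
    return p_raw, obs


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the genome-wide scan
# ---------------------------------------------------------------------------

def _window_rng(seed: int, window: Window) -> np.random.Generator:
    """Per-window generator derived from (seed, chrom, start): results do not
    depend on window iteration order."""
    key = (int(seed) & 0x7FFFFFFF, zlib.crc32(window.chrom.encode()), window.start)
    return np.random.default_rng(np.random.SeedSequence(key))


def scan(
    tracks: Sequence[StateTrack] | Mapping[str, StateTrack],
    classification: SampleClassification,
    layout: GenomeLayout,
    windowing_params: WindowingParams | None = None,
    mi_params: MIParams | None = None,
    progress: bool = False,
) -> list[WindowResult]:
    """Run the full scan: profile -> MI -> permutation p per window, then BH
    across all scanned windows genome-wide.

    Windows in which every sample is undefined are kept (MI 0, raw p 1,
    ``all_undefined`` flag) so the multiple-testing family size is the full
    window count. The returned list follows genome order; use
    :func:`filter_significant` for the MI/FDR-filtered view.
    """
    windowing_params = windowing_params or WindowingParams()
    mi_params = mi_params or MIParams()
    if not isinstance(tracks, Mapping):
        tracks = {t.sample_id: t for t in tracks}
    sample_order = tuple(s for s in classification.samples if s in tracks)
    missing = set(classification.samples) - set(sample_order)
    if missing:
        raise KeyError(f"no track for sample(s): {', '.join(sorted(missing))}")

    results: list[WindowResult] = []
    for window in make_windows(layout, windowing_params):
        profile = build_profile(tracks, window, windowing_params, sample_order)
        undef = all(s == "undefined" for s in profile.states)
        n_defined = sum(s != "undefined" for s in profile.states)
        n_states = len({s for s in profile.states if s != "undefined"})
        if undef:
            results.append(WindowResult(window, 0.0, 1.0, np.nan, 0, 0,
                                        profile.states, all_undefined=True))
            continue
        rng = _window_rng(mi_params.seed, window)
        p_raw, mi = permutation_pvalue(profile, classification, mi_params, rng)
        results.append(WindowResult(window, mi, p_raw, np.nan, n_defined,
                                    n_states, profile.states))

    p_adj = bh_adjust([r.p_raw for r in results]) if results else np.empty(0)
    for r, q in zip(results, p_adj):
        r.p_adj = float(q)
    return results


def filter_significant(results: Iterable[WindowResult],
                       mi_params: MIParams | None = None) -> list[WindowResult]:
    """Windows passing both MI >= mi_threshold and adjusted p <= fdr_threshold,
    sorted by MI descending (ties broken by genome position)."""
    mi_params = mi_params or MIParams()
    keep = [r for r in results
            if r.mi >= mi_params.mi_threshold and r.p_adj <= mi_params.fdr_threshold]
    return sorted(keep, key=lambda r: (-r.mi, r.window.chrom, r.window.start))


def results_to_frame(results: Iterable[WindowResult],
                     sample_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Tabular view of scan results; per-sample states as one column each."""
    rows = []
    for r in results:
        row = {
            "chrom": r.window.chrom, "start": r.window.start, "end": r.window.end,
            "mi": r.mi, "p_raw": r.p_raw, "p_adj": r.p_adj,
            "n_defined": r.n_defined, "n_states_observed": r.n_states_observed,
            "all_undefined": r.all_undefined,
        }
        if sample_order and r.states:
            row.update({f"state:{s}": st for s, st in zip(sample_order, r.states)})
        rows.append(row)
    return pd.DataFrame(rows)
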