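"""Simulation replicates and sensitivity/specificity summaries.

One replicate simulates a deletion-free control and a deletion-carrying
mutant at the same coverage, runs the windowed ∆depth scan with an unpaired
resampled null, and scores calls against the implanted truth with the >=80%
fractional-overlap rule.  Across replicates the module reports mean ± SD
sensitivity and specificity under the q95 and q99 criteria, per-length-class
true-positive percentages, and the length distribution of false positives.

Definitions:

* sensitivity (per replicate) — detected truth deletions / all truth deletions;
* specificity (per replicate) — windows containing no truth-deletion base that
  lie outside every called region, over all such windows (window-level);
* TP% (per length class) — detected / introduced × 100, pooled over replicates;
* FP% (per length bin) — false-positive calls in the bin / all false positives
  × 100, binned by the call's own length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import deltadetect, simcov, windows
from .deltadetect import NullThresholds, RegionCall
from .simcov import SimLayout, TruthDeletion

__all__ = [
    "SimConfig",
    "ReplicateResult",
    "EvalSummary",
    "run_replicate",
    "run_replicates",
    "sensitivity_specificity",
    "tp_fp_length_distributions",
]

CRITERIA = ("q95", "q99")


@dataclass
class SimConfig:
    """Parameters of one simulation study."""

    n_chroms: int = 3
    chrom_length: int = 30_000_000
    coverage: float = 5.0
    read_length: int = simcov.BENCH_READ_LENGTH
    window_size: int = windows.BENCH_WINDOW
    step: int = windows.BENCH_STEP
    reps: int = 4000
    length_classes: tuple[int, ...] = simcov.DEFAULT_LENGTH_CLASSES
    n_per_class: int = 1
    repeat_fraction: float = 0.05
    min_fraction: float = 0.8
    normalize: bool = True

    def to_dict(self) -> dict:
        return {
            "n_chroms": self.n_chroms,
            "chrom_length": self.chrom_length,
            "coverage": self.coverage,
            "read_length": self.read_length,
            "window_size": self.window_size,
            "step": self.step,
            "reps": self.reps,
            "length_classes": list(self.length_classes),
            "n_per_class": self.n_per_class,
            "repeat_fraction": self.repeat_fraction,
            "min_fraction": self.min_fraction,
            "normalize": self.normalize,
        }


@dataclass
class ReplicateResult:
    """Truth, calls and per-criterion scoring for one simulation replicate."""

    seed: int
    truth: list[TruthDeletion]
    thresholds: NullThresholds
    calls: dict[str, list[RegionCall]]            # criterion -> calls
    detected: dict[str, list[bool]]               # criterion -> per-truth flags
    false_positives: dict[str, list[RegionCall]]  # criterion -> FP calls
    n_windows: int
    n_clean_windows: int
    clean_uncalled: dict[str, int]                # criterion -> clean windows not called

    def sensitivity(self, criterion: str) -> float:
        flags = self.detected[criterion]
        if not flags:
            raise ValueError("no truth deletions: sensitivity undefined")
        return sum(flags) / len(flags)

    def specificity(self, criterion: str) -> float:
        if self.n_clean_windows == 0:
            raise ValueError("no deletion-free windows: specificity undefined")
        return self.clean_uncalled[criterion] / self.n_clean_windows


@dataclass
class EvalSummary:
    """Mean ± SD sensitivity/specificity and TP%/FP% length distributions."""

    criterion: str
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    tp_pct_by_class: dict[int, float]
    fp_pct_by_bin: dict[str, float]
    n_replicates: int


def _window_cleanliness(
    tracks: Mapping[str, windows.WindowTrack],
    truth: Sequence[TruthDeletion],
) -> dict[str, np.ndarray]:
    """Per chromosome, boolean mask of windows containing no truth-deletion bp."""
    clean: dict[str, np.ndarray] = {}
    for chrom, track in tracks.items():
        mask = np.ones(track.n_windows, dtype=bool)
        ends = track.ends()
        for t in truth:
            if t.chrom == chrom:
                mask &= ~((track.starts < t.end) & (ends > t.start))
        clean[chrom] = mask
    return clean


def run_replicate(config: SimConfig, seed: int) -> ReplicateResult:
    """Simulate, scan and score one replicate; deterministic given ``seed``.

    The control sample is simulated deletion-free and the mutant carries the
    implanted deletions; both are windowed, per-sample mean-normalized (when
    configured), differenced, and thresholded under q95 and q99.
    """
    s_layout, s_truth, s_wt, s_mut, s_null = (
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(5)
    )
    layout = simcov.default_layout(
        s_layout,
        n_chroms=config.n_chroms,
        chrom_length=config.chrom_length,
        repeat_fraction=config.repeat_fraction,
    )
    truth = simcov.introduce_deletions(
        layout, config.length_classes, config.n_per_class, seed=s_truth
    )
    wt_profiles = simcov.simulate_depth(
        layout, (), config.coverage, config.read_length, seed=s_wt, sample_id="wt"
    )
    mut_profiles = simcov.simulate_depth(
        layout, truth, config.coverage, config.read_length, seed=s_mut,
        sample_id="mut",
    )

    wt_tracks = {
        c: windows.sliding_mean(p, config.window_size, config.step)
        for c, p in wt_profiles.items()
    }
    mut_tracks = {
        c: windows.sliding_mean(p, config.window_size, config.step)
        for c, p in mut_profiles.items()
    }
    if config.normalize:
        wt_tracks = windows.normalize_tracks(wt_tracks)
        mut_tracks = windows.normalize_tracks(mut_tracks)

    # Thresholds estimate the no-deletion null: windows overlapping implanted
    # deletions are excluded from the resampling pools (see resample_null).
    thresholds = deltadetect.resample_null(
        wt_tracks,
        mut_tracks,
        reps=config.reps,
        seed=s_null,
        exclude_intervals=[(t.chrom, t.start, t.end) for t in truth],
    )
    deltas = {
        c: deltadetect.delta_track(wt_tracks[c], mut_tracks[c]) for c in wt_tracks
    }

    clean = _window_cleanliness(wt_tracks, truth)
    n_windows = sum(t.n_windows for t in wt_tracks.values())
    n_clean = int(sum(m.sum() for m in clean.values()))

    calls: dict[str, list[RegionCall]] = {}
    detected: dict[str, list[bool]] = {}
    fps: dict[str, list[RegionCall]] = {}
    clean_uncalled: dict[str, int] = {}
    for criterion in CRITERIA:
        crit_calls: list[RegionCall] = []
        for chrom, delta in deltas.items():
            crit_calls.extend(
                deltadetect.call_exceedance_regions(delta, thresholds, criterion)
            )
        calls[criterion] = crit_calls
        detected[criterion], fps[criterion] = deltadetect.match_calls_to_truth(
            crit_calls, truth, config.min_fraction
        )
        # per-window specificity: a deletion-free window counts against
        # specificity iff its own ∆depth exceeded the threshold (equivalently,
        # its footprint lies inside a called region, since merged runs have
        # no interior non-exceeding windows)
        upper = thresholds.upper(criterion)
        uncalled = 0
        for chrom, delta in deltas.items():
            exceed = (delta.values > upper) & delta.full_width_mask()
            uncalled += int((clean[chrom] & ~exceed).sum())
        clean_uncalled[criterion] = uncalled

    return ReplicateResult(
        seed=seed,
        truth=truth,
        thresholds=thresholds,
        calls=calls,
        detected=detected,
        false_positives=fps,
        n_windows=n_windows,
        n_clean_windows=n_clean,
        clean_uncalled=clean_uncalled,
    )


def run_replicates(
    config: SimConfig, n_replicates: int, seed: int
) -> list[ReplicateResult]:
    """Run ``n_replicates`` independent replicates with child seeds of ``seed``."""
    children = np.random.SeedSequence(seed).spawn(n_replicates)
    return [
        run_replicate(config, int(c.generate_state(1)[0] % (2**31)))
        for c in children
    ]


def fp_length_bins(
    length_classes: Sequence[int] = simcov.DEFAULT_LENGTH_CLASSES,
    small_split: int = 1_000,
) -> tuple[tuple[str, int, float], ...]:
    """Length bins for false-positive calls: a small/large split plus class edges.

    ``small_split`` separates sub-threshold noise calls (the benchmark default
    of 1 kbp is the 20 kbp boundary of the full-scale design divided by the
    same 1/20 geometry factor).
    """
    edges = [0, small_split] + sorted(c for c in set(length_classes) if c > small_split)
    bins: list[tuple[str, int, float]] = []
    for lo, hi in zip(edges, edges[1:] + [float("inf")]):
        name = f"<{edges[1]}" if lo == 0 else (f">={lo}" if hi == float("inf") else f"{lo}-{hi}")
        bins.append((name, lo, hi))
    return tuple(bins)


DEFAULT_FP_BINS = fp_length_bins()


def tp_fp_length_distributions(
    results: Sequence[ReplicateResult],
    criterion: str = "q99",
    fp_bins: Sequence[tuple[str, int, float]] = DEFAULT_FP_BINS,
) -> tuple[dict[int, float], dict[str, float]]:
    """TP% per introduced length class and FP% per called-length bin.

    TP% = detected / introduced × 100 pooled over replicates for each class;
    FP% = calls in bin / total false positives × 100 (empty dict if no FPs).
    """
    introduced: dict[int, int] = {}
    detected_n: dict[int, int] = {}
    for res in results:
        for t, flag in zip(res.truth, res.detected[criterion]):
            introduced[t.length_class] = introduced.get(t.length_class, 0) + 1
            detected_n[t.length_class] = detected_n.get(t.length_class, 0) + int(flag)
    tp_pct = {
        cls: 100.0 * detected_n[cls] / n for cls, n in sorted(introduced.items())
    }

    fp_lengths = [
        call.length for res in results for call in res.false_positives[criterion]
    ]
    fp_pct: dict[str, float] = {}
    if fp_lengths:
        total = len(fp_lengths)
        for name, lo, hi in fp_bins:
            count = sum(1 for L in fp_lengths if lo <= L < hi)
            fp_pct[name] = 100.0 * count / total
    return tp_pct, fp_pct


def sensitivity_specificity(
    results: Sequence[ReplicateResult], criterion: str = "q99"
) -> EvalSummary:
    """Mean ± sample SD of sensitivity and specificity over replicates."""
    if len(results) < 2:
        raise ValueError("need at least 2 replicates for a mean ± SD summary")
    if all(len(r.truth) == 0 for r in results):
        raise ValueError("no truth deletions in any replicate")
    sens = np.array([r.sensitivity(criterion) for r in results])
    spec = np.array([r.specificity(criterion) for r in results])
    tp_pct, fp_pct = tp_fp_length_distributions(results, criterion)
    return EvalSummary(
        criterion=criterion,
        sensitivity_mean=float(sens.mean()),
        sensitivity_sd=float(sens.std(ddof=1)),
        specificity_mean=float(spec.mean()),
        specificity_sd=float(spec.std(ddof=1)),
        tp_pct_by_class=tp_pct,
        fp_pct_by_bin=fp_pct,
        n_replicates=len(results),
    )
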