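"""Sliding-window summaries of depth and variants along chromosomes.

The genome scan uses a moving average of per-base depth with a 3 Mbp window
advanced in 1 Mbp steps; simulation benchmarking uses 1 Mbp windows with a
10 kbp step.  Trailing windows are truncated at the chromosome end rather
than dropped so terminal deletions stay visible, and a chromosome shorter
than one window yields a single full-chromosome window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .depthio import DepthProfile, VariantRecord

__all__ = [
    "WindowTrack",
    "sliding_mean",
    "genome_mean",
    "normalize_track",
    "normalize_tracks",
    "snp_density",
    "ts_tv_ratio",
]

GENOME_SCAN_WINDOW = 3_000_000
GENOME_SCAN_STEP = 1_000_000
# full-scale simulation scan (1 Mbp window / 10 kbp step on real genomes)
SIMULATION_WINDOW = 1_000_000
SIMULATION_STEP = 10_000
# desk-scale benchmark grid: every length divided by 20, ratios preserved
BENCH_WINDOW = 50_000
BENCH_STEP = 500


@dataclass
class WindowTrack:
    """Per-window values (mean depth, normalized depth, or SNP counts).

    ``starts`` are 0-based window starts spaced by ``step``; window ``i``
    covers ``[starts[i], min(starts[i] + window_size, chrom_length))``.
    """

    chrom: str
    window_size: int
    step: int
    starts: np.ndarray
    values: np.ndarray
    chrom_length: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.starts.shape != self.values.shape:
            raise ValueError("starts and values must be the same length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("window values must be finite")

    @property
    def n_windows(self) -> int:
        return int(self.starts.size)

    def ends(self) -> np.ndarray:
        return np.minimum(self.starts + self.window_size, self.chrom_length)

    def footprints(self) -> Iterator[tuple[int, int, float]]:
        for start, end, value in zip(self.starts, self.ends(), self.values):
            yield int(start), int(end), float(value)

    def full_width_mask(self) -> np.ndarray:
        """True for windows whose footprint has the full nominal width.

        Trailing windows truncated at the chromosome end average over fewer
        bases and carry inflated sampling noise (up to sqrt(w/span)-fold), so
        exceedance testing and null resampling restrict themselves to
        full-width windows; truncated windows remain in the track for
        visualization and export.  A chromosome shorter than one window has
        its single window counted as full.
        """
        nominal = min(self.window_size, self.chrom_length)
        return (self.ends() - self.starts) >= nominal

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.window_size == other.window_size
            and self.step == other.step
            and self.chrom_length == other.chrom_length
            and np.array_equal(self.starts, other.starts)
        )


def _window_starts(length: int, window_size: int, step: int) -> np.ndarray:
    if length <= window_size:
        return np.zeros(1, dtype=np.int64)
    # last start is the largest multiple of step below the chromosome end
    return np.arange(0, length, step, dtype=np.int64)


def sliding_mean(
    profile: DepthProfile, window_size: int, step: int
) -> WindowTrack:
    """Moving average of per-base depth over windows of ``window_size`` per ``step``.

    Uses a cumulative sum so cost is O(length); trailing windows shrink to
    the chromosome end and their mean uses the truncated footprint.
    """
    if not (1 <= step <= window_size):
        raise ValueError("require window_size >= step >= 1")
    length = profile.length
    starts = _window_starts(length, window_size, step)
    ends = np.minimum(starts + window_size, length)
    csum = np.concatenate(([0.0], np.cumsum(profile.depth, dtype=np.float64)))
    sums = csum[ends] - csum[starts]
    values = sums / np.maximum(ends - starts, 1)
    return WindowTrack(
        chrom=profile.chrom,
        window_size=window_size,
        step=step,
        starts=starts,
        values=values,
        chrom_length=length,
        sample_id=profile.sample_id,
    )


def genome_mean(tracks: Mapping[str, WindowTrack] | Sequence[WindowTrack]) -> float:
    """Mean window value over all chromosomes of one sample."""
    items = tracks.values() if isinstance(tracks, Mapping) else tracks
    values = np.concatenate([t.values for t in items])
    if values.size == 0:
        raise ValueError("no windows")
    return float(values.mean())


def normalize_track(track: WindowTrack, mean: float) -> WindowTrack:
    """Divide window values by a genome-wide mean so the genome average is 1."""
    if not (mean > 0):
        raise ValueError("genome mean must be positive")
    return replace(track, values=track.values / mean)


def normalize_tracks(tracks: Mapping[str, WindowTrack]) -> dict[str, WindowTrack]:
    """Normalize every chromosome of a sample by the sample's genome-wide mean."""
    mean = genome_mean(tracks)
    return {chrom: normalize_track(t, mean) for chrom, t in tracks.items()}


def snp_density(
    variants: Sequence[VariantRecord],
    chrom_lengths: Mapping[str, int],
    bin_size: int = 10_000_000,
) -> dict[str, WindowTrack]:
    """Count SNPs per non-overlapping bin (default 10 Mbp) along each chromosome."""
    if bin_size < 1:
        raise ValueError("bin size must be >= 1")
    tracks: dict[str, WindowTrack] = {}
    snps = [v for v in variants if v.kind == "snp"]
    for chrom, length in chrom_lengths.items():
        length = int(length)
        starts = _window_starts(length, bin_size, bin_size)
        counts = np.zeros(starts.size, dtype=np.float64)
        for var in snps:
            if var.chrom != chrom:
                continue
            if not (1 <= var.pos <= length):
                raise ValueError(
                    f"variant at {var.chrom}:{var.pos} outside declared length {length}"
                )
            counts[min((var.pos - 1) // bin_size, starts.size - 1)] += 1
        tracks[chrom] = WindowTrack(
            chrom=chrom,
            window_size=bin_size,
            step=bin_size,
            starts=starts,
            values=counts,
            chrom_length=length,
        )
    return tracks


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def ts_tv_ratio(variants: Sequence[VariantRecord]) -> float:
    """Transitions (A<->G, C<->T) over transversions among SNPs; indels ignored."""
    ts = tv = 0
    for var in variants:
        if var.kind != "snp":
            continue
        if (var.ref.upper(), var.alt.upper()) in _TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        raise ZeroDivisionError("no transversions: Ts/Tv undefined")
    return ts / tv
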