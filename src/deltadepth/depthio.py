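"""I/O for per-base depth tables, minimal VCFs, and BED/bedGraph tracks.

Input depth tables follow the three-column ``samtools depth`` dialect
(chromosome, 1-based position, depth).  Positions absent from the table are
taken to be zero-depth — ``samtools depth`` omits them by default — so every
chromosome is materialised as a dense vector of its full declared length.
All internal coordinates are 0-based half-open; BED and bedGraph outputs use
the same convention, matching their standards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DepthProfile",
    "VariantRecord",
    "DepthParseError",
    "read_depth_table",
    "write_depth_table",
    "read_variants",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]


class DepthParseError(ValueError):
    """Raised for malformed or out-of-bounds depth-table rows."""


@dataclass
class DepthProfile:
    """Dense per-base depth for one chromosome of one sample.

    ``depth[i]`` is the coverage at 0-based position ``i``; the vector always
    spans the full chromosome, with unlisted positions at zero.
    """

    chrom: str
    depth: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D vector")
        if self.depth.size and self.depth.min() < 0:
            raise ValueError("depths must be non-negative")

    @property
    def length(self) -> int:
        return int(self.depth.size)

    def mean(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic SNP or short indel (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @property
    def kind(self) -> str:
        return "snp" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"


def read_depth_table(
    path: str | Path,
    chrom_lengths: Mapping[str, int],
    sample_id: str = "",
) -> dict[str, DepthProfile]:
    """Read a samtools-depth TSV into one dense :class:`DepthProfile` per chromosome.

    Every chromosome in ``chrom_lengths`` is returned, even if absent from the
    file (all-zero profile).  Rows naming a chromosome not in ``chrom_lengths``
    or a position beyond its declared length raise :class:`DepthParseError`.
    """
    profiles = {
        chrom: np.zeros(int(length), dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    try:
        table = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
            dtype={"chrom": str},
            comment="#",
        )
    except pd.errors.EmptyDataError:
        table = pd.DataFrame(columns=["chrom", "pos", "depth"])
    except (ValueError, pd.errors.ParserError) as exc:
        raise DepthParseError(f"{path}: malformed depth table: {exc}") from exc

    for col in ("pos", "depth"):
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            lineno = int(bad.idxmax()) + 1
            raise DepthParseError(
                f"{path}: line {lineno}: non-numeric {col!r} field"
            )
        table[col] = numeric.astype(np.int64)

    for chrom, group in table.groupby("chrom", sort=False):
        if chrom not in profiles:
            raise DepthParseError(f"{path}: unknown chromosome {chrom!r}")
        pos = group["pos"].to_numpy()
        length = profiles[chrom].size
        if pos.size and (pos.min() < 1 or pos.max() > length):
            lineno = int(group.index[(pos < 1) | (pos > length)][0]) + 1
            raise DepthParseError(
                f"{path}: line {lineno}: position outside [1, {length}] on {chrom}"
            )
        profiles[chrom][pos - 1] = group["depth"].to_numpy()

    return {
        chrom: DepthProfile(chrom=chrom, depth=vec, sample_id=sample_id)
        for chrom, vec in profiles.items()
    }


def write_depth_table(
    profiles: Iterable[DepthProfile],
    path: str | Path,
    omit_zero: bool = True,
) -> None:
    """Write profiles as a samtools-depth TSV (1-based positions).

    With ``omit_zero`` (the default, matching samtools) zero-depth positions
    are not listed; readers must apply the fill-zero rule.
    """
    with open(path, "w") as handle:
        for prof in profiles:
            depth = prof.depth
            if omit_zero:
                (idx,) = np.nonzero(depth)
            else:
                idx = np.arange(depth.size)
            frame = pd.DataFrame(
                {"chrom": prof.chrom, "pos": idx + 1, "depth": depth[idx]}
            )
            frame.to_csv(handle, sep="\t", header=False, index=False)


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read SNPs and short indels (≤ 25 bp length difference) from a VCF.

    Multi-allelic records are skipped with a warning; indels longer than the
    25 bp caller ceiling are skipped with a logged count.  Requires cyvcf2.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    n_multi = n_long = 0
    for var in VCF(str(path)):
        alts = var.ALT
        if len(alts) != 1:
            n_multi += 1
            continue
        ref, alt = var.REF, alts[0]
        if abs(len(ref) - len(alt)) > 25:
            n_long += 1
            continue
        records.append(VariantRecord(chrom=var.CHROM, pos=var.POS, ref=ref, alt=alt))
    if n_multi:
        logger.warning("skipped %d multi-allelic record(s)", n_multi)
    if n_long:
        logger.info("skipped %d indel(s) longer than 25 bp", n_long)
    return records


def _sorted_regions(
    regions: Sequence[tuple],
) -> list[tuple]:
    ordered = sorted(regions, key=lambda r: (r[0], r[1], r[2]))
    if list(ordered) != list(regions):
        logger.info("BED intervals re-sorted before writing")
    return ordered


def write_bed(regions: Sequence[tuple], path: str | Path) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED (0-based half-open)."""
    with open(path, "w") as handle:
        for region in _sorted_regions(regions):
            chrom, start, end = region[:3]
            extra = "".join(f"\t{x}" for x in region[3:])
            handle.write(f"{chrom}\t{int(start)}\t{int(end)}{extra}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read the first three BED columns back as (chrom, start, end) tuples."""
    out: list[tuple[str, int, int]] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out.append((fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bedgraph(track, path: str | Path) -> None:
    """Write a window track as bedGraph, one line per window footprint.

    With step < window the footprints overlap; consecutive overlapping lines
    are emitted as-is (a deliberate relaxed dialect for sliding tracks).
    """
    with open(path, "w") as handle:
        for start, end, value in track.footprints():
            handle.write(f"{track.chrom}\t{start}\t{end}\t{value:g}\n")
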