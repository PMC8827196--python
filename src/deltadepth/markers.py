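"""Co-dominant three-primer PCR marker layout across a deletion breakpoint.

The assay places a forward primer upstream of the deletion (pre-deletion),
a forward primer inside the deleted segment (in-deletion), and a reverse
primer downstream (post-deletion).  In a wild-type homozygote the in- and
post-deletion primers amplify a fragment spanning the distal breakpoint; in
a mutant homozygote the in-deletion primer has no template, and the pre- and
post-deletion primers amplify a shorter junction fragment (the deleted
segment collapses out of the product).  Heterozygotes show both bands, so
the three genotypes are distinguishable on one gel lane.

Only coordinates and fragment arithmetic are modelled here; primer
sequences, melting temperatures and genome-wide specificity are left to
dedicated design tools.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["MarkerLayout", "design_codominant_layout", "predict_fragments"]

GENOTYPES = ("wild_homozygote", "mutant_homozygote", "heterozygote")


@dataclass(frozen=True)
class PrimerSite:
    """A primer footprint (0-based half-open) with strand orientation."""

    start: int
    end: int
    strand: str  # "+" forward, "-" reverse


@dataclass(frozen=True)
class MarkerLayout:
    """Coordinates of the three primers around a deletion (0-based half-open)."""

    deletion_start: int
    deletion_end: int
    pre_primer: PrimerSite
    in_primer: PrimerSite
    post_primer: PrimerSite

    @property
    def deletion_length(self) -> int:
        return self.deletion_end - self.deletion_start

    def validate(self) -> None:
        if not self.pre_primer.end <= self.deletion_start:
            raise ValueError("pre-deletion primer must lie entirely before the deletion")
        if not (
            self.deletion_start <= self.in_primer.start
            and self.in_primer.end <= self.deletion_end
        ):
            raise ValueError("in-deletion primer must lie entirely inside the deletion")
        if not self.post_primer.start >= self.deletion_end:
            raise ValueError("post-deletion primer must lie entirely after the deletion")


def design_codominant_layout(
    deletion_start: int,
    deletion_end: int,
    wt_target: int,
    mut_target: int,
    primer_len: int = 20,
) -> MarkerLayout:
    """Solve primer coordinates so the two amplicons hit the requested sizes.

    The wild-type band runs from the in-deletion primer start to the
    post-deletion primer end (``wt_target`` bp); the mutant band is the
    pre-to-post product minus the deleted length (``mut_target`` bp).  The
    post-deletion primer is anchored ``mut_target / 2`` past the distal
    breakpoint, so the mutant junction fragment is centred on the collapsed
    breakpoint and the primers sit conservatively clear of it.
    """
    deletion_length = deletion_end - deletion_start
    if min(wt_target, mut_target) <= 2 * primer_len:
        raise ValueError("target amplicons must exceed twice the primer length")
    if wt_target >= deletion_length:
        raise ValueError("wild-type amplicon must be shorter than the deletion")

    post_end = deletion_end + mut_target // 2
    in_start = post_end - wt_target
    pre_start = post_end - mut_target - deletion_length
    if pre_start < 0:
        raise ValueError("mutant amplicon target unreachable: pre-primer before origin")

    layout = MarkerLayout(
        deletion_start=deletion_start,
        deletion_end=deletion_end,
        pre_primer=PrimerSite(pre_start, pre_start + primer_len, "+"),
        in_primer=PrimerSite(in_start, in_start + primer_len, "+"),
        post_primer=PrimerSite(post_end - primer_len, post_end, "-"),
    )
    layout.validate()
    return layout


def predict_fragments(layout: MarkerLayout, genotype: str) -> set[int]:
    """Expected PCR band sizes for a genotype (e.g. 712 bp WT / 414 bp mutant bands).

    Mutant homozygotes lack the in-deletion template entirely, so only the
    junction product appears; heterozygotes show the union of both bands.
    """
    layout.validate()
    wt_fragment = layout.post_primer.end - layout.in_primer.start
    mut_fragment = (
        layout.post_primer.end - layout.pre_primer.start - layout.deletion_length
    )
    if genotype == "wild_homozygote":
        return {wt_fragment}
    if genotype == "mutant_homozygote":
        return {mut_fragment}
    if genotype == "heterozygote":
        return {wt_fragment, mut_fragment}
    raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
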