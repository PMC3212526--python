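"""Two-stage conserved-site acceptance filter and sub-region delineation.

A candidate motif is judged by its residues at the 19 canonical conserved
sites of the bHLH domain after alignment to the reference profile: stage 1
keeps candidates with fewer than nine variations from the conserved residue
sets; stage 2 (historically applied after re-alignment of the survivors)
discards anything with fewer than ten conserved residues.  The two printed
thresholds are not equivalent (fewer than nine variations already implies
at least eleven matches of nineteen); both are applied sequentially as
stated, and the redundancy is surfaced in the log rather than tidied away.

Alignment to the profile is global with free end gaps against the
reference consensus; sites aligned to a gap count as variations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .catalog import (
    DEFAULT_REGION_TEMPLATE,
    ConservedSiteProfile,
    ReferenceMotif,
)

log = logging.getLogger(__name__)

STAGE1_MAX_VARIATIONS = 9   # keep if variations < 9
STAGE2_MIN_MATCHES = 10     # discard if matches < 10


class FilterError(ValueError):
    pass


class UnalignableError(FilterError):
    """Candidate too short or too divergent to map onto the profile."""


@dataclass(frozen=True)
class AlignedCandidate:
    candidate_id: str
    sequence: str
    #: profile column -> candidate residue index (None where the candidate
    #: has a deletion relative to the profile)
    profile_to_candidate: tuple[int | None, ...]
    score: float

    def residue_at(self, column: int) -> str | None:
        idx = self.profile_to_candidate[column]
        return None if idx is None else self.sequence[idx]


@dataclass(frozen=True)
class SiteEvaluation:
    candidate_id: str
    matches: int
    variations: int

    def __post_init__(self) -> None:
        if self.matches < 0 or self.variations < 0:
            raise FilterError("negative site counts")


def reference_consensus(refs: Sequence[ReferenceMotif]) -> str:
    """Majority residue per profile column (ties to the alphabetically
    first residue); references must share one coordinate system."""
    if not refs:
        raise FilterError("no references")
    length = min(len(r.sequence) for r in refs)
    cols = []
    for i in range(length):
        counts: dict[str, int] = {}
        for r in refs:
            aa = r.sequence[i]
            counts[aa] = counts.get(aa, 0) + 1
        cols.append(max(sorted(counts), key=lambda a: counts[a]))
    return "".join(cols)


def _make_aligner(
    matrix: str = "PAM250",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on both sequences
    for attr in (
        "open_end_insertion_score", "extend_end_insertion_score",
        "open_end_deletion_score", "extend_end_deletion_score",
    ):
        setattr(aligner, attr, 0.0)
    return aligner


def align_to_profile(
    candidate: str,
    refs: Sequence[ReferenceMotif] | str,
    candidate_id: str = "candidate",
    min_length_fraction: float = 0.5,
    **aligner_kwargs,
) -> AlignedCandidate:
    """Globally align *candidate* to the reference consensus (free end gaps)
    and return the per-column residue lookup."""
    if not candidate:
        raise FilterError("empty candidate")
    consensus = refs if isinstance(refs, str) else reference_consensus(refs)
    if len(candidate) < min_length_fraction * len(consensus):
        raise UnalignableError(
            f"{candidate_id}: {len(candidate)} residues is shorter than half "
            f"the {len(consensus)}-column profile"
        )
    aligner = _make_aligner(**aligner_kwargs)
    aln = aligner.align(consensus, candidate.replace("*", "X"))[0]
    mapping: list[int | None] = [None] * len(consensus)
    for (t0, t1), (q0, q1) in zip(*aln.aligned):
        for k in range(t1 - t0):
            mapping[t0 + k] = q0 + k
    return AlignedCandidate(
        candidate_id=candidate_id,
        sequence=candidate,
        profile_to_candidate=tuple(mapping),
        score=float(aln.score),
    )


def evaluate_sites(
    aligned: AlignedCandidate, profile: ConservedSiteProfile
) -> SiteEvaluation:
    """Count conserved-site matches; a site aligned to a gap is a variation."""
    matches = 0
    for pos, allowed in zip(profile.site_positions, profile.consensus_residues):
        aa = aligned.residue_at(pos)
        if aa is not None and aa in allowed:
            matches += 1
    return SiteEvaluation(
        candidate_id=aligned.candidate_id,
        matches=matches,
        variations=profile.n_sites - matches,
    )


def apply_filter(
    evals: Sequence[SiteEvaluation],
    stage1_max_variations: int = STAGE1_MAX_VARIATIONS,
    stage2_min_matches: int = STAGE2_MIN_MATCHES,
) -> tuple[list[SiteEvaluation], list[SiteEvaluation]]:
    """Sequential two-stage rule; returns (accepted, discarded).

    Stage 1: variations < stage1_max_variations marks a candidate as a
    potential member.  Stage 2: potentials with matches < stage2_min_matches
    are discarded.  With both defaults over the same 19 sites stage 2 is
    subsumed by stage 1; the log notes when it would have acted.
    """
    accepted, discarded = [], []
    for e in evals:
        stage1 = e.variations < stage1_max_variations
        stage2 = e.matches >= stage2_min_matches
        if stage1 and not stage2:
            log.info(
                "%s: passed stage 1 (%d variations) but discarded at stage 2 "
                "(%d matches)", e.candidate_id, e.variations, e.matches,
            )
        (accepted if stage1 and stage2 else discarded).append(e)
    return accepted, discarded


def delineate_regions(
    aligned: AlignedCandidate,
    template: Mapping[str, tuple[int, int]] = DEFAULT_REGION_TEMPLATE,
) -> dict[str, tuple[int, int]]:
    """Map the basic/helix1/loop/helix2 template through the alignment.

    Returns contiguous half-open intervals in candidate coordinates covering
    the whole candidate; insertions relative to the profile extend the
    region they fall inside, so a loop insertion grows the loop interval.
    """
    n = len(aligned.sequence)
    mapped = [i for i in aligned.profile_to_candidate if i is not None]
    if not mapped:
        raise UnalignableError(f"{aligned.candidate_id}: nothing aligned")
    names = sorted(template, key=lambda k: template[k][0])
    bounds: list[int] = [0]
    for name in names[1:]:
        col = template[name][0]
        # first candidate residue aligned at or after this template boundary
        idx = next(
            (
                aligned.profile_to_candidate[c]
                for c in range(col, len(aligned.profile_to_candidate))
                if aligned.profile_to_candidate[c] is not None
            ),
            n,
        )
        bounds.append(max(idx, bounds[-1]))
    bounds.append(n)
    return {name: (bounds[i], bounds[i + 1]) for i, name in enumerate(names)}


def region_of_residue(
    region_map: Mapping[str, tuple[int, int]], residue_index: int
) -> str:
    for name, (a, b) in region_map.items():
        if a <= residue_index < b:
            return name
    raise FilterError(f"residue {residue_index} outside region map")
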