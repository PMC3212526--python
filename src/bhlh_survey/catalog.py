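"""Reference bHLH motif sets and the family -> high-order-group catalog.

The survey classifies candidate basic helix-loop-helix (bHLH) motifs against a
reference collection of animal bHLH families.  Animal bHLH proteins fall into
45 named families which are further binned into six high-order groups (A-F) by
the DNA element they bind and their domain architecture, plus an "orphan" bin
for members that sit in no named family.

Published reference motif collections (a 45-family representative set and the
114-motif mouse set) are supplied by the user as FASTA with ``id|family``
headers.  When no file is given, a deterministic synthetic stand-in set with
the same family structure is generated so the whole pipeline runs offline;
see :func:`synthesize_reference_set`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Motif coordinate system used by the synthetic reference set: 60 residues
#: partitioned into the four canonical sub-regions (half-open intervals).
DEFAULT_REGION_TEMPLATE: dict[str, tuple[int, int]] = {
    "basic": (0, 13),
    "helix1": (13, 28),
    "loop": (28, 42),
    "helix2": (42, 60),
}

#: Default positions (0-based, profile coordinates) of the 19 canonical
#: conserved sites of the bHLH motif.  The identity of the sites is a
#: documented convention of this package, not a fact of any one dataset:
#: the two most conserved motif positions (sites 23 and 59, 1-based) are
#: included and the remainder are spread over the basic region and the two
#: helices, leaving the variable loop nearly free, which mirrors how the
#: motif's conservation is distributed.  Configurable via ``conserved_sites``.
DEFAULT_CONSERVED_SITES: tuple[int, ...] = (
    4, 7, 9, 12,                 # basic
    13, 16, 17, 20, 22, 24, 27,  # helix 1 (includes site 23, 1-based)
    35,                          # loop
    42, 45, 46, 49, 53, 56, 58,  # helix 2 (includes site 59, 1-based)
)

#: 60-residue bHLH-like consensus used as the root of the synthetic
#: reference set (basic | helix1 | loop | helix2).
CONSENSUS_MOTIF = (
    "RADRRNAHNARER"        # basic
    "RRDRINEAFDELRNV"      # helix 1
    "VPSASGDKKLSKVE"       # loop
    "TLRMAVEYIRSLQELLGE"   # helix 2
)

#: Highly divergent single-motif outgroup used to root in-group trees,
#: standing in for the rice R-family motif conventionally used for that
#: purpose.  Generated once from the consensus at high substitution rate.
OUTGROUP_ID = "OsRa"


class CatalogError(ValueError):
    """Raised for malformed reference sets or catalog violations."""


@dataclass(frozen=True)
class ReferenceMotif:
    """One reference bHLH motif with family/group membership."""

    id: str
    family: str
    group: str
    sequence: str
    region_map: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_TEMPLATE)
    )

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if not 50 <= n <= 75:
            raise CatalogError(
                f"motif {self.id!r}: length {n} outside [50, 75]"
            )
        intervals = sorted(self.region_map.values())
        if intervals[0][0] != 0 or intervals[-1][1] != n:
            raise CatalogError(f"motif {self.id!r}: regions do not cover sequence")
        for (a, b), (c, d) in zip(intervals, intervals[1:]):
            if b != c:
                raise CatalogError(
                    f"motif {self.id!r}: regions not contiguous at {b}/{c}"
                )


@dataclass(frozen=True)
class FamilyCatalog:
    """The family -> high-order group map (A-F plus the orphan bin)."""

    families: tuple[tuple[str, str], ...]

    @property
    def group_of(self) -> dict[str, str]:
        return dict(self.families)

    @property
    def group_family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, g in self.families:
            counts[g] = counts.get(g, 0) + 1
        return counts

    def __contains__(self, family: str) -> bool:
        return family in self.group_of


@dataclass(frozen=True)
class ConservedSiteProfile:
    """The 19 conserved alignment positions and their accepted residues."""

    site_positions: tuple[int, ...]
    consensus_residues: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.site_positions) != len(self.consensus_residues):
            raise CatalogError("site/residue-set length mismatch")
        if list(self.site_positions) != sorted(set(self.site_positions)):
            raise CatalogError("site positions must be strictly increasing")
        if any(not s for s in self.consensus_residues):
            raise CatalogError("each conserved site needs a non-empty residue set")

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)


# ---------------------------------------------------------------------------
# catalog / reference IO


def load_family_catalog(path=None) -> FamilyCatalog:
    """Load the family->group TSV; defaults to the packaged 45-family animal
    catalog (22 A, 12 B, 7 C, 1 D, 2 E, 1 F families plus the orphan bin)."""
    if path is None:
        ref = resources.files("bhlh_survey.data") / "family_groups.tsv"
        text = ref.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    rows = []
    lines = [l for l in text.splitlines() if l.strip()]
    header = lines[0].split("\t")
    if header[:2] != ["family", "group"]:
        raise CatalogError(f"catalog header must be family/group, got {header}")
    for line in lines[1:]:
        fam, group = line.split("\t")[:2]
        rows.append((fam, group))
    return FamilyCatalog(families=tuple(rows))


def load_reference_set(path, catalog: FamilyCatalog) -> list[ReferenceMotif]:
    """Load reference motifs from FASTA with ``id|family`` headers.

    Every record is validated against the motif invariants; records whose
    family is absent from *catalog* are rejected with an error naming them.
    """
    motifs: list[ReferenceMotif] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise CatalogError(
                f"reference header {rec.id!r} does not encode 'id|family'"
            )
        mid, family = rec.id.split("|", 1)
        if family not in catalog:
            raise CatalogError(
                f"reference {mid!r}: family {family!r} absent from catalog"
            )
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise CatalogError(f"reference {mid!r}: invalid residues {sorted(bad)}")
        motifs.append(
            ReferenceMotif(
                id=mid,
                family=family,
                group=catalog.group_of[family],
                sequence=seq,
                region_map=_scaled_regions(len(seq)),
            )
        )
    if not motifs:
        warnings.warn("reference FASTA contained no records", stacklevel=2)
    return motifs


def write_reference_set(motifs: Iterable[ReferenceMotif], path) -> None:
    records = [
        SeqRecord(Seq(m.sequence), id=f"{m.id}|{m.family}", description="")
        for m in motifs
    ]
    SeqIO.write(records, str(path), "fasta")


def _scaled_regions(n: int) -> dict[str, tuple[int, int]]:
    """Region template scaled proportionally to a motif of length *n*."""
    if n == 60:
        return dict(DEFAULT_REGION_TEMPLATE)
    out = {}
    for name, (a, b) in DEFAULT_REGION_TEMPLATE.items():
        out[name] = (round(a * n / 60), round(b * n / 60))
    # re-impose contiguity after rounding
    names = ["basic", "helix1", "loop", "helix2"]
    for x, y in zip(names, names[1:]):
        out[y] = (out[x][1], out[y][1])
    out["helix2"] = (out["helix2"][0], n)
    return out


# ---------------------------------------------------------------------------
# conserved-site profile


def build_conserved_profile(
    refs: Sequence[ReferenceMotif],
    site_positions: Sequence[int] = DEFAULT_CONSERVED_SITES,
    cutoff: float = 0.5,
) -> ConservedSiteProfile:
    """Consensus residue sets at the conserved sites.

    A residue belongs to a site's conserved set when its frequency among the
    aligned references at that position is >= *cutoff*.  References must share
    one coordinate system (the synthetic set is gap-free at 60 residues).
    When the cutoff admits no residue at a site, the single most frequent
    residue is used so the set is never empty.
    """
    if len(refs) < 2:
        raise CatalogError("need at least 2 references to build a profile")
    length = min(len(r.sequence) for r in refs)
    sets = []
    for pos in site_positions:
        if pos >= length:
            raise CatalogError(f"conserved site {pos} outside alignment (len {length})")
        counts: dict[str, int] = {}
        for r in refs:
            aa = r.sequence[pos]
            counts[aa] = counts.get(aa, 0) + 1
        total = len(refs)
        chosen = {aa for aa, c in counts.items() if c / total >= cutoff}
        if not chosen:
            chosen = {max(counts, key=lambda a: (counts[a], a))}
        sets.append(frozenset(chosen))
    return ConservedSiteProfile(
        site_positions=tuple(site_positions), consensus_residues=tuple(sets)
    )


# ---------------------------------------------------------------------------
# synthetic stand-in reference sets

#: Number of motifs per family in the synthetic "mouse-like" set.  Mirrors the
#: per-family member counts of the mouse repertoire (114 motifs): the surveyed
#: panda counts plus the seven members the panda lacks; Delilah has no mouse
#: member and contributes none.
_MOUSE_LIKE_EXTRA = {
    "Beta3": 1, "Mesp": 1, "Paraxis": 1, "Myc": 1,
    "H/E(spl)": 1, "COE": 1, "Orphan": 1,
}


def _panda_family_counts() -> dict[str, int]:
    from .introns import load_table1  # late import to avoid a cycle

    t1 = load_table1()
    counts: dict[str, int] = {}
    for fam in t1["family"]:
        counts[fam] = counts.get(fam, 0) + 1
    return counts


def mouse_like_family_counts(catalog: FamilyCatalog) -> dict[str, int]:
    counts = _panda_family_counts()
    for fam, extra in _MOUSE_LIKE_EXTRA.items():
        counts[fam] = counts.get(fam, 0) + extra
    return {fam: counts.get(fam, 0) for fam, _ in catalog.families}


def synthesize_reference_set(
    catalog: FamilyCatalog,
    members_per_family: Mapping[str, int] | int = 1,
    seed: int = 0,
    family_divergence: float = 0.5,
    member_divergence: float = 0.2,
) -> list[ReferenceMotif]:
    """Deterministic synthetic stand-in for a published reference motif set.

    Each family receives a family-characteristic motif obtained by mutating
    the consensus at non-conserved positions with probability
    *family_divergence*; members within a family are small perturbations
    (*member_divergence*) of the family motif.  The 19 conserved sites carry
    the consensus residues in every reference, so the conserved-site profile
    of the set is exactly the consensus.  Fully reproducible for fixed seed.
    """
    protected = set(DEFAULT_CONSERVED_SITES)
    refs: list[ReferenceMotif] = []
    for fam_idx, (fam, group) in enumerate(catalog.families):
        if isinstance(members_per_family, int):
            n = members_per_family
        else:
            n = members_per_family.get(fam, 0)
        # per-family streams: the family motif (and each member) is the same
        # whatever subset of members other sets request
        fam_rng = np.random.default_rng([seed, fam_idx])
        fam_seq = _mutate(CONSENSUS_MOTIF, family_divergence, protected, fam_rng)
        for k in range(n):
            # every member carries private substitutions away from the
            # (unobserved) family ancestor -- no extant ancestral sequence
            member_rng = np.random.default_rng([seed, fam_idx, k])
            seq = _mutate(fam_seq, member_divergence, protected, member_rng)
            safe = fam.replace("/", "").replace("(", "").replace(")", "")
            refs.append(
                ReferenceMotif(
                    id=f"{safe}_{k + 1}",
                    family=fam,
                    group=group,
                    sequence=seq,
                )
            )
    return refs


def outgroup_motif(seed: int = 0) -> ReferenceMotif:
    """Distant outgroup motif for rooting in-group trees."""
    rng = np.random.default_rng(10_000_019 + seed)
    seq = _mutate(CONSENSUS_MOTIF, 0.8, set(), rng)
    return ReferenceMotif(id=OUTGROUP_ID, family="outgroup", group="outgroup",
                          sequence=seq)


def _mutate(seq: str, rate: float, protected: set[int], rng) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)
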