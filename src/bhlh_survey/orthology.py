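"""In-group phylogenetic ortholog assignment and its outcome categories.

Each candidate motif is analysed together with the reference members of the
family (or families) nearest to it in the global tree, rooted by a distant
outgroup, with three tree methods: neighbor joining (1,000 bootstrap
replicates), maximum parsimony (100 replicates) and the likelihood-flavoured
ML-surrogate (NJ on maximum-likelihood distances, 1,000 replicates).  Per
method the candidate either pairs off with a unique reference (a two-taxon
clade under the root: ``mono_with_partner``), groups with a whole family
without singling out a member (``n/m*``), or shows no family-level
monophyly (``n/m``).

A candidate's call is categorised by how many methods support the same
partner with bootstrap strictly above 50:

  1. all three methods agree above 50;
  2. exactly two methods above 50 (the third weak or n/m*, n/m);
  3. some method finds the partner but fewer than two are above 50;
  4. no method finds any partner -- the analysis is rerun on whole protein
     sequences when those are available, and the result recorded as the
     whole-protein fallback.

"Above 50" is strict: a bootstrap of exactly 50 counts as weak.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import dendropy

from .catalog import ReferenceMotif
from .phylo import (
    BootstrapConfig,
    bootstrap_support,
    edge_bipartitions,
    leaf_labels,
)

METHODS = ("NJ", "MP", "ML-surrogate")

MONO = "mono_with_partner"
NM_FAMILY = "n/m*"
NM = "n/m"


class OrthologyError(ValueError):
    pass


@dataclass(frozen=True)
class MethodResult:
    method: str
    partner: str | None
    bootstrap: float | None
    flag: str

    def __post_init__(self) -> None:
        if (self.partner is not None) != (self.flag == MONO):
            raise OrthologyError("partner must be set iff flag is mono_with_partner")

    @property
    def strong(self) -> bool:
        return (
            self.flag == MONO
            and self.bootstrap is not None
            and self.bootstrap > 50.0
        )

    def token(self) -> str:
        if self.flag == MONO:
            return f"{self.bootstrap:.0f}" if self.bootstrap is not None else "?"
        return self.flag


@dataclass(frozen=True)
class OrthologCall:
    candidate_id: str
    family: str | None
    partner: str | None
    category: int
    results: tuple[MethodResult, ...]
    sub_label: str = ""

    def __post_init__(self) -> None:
        if self.category not in (1, 2, 3, 4):
            raise OrthologyError(f"bad category {self.category}")


@dataclass(frozen=True)
class InGroupConfig:
    nj_replicates: int = 1000
    mp_replicates: int = 100
    ml_replicates: int = 1000
    seed: int = 0
    min_ingroup: int = 8
    max_mp_taxa: int = 12
    methods: tuple[str, ...] = METHODS


# ---------------------------------------------------------------------------
# in-group selection


def select_ingroup(
    candidate_id: str,
    global_tree: dendropy.Tree,
    refs: Sequence[ReferenceMotif],
    min_ingroup: int = 8,
) -> list[ReferenceMotif]:
    """Reference members of the family clade(s) nearest the candidate.

    Walks rootward from the candidate's leaf in the global tree, collecting
    the families of the reference leaves encountered, until whole families
    totalling at least *min_ingroup* members are gathered.
    """
    by_id = {r.id: r for r in refs}
    by_family: dict[str, list[ReferenceMotif]] = {}
    for r in refs:
        by_family.setdefault(r.family, []).append(r)
    leaf = next(
        (
            lf
            for lf in global_tree.leaf_node_iter()
            if lf.taxon.label == candidate_id
        ),
        None,
    )
    if leaf is None:
        raise OrthologyError(f"candidate {candidate_id!r} not in global tree")
    chosen_families: list[str] = []
    n_members = 0
    node = leaf.parent_node
    while node is not None and n_members < min_ingroup:
        for lf in node.leaf_iter():
            r = by_id.get(lf.taxon.label)
            if r is not None and r.family not in chosen_families:
                chosen_families.append(r.family)
                n_members += len(by_family[r.family])
                if n_members >= min_ingroup:
                    break
        node = node.parent_node
    out: list[ReferenceMotif] = []
    for fam in chosen_families:
        out.extend(by_family[fam])
    return out


# ---------------------------------------------------------------------------
# per-method analysis


def _method_result(
    method: str,
    tree: dendropy.Tree,
    support: Mapping[frozenset[str], float],
    candidate_id: str,
    refs_by_id: Mapping[str, ReferenceMotif],
    outgroup: str,
) -> MethodResult:
    """Classify one method's tree: unique partner, family-only, or none."""
    clades = edge_bipartitions(tree, anchor=outgroup)
    partners = [
        next(iter(c - {candidate_id}))
        for c in clades
        if len(c) == 2 and candidate_id in c
    ]
    if len(partners) == 1 and partners[0] in refs_by_id:
        partner = partners[0]
        bs = support.get(frozenset({candidate_id, partner}), 0.0)
        return MethodResult(method=method, partner=partner, bootstrap=bs,
                            flag=MONO)
    # family-level monophyly: candidate + all present members of one family
    leaves = leaf_labels(tree)
    families: dict[str, set[str]] = {}
    for label in leaves:
        r = refs_by_id.get(label)
        if r is not None:
            families.setdefault(r.family, set()).add(label)
    for members in families.values():
        if frozenset(members | {candidate_id}) in clades:
            return MethodResult(method=method, partner=None, bootstrap=None,
                                flag=NM_FAMILY)
    return MethodResult(method=method, partner=None, bootstrap=None, flag=NM)


def run_ingroup_analysis(
    candidate_id: str,
    candidate_seq: str,
    ingroup: Sequence[ReferenceMotif],
    outgroup: ReferenceMotif,
    cfg: InGroupConfig = InGroupConfig(),
) -> tuple[MethodResult, ...]:
    """NJ / MP / ML-surrogate trees with bootstrap for one candidate.

    Sequences must be projected into a common coordinate system (equal
    aligned length).  The outgroup roots every tree.
    """
    if len(ingroup) < 2:
        raise OrthologyError("in-group needs at least 2 reference members")
    labels = [candidate_id] + [r.id for r in ingroup] + [outgroup.id]
    seqs = [candidate_seq] + [r.sequence for r in ingroup] + [outgroup.sequence]
    if len({len(s) for s in seqs}) != 1:
        raise OrthologyError("in-group sequences must share aligned length")
    refs_by_id = {r.id: r for r in ingroup}
    replicates = {
        "NJ": cfg.nj_replicates,
        "MP": cfg.mp_replicates,
        "ML-surrogate": cfg.ml_replicates,
    }
    results = []
    for method in cfg.methods:
        if method == "MP" and len(labels) > cfg.max_mp_taxa:
            results.append(
                MethodResult(method=method, partner=None, bootstrap=None,
                             flag=NM)
            )
            continue
        tree, support = bootstrap_support(
            labels,
            seqs,
            builder=method,
            cfg=BootstrapConfig(replicates=replicates[method], seed=cfg.seed),
            anchor=outgroup.id,
        )
        results.append(
            _method_result(method, tree, support, candidate_id, refs_by_id,
                           outgroup.id)
        )
    return tuple(results)


# ---------------------------------------------------------------------------
# categorisation


def categorize(
    candidate_id: str,
    results: Sequence[MethodResult],
    refs_by_id: Mapping[str, ReferenceMotif] | None = None,
    fallback: Callable[[], tuple[MethodResult, ...]] | None = None,
) -> OrthologCall:
    """Total mapping from per-method results to one of the four categories.

    The assigned partner is the one the most methods agree on (the NJ
    partner on ties).  When no method finds any partner the optional
    *fallback* (whole-protein rerun) is invoked and its results recorded as
    category 4.
    """
    results = tuple(results)
    partnered = [r for r in results if r.partner is not None]
    if not partnered:
        if fallback is not None:
            fb = tuple(fallback())
            fb_partnered = [r for r in fb if r.partner is not None]
            partner = _modal_partner(fb_partnered)
            family = _family_of(partner, refs_by_id)
            return OrthologCall(
                candidate_id=candidate_id, family=family, partner=partner,
                category=4, results=fb, sub_label="whole-protein",
            )
        return OrthologCall(
            candidate_id=candidate_id, family=None, partner=None, category=4,
            results=results, sub_label="unresolved",
        )
    partner = _modal_partner(partnered)
    strong = [r for r in results if r.partner == partner and r.strong]
    n_strong = len(strong)
    if n_strong == 3:
        category = 1
        sub = ""
    elif n_strong == 2:
        category = 2
        weak = [r.method for r in results if r not in strong]
        sub = "+".join(r.method for r in strong) + f" strong; {weak[0]} weak"
    else:
        category = 3
        sub = "single-method or weak support"
    return OrthologCall(
        candidate_id=candidate_id,
        family=_family_of(partner, refs_by_id),
        partner=partner,
        category=category,
        results=results,
        sub_label=sub,
    )


def _modal_partner(partnered: Sequence[MethodResult]) -> str | None:
    if not partnered:
        return None
    counts: dict[str, int] = {}
    for r in partnered:
        counts[r.partner] = counts.get(r.partner, 0) + 1
    best = max(counts.values())
    tied = [p for p, c in counts.items() if c == best]
    if len(tied) == 1:
        return tied[0]
    for r in partnered:  # method priority order (NJ first)
        if r.partner in tied:
            return r.partner
    return tied[0]


def _family_of(partner, refs_by_id):
    if partner is None or refs_by_id is None:
        return None
    r = refs_by_id.get(partner)
    return r.family if r is not None else None


# ---------------------------------------------------------------------------
# fixture-mode categorisation (printed bootstrap columns)


def categorize_printed(
    nj: str, mp: str, ml: str, whole_protein: bool = False
) -> int:
    """Category from printed bootstrap tokens (integers or n/m, n/m*)."""
    if whole_protein:
        return 4
    def strong(tok: str) -> bool:
        try:
            return float(tok) > 50.0
        except ValueError:
            return False
    n_strong = sum(strong(t) for t in (nj, mp, ml))
    n_partner = sum(t not in (NM, NM_FAMILY, "", "/") for t in (nj, mp, ml))
    if n_strong == 3:
        return 1
    if n_strong == 2:
        return 2
    if n_partner >= 1:
        return 3
    return 4


def calls_to_tsv(calls: Sequence[OrthologCall], path) -> None:
    """Write calls in the survey's gene-listing shape: candidate, assigned
    family, partner (homologue), per-method bootstrap tokens, category."""
    with open(path, "w") as fh:
        fh.write("candidate\tfamily\thomologue\tnj\tmp\tml\tcategory\tnote\n")
        for c in calls:
            tokens = {r.method: r.token() for r in c.results}
            fh.write(
                f"{c.candidate_id}\t{c.family or 'unresolved'}\t"
                f"{c.partner or '/'}\t{tokens.get('NJ', '/')}\t"
                f"{tokens.get('MP', '/')}\t{tokens.get('ML-surrogate', '/')}\t"
                f"{c.category}\t{c.sub_label}\n"
            )
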