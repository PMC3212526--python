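"""Translated motif scanning of genomic contigs with splice-aware chaining.

Each reference motif is scanned against all six reading frames of a contig
with an ungapped log-odds profile (PAM250 by default).  Motifs interrupted
by introns appear as two or more high-scoring sub-alignments whose genomic
spacing is the intron; these are chained into one multi-segment candidate
by a dynamic programme over query split points, constrained to canonical
``GT..AG`` intron boundaries, gap lengths within ``[min_intron_bp,
max_gap_bp]``, and at most three introns (the maximum seen in surveyed
motifs).  Each intron in a chain pays a fixed score penalty so that a
contiguous placement is always preferred when one explains the locus.

Scoring is deliberately permissive (low default threshold): the survey's
contract is to collect *all* bHLH-related loci and let the conserved-site
filter and phylogenetic assignment decide.  Candidates sharing a locus --
same contig, same strand, overlapping coding regions -- are deduplicated to
the single highest-scoring hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .catalog import ReferenceMotif
from .simulate import reverse_complement, segment_frame

SCAN_ALPHABET = "ACDEFGHIKLMNPQRSTVWYX*"
_IDX = {aa: i for i, aa in enumerate(SCAN_ALPHABET)}
_IUPAC = set("ACGTNRYSWKMBDHVU")


class ScanError(ValueError):
    pass


@dataclass(frozen=True)
class ScanConfig:
    """Knobs of the translated scan.

    score_threshold : minimum total log-odds score of a reported hit
        (PAM250 units); low by default so every bHLH-related locus is kept.
    max_gap_bp : maximum genomic gap bridged between chained sub-hits
        (default 50 kb, comfortably above the longest motif intron seen).
    min_intron_bp : shortest bridgeable gap.
    intron_penalty : score deducted per chained intron.
    piece_min_codons : shortest query piece the chainer will place.
    piece_rel_score : a piece must reach this fraction of its own
        perfect-match score to become a chaining candidate.
    """

    score_threshold: float = 60.0
    max_gap_bp: int = 50_000
    substitution_matrix: str = "PAM250"
    min_intron_bp: int = 60
    intron_penalty: float = 15.0
    piece_min_codons: int = 4
    piece_rel_score: float = 0.4
    max_introns: int = 3
    beam_width: int = 50
    max_chain_queries: int = 4
    #: splice-signal scoring: reward per matching base of the extended
    #: donor consensus (GT + donor_consensus_ext) and per pyrimidine in the
    #: window upstream of the acceptor AG; disambiguates true splice
    #: boundaries from chance GT..AG pairs.
    donor_consensus_ext: str = "AAG"
    donor_bonus_per_base: float = 2.0
    acceptor_pyrimidine_window: int = 8
    acceptor_bonus_per_base: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.score_threshold):
            raise ScanError("score_threshold must be finite")
        if self.max_gap_bp < 0:
            raise ScanError("max_gap_bp must be >= 0")


@dataclass(frozen=True)
class CandidateHit:
    """One (possibly intron-interrupted) motif locus on a contig."""

    contig_id: str
    frame: int  # frame label of the first coding segment, +1..+3 / -1..-3
    segments: tuple[tuple[int, int], ...]  # 1-based inclusive, reading order
    score: float
    translated_seq: str
    query_id: str
    segment_frames: tuple[int, ...] = ()

    @property
    def strand(self) -> str:
        return "+" if self.frame > 0 else "-"

    @property
    def extent(self) -> tuple[int, int]:
        coords = [c for seg in self.segments for c in seg]
        return min(coords), max(coords)


def scoring_matrix(name: str = "PAM250") -> np.ndarray:
    """Similarity matrix over SCAN_ALPHABET; X scores -1 against everything
    (ambiguity never counts as a match) and stops score -30."""
    S = substitution_matrices.load(name)
    n = len(SCAN_ALPHABET)
    M = np.full((n, n), -1.0)
    for i, a in enumerate(SCAN_ALPHABET[:20]):
        for j, b in enumerate(SCAN_ALPHABET[:20]):
            M[i, j] = S[a, b]
    M[_IDX["*"], :] = -30.0
    M[:, _IDX["*"]] = -30.0
    return M


def validate_contig(contig: str) -> str:
    contig = contig.upper()
    for m in re.finditer(f"[^{''.join(sorted(_IUPAC))}]", contig):
        raise ScanError(
            f"non-IUPAC character {m.group()!r} at position {m.start() + 1}"
        )
    return contig.replace("U", "T")


def _translate_positions(strand_seq: str) -> np.ndarray:
    """aa index (into SCAN_ALPHABET) of the codon starting at every 0-based
    position p of the strand sequence; length len(seq) - 2."""
    L = len(strand_seq)
    out = np.full(max(L - 2, 0), _IDX["X"], dtype=np.int8)
    for f in range(3):
        n_codons = (L - f) // 3
        if n_codons <= 0:
            continue
        prot = str(Seq(strand_seq[f: f + 3 * n_codons]).translate())
        idx = np.array([_IDX.get(c, _IDX["X"]) for c in prot], dtype=np.int8)
        out[f: f + 3 * (n_codons - 1) + 1: 3] = idx
    return out


def _prefix_scores(qidx: np.ndarray, aa: np.ndarray, M: np.ndarray,
                   pad: int) -> np.ndarray:
    """PS[p, k] = score of query[0:k] placed with first codon at padded
    position p (positions outside the sequence score as X)."""
    Lq = len(qidx)
    P = len(aa) + 2 * pad
    aa_ext = np.full(P + 3 * Lq, _IDX["X"], dtype=np.int8)
    aa_ext[pad: pad + len(aa)] = aa
    PS = np.zeros((P, Lq + 1), dtype=np.float32)
    base = np.arange(P)
    for k in range(Lq):
        PS[:, k + 1] = PS[:, k] + M[qidx[k], aa_ext[base + 3 * k]]
    return PS


def six_frame_scan(
    contig: str,
    queries: Sequence[ReferenceMotif],
    cfg: ScanConfig = ScanConfig(),
    contig_id: str = "contig",
) -> list[CandidateHit]:
    """Scan both strands of *contig* with every query motif.

    Returns all contiguous placements scoring at least the threshold plus
    all chained (intron-interrupted) placements; overlapping reports are
    resolved later by :func:`dedupe_hits`.
    """
    if len(contig) < 3:
        raise ScanError("contig shorter than one codon")
    if not queries:
        raise ScanError("no query motifs")
    contig = validate_contig(contig)
    M = scoring_matrix(cfg.substitution_matrix)
    L = len(contig)
    hits: list[CandidateHit] = []
    for strand in "+-":
        seq = contig if strand == "+" else reverse_complement(contig)
        aa = _translate_positions(seq)
        donor = np.zeros(L, dtype=bool)
        acceptor = np.zeros(L + 1, dtype=bool)
        donor_bonus = np.zeros(L)
        acceptor_bonus = np.zeros(L + 1)
        ext = cfg.donor_consensus_ext
        w = cfg.acceptor_pyrimidine_window
        for m in re.finditer("(?=GT)", seq):
            e = m.start()
            donor[e] = True
            tail = seq[e + 2: e + 2 + len(ext)]
            donor_bonus[e] = cfg.donor_bonus_per_base * sum(
                a == b for a, b in zip(tail, ext)
            )
        for m in re.finditer("(?=AG)", seq):
            s = m.start() + 2
            acceptor[s] = True
            window = seq[max(s - 2 - w, 0): s - 2]
            acceptor_bonus[s] = cfg.acceptor_bonus_per_base * sum(
                c in "CT" for c in window
            )
        # pass 1: contiguous placements for every query, plus the block
        # anchor ratio that flags a possibly intron-split locus
        ratios: list[tuple[float, int]] = []
        for iq, q in enumerate(queries):
            full_hits, ratio = _scan_full(
                seq, aa, q, M, cfg, contig_id, strand, L
            )
            hits.extend(full_hits)
            ratios.append((ratio, iq))
        # pass 2: splice-aware chaining for the best-anchored queries only
        # (the deduplication step keeps the best interpretation per locus,
        # so weaker same-family queries add nothing but time)
        ratios.sort(key=lambda t: (-t[0], t[1]))
        for ratio, iq in ratios[: cfg.max_chain_queries]:
            if ratio < 0.5:
                break
            hits.extend(
                _scan_chained(seq, aa, donor, acceptor, donor_bonus,
                              acceptor_bonus, queries[iq], M, cfg,
                              contig_id, strand, L)
            )
    return sorted(
        hits, key=lambda h: (h.contig_id, h.extent[0], -h.score, h.query_id)
    )


def _query_arrays(query, M):
    qidx = np.array([_IDX.get(c, _IDX["X"]) for c in query.sequence],
                    dtype=np.int8)
    self_scores = np.array(
        [M[qidx[k], qidx[k]] for k in range(len(qidx))], dtype=np.float64
    )
    return qidx, np.concatenate([[0.0], np.cumsum(self_scores)])


def _scan_full(seq, aa, query, M, cfg, contig_id, strand, L):
    """Contiguous placements of the whole query, plus the best quarter-block
    anchor ratio (at least one block of an intron-split motif is intron-free,
    so a low ratio certifies that chaining cannot recover anything here)."""
    qidx, cum_self = _query_arrays(query, M)
    Lq = len(qidx)
    pad = 3 * Lq
    PS = _prefix_scores(qidx, aa, M, pad)
    out: list[CandidateHit] = []
    full = PS[:, Lq]
    good = np.nonzero(full >= cfg.score_threshold)[0]
    for p in good:
        s0 = int(p) - pad
        if s0 < 0 or s0 + 3 * Lq > L:
            continue
        out.append(
            _make_hit(seq, aa, [(s0, 0, Lq)], float(full[p]), query,
                      contig_id, strand, L)
        )
    ratio = 0.0
    bounds = [round(i * Lq / 4) for i in range(5)]
    for b0, b1 in zip(bounds, bounds[1:]):
        block = PS[:, b1] - PS[:, b0]
        denom = cum_self[b1] - cum_self[b0]
        if denom > 0:
            ratio = max(ratio, float(block.max(initial=-np.inf)) / denom)
    return out, ratio


def _scan_chained(seq, aa, donor, acceptor, donor_bonus, acceptor_bonus,
                  query, M, cfg, contig_id, strand, L):
    qidx, cum_self = _query_arrays(query, M)
    Lq = len(qidx)
    pad = 3 * Lq
    PS = _prefix_scores(qidx, aa, M, pad)
    out: list[CandidateHit] = []
    pieces = _piece_candidates(PS, donor, acceptor, qidx, cum_self, cfg, pad, L)
    for chain, score in _chain_pieces(pieces, Lq, cfg, donor_bonus,
                                      acceptor_bonus):
        if score < cfg.score_threshold:
            continue
        segs = [(s, k0, k1) for (k0, k1, s, _sc) in chain]
        out.append(
            _make_hit(seq, aa, segs, score, query, contig_id, strand, L)
        )
    return out


def _piece_candidates(PS, donor, acceptor, qidx, cum_self, cfg, pad, L):
    """For each query split pair (k0, k1): boundary-compatible placements
    scoring at least piece_rel_score of the piece's perfect score."""
    Lq = len(qidx)
    cands: dict[tuple[int, int], list[tuple[int, float]]] = {}
    acc = acceptor[:L]
    for k0 in range(0, Lq - cfg.piece_min_codons + 1):
        if k0 != 0 and k0 < cfg.piece_min_codons:
            continue
        # PS rows for virtual start = s - 3*k0 + pad, s in [0, L)
        lo = pad - 3 * k0
        block = PS[lo: lo + L]
        for k1 in range(k0 + cfg.piece_min_codons, Lq + 1):
            if k1 != Lq and Lq - k1 < cfg.piece_min_codons:
                continue
            if k0 == 0 and k1 == Lq:
                continue  # contiguous case handled separately
            sc = block[:, k1] - block[:, k0]
            floor = cfg.piece_rel_score * (cum_self[k1] - cum_self[k0])
            ok = sc >= floor
            if k0 > 0:  # needs AG immediately upstream
                ok &= acc
            step = 3 * (k1 - k0)
            if k1 < Lq:  # needs GT immediately downstream
                ok[max(L - step, 0):] = False
                ok_idx = np.nonzero(ok)[0]
                ok_idx = ok_idx[donor[ok_idx + step]]
            else:
                ok[max(L - step + 1, 0):] = False
                ok_idx = np.nonzero(ok)[0]
            if ok_idx.size == 0:
                continue
            if ok_idx.size > cfg.beam_width:
                top = np.argsort(sc[ok_idx])[::-1][: cfg.beam_width]
                ok_idx = ok_idx[top]
            cands[(k0, k1)] = [(int(s), float(sc[s])) for s in ok_idx]
    return cands


def _chain_pieces(pieces, Lq, cfg, donor_bonus, acceptor_bonus):
    """Enumerate chains of 2..max_introns+1 boundary-linked pieces covering
    the whole query; yields (chain, total score).  Chains are built by a
    beam-limited DFS ordered deterministically."""
    # states at split k: list of (chain, end_genomic, score)
    results = []
    first = [
        ((0, k1, s, sc), k1, s + 3 * k1, sc)
        for (k0, k1), lst in sorted(pieces.items())
        if k0 == 0 and k1 < Lq
        for (s, sc) in lst
    ]
    frontier = [([p], k1, e, sc) for (p, k1, e, sc) in first]
    n_pieces = 1
    while frontier and n_pieces <= cfg.max_introns:
        nxt = []
        for chain, k, end, score in frontier:
            for (k0, k1), lst in sorted(pieces.items()):
                if k0 != k:
                    continue
                for (s, sc) in lst:
                    gap = s - end
                    if not (cfg.min_intron_bp <= gap <= cfg.max_gap_bp):
                        continue
                    piece = (k0, k1, s, sc)
                    new_score = (score + sc - cfg.intron_penalty
                                 + donor_bonus[end] + acceptor_bonus[s])
                    if k1 == Lq:
                        results.append((chain + [piece], new_score))
                    else:
                        nxt.append(
                            (chain + [piece], k1, s + 3 * (k1 - k0), new_score)
                        )
        nxt.sort(key=lambda t: -t[3])
        frontier = nxt[: cfg.beam_width * 4]
        n_pieces += 1
    # deterministic order, best first
    results.sort(key=lambda t: (-t[1], t[0][0][2]))
    return results


def _make_hit(seq, aa, segs, score, query, contig_id, strand, L):
    """segs: list of (genomic 0-based start on this strand, k0, k1)."""
    translated = "".join(
        SCAN_ALPHABET[aa[s + 3 * (k - k0)]]
        for (s, k0, k1) in segs
        for k in range(k0, k1)
    )
    coords = []
    for (s, k0, k1) in segs:
        b0, b1 = s, s + 3 * (k1 - k0) - 1  # 0-based inclusive on strand
        if strand == "+":
            coords.append((b0 + 1, b1 + 1))
        else:
            coords.append((L - b0, L - b1))
    frames = tuple(segment_frame(a, b, L) for a, b in coords)
    return CandidateHit(
        contig_id=contig_id,
        frame=frames[0],
        segments=tuple(coords),
        score=round(score, 4),
        translated_seq=translated,
        query_id=query.id,
        segment_frames=frames,
    )


# ---------------------------------------------------------------------------
# dedup


def _overlaps(a: CandidateHit, b: CandidateHit) -> bool:
    if a.contig_id != b.contig_id or a.strand != b.strand:
        return False
    (a0, a1), (b0, b1) = a.extent, b.extent
    return a0 <= b1 and b0 <= a1


def dedupe_hits(hits: Sequence[CandidateHit]) -> list[CandidateHit]:
    """Keep one hit per locus: cluster hits that share contig, strand and
    overlapping coding regions (transitively) and keep the highest-scoring
    member of each cluster.  Idempotent and order-independent; output sorted
    by (contig, leftmost coordinate)."""
    hits = sorted(
        hits,
        key=lambda h: (h.contig_id, h.strand, h.extent[0], h.extent[1],
                       -h.score, h.query_id, h.segments),
    )
    parent = list(range(len(hits)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            if hits[j].contig_id != hits[i].contig_id:
                break
            if _overlaps(hits[i], hits[j]):
                union(i, j)
    best: dict[int, CandidateHit] = {}
    for i, h in enumerate(hits):
        r = find(i)
        cur = best.get(r)
        if cur is None or (h.score, h.query_id) > (cur.score, cur.query_id):
            if cur is None or h.score > cur.score:
                best[r] = h
    return sorted(best.values(), key=lambda h: (h.contig_id, h.extent[0]))


def hits_to_tsv(hits: Iterable[CandidateHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tframe\tsegments\tscore\tquery_id\ttranslation\n")
        for h in hits:
            segtxt = ";".join(f"{a}-{b}" for a, b in h.segments)
            fh.write(
                f"{h.contig_id}\t{h.frame:+d}\t{segtxt}\t{h.score}\t"
                f"{h.query_id}\t{h.translated_seq}\n"
            )
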