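"""Synthetic genomes with planted, family-labelled, intron-split bHLH genes.

The generator emulates exactly the gene structures the survey has to
recover: a ~60-residue bHLH motif is drawn from a reference family, mutated
at a configurable per-site rate (optionally sparing the 19 conserved sites),
reverse-translated with a fixed codon table, split by 0-3 spliceosomal
introns (``GT..AG`` boundaries, inserted at codon boundaries), and embedded
on either strand of i.i.d. background sequence.  Ground truth (1-based
inclusive segment coordinates, per-segment reading frames, intron lengths
and the motif sub-region each intron interrupts) is recorded alongside, as
GFF3 plus a TSV mirror shaped like the survey's coding-region table.

Defaults mirror the surveyed repertoire: intron counts are drawn with the
frequencies observed across the 107 members (56% intronless, 24%/18%/2% with
one/two/three introns) and intron lengths are log-uniform on [60, 3000] bp --
short enough to keep simulated contigs small while exercising the same
splice geometry as the real table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import (
    DEFAULT_CONSERVED_SITES,
    DEFAULT_REGION_TEMPLATE,
    AMINO_ACIDS,
    ReferenceMotif,
)

#: Fixed reverse-translation table (one codon per amino acid).
CODON_OF = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

_COMP = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVHDB")

MIN_INTRON_BP = 60


class SimulationError(ValueError):
    pass


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def reverse_translate(motif: str) -> str:
    try:
        return "".join(CODON_OF[aa] for aa in motif)
    except KeyError as e:
        raise SimulationError(f"cannot reverse-translate residue {e}") from e


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Plan for one planted gene before realisation on a contig."""

    gene_id: str
    family: str
    motif_seq: str
    intron_plan: tuple[tuple[int, int], ...]  # (codon index, intron bp)
    strand: str  # '+' or '-'
    contig_id: str
    insertion_offset: int  # 0-based bp offset into the background

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SimulationError(f"bad strand {self.strand!r}")
        idxs = [k for k, _ in self.intron_plan]
        if idxs != sorted(set(idxs)):
            raise SimulationError("intron codon indices must strictly increase")
        if any(not 0 < k < len(self.motif_seq) for k in idxs):
            raise SimulationError("intron codon indices must be interior")
        if any(n < MIN_INTRON_BP for _, n in self.intron_plan):
            raise SimulationError(f"introns must be >= {MIN_INTRON_BP} bp")
        if len(self.intron_plan) > 3:
            raise SimulationError("at most 3 introns per gene")

    def intron_regions(
        self, template: Mapping[str, tuple[int, int]] = DEFAULT_REGION_TEMPLATE
    ) -> list[str]:
        """Sub-region of the downstream residue of each planned intron."""
        out = []
        for k, _ in self.intron_plan:
            for name, (a, b) in template.items():
                if a <= k < b:
                    out.append(name)
                    break
        return out


@dataclass(frozen=True)
class RealizedGene:
    spec: SyntheticGeneSpec
    #: 1-based inclusive coordinates in reading order; descending pairs on '-'.
    segments: tuple[tuple[int, int], ...]
    frames: tuple[int, ...]


@dataclass
class GroundTruth:
    genes: list[RealizedGene] = field(default_factory=list)
    background_gc: float = 0.42
    contig_lengths: dict[str, int] = field(default_factory=dict)


def segment_frame(start: int, end: int, contig_len: int) -> int:
    """Reading-frame label of a coding segment, +1..+3 / -1..-3.

    Plus-strand frames are numbered by offset of the segment start from the
    contig start; minus-strand frames by offset of the (higher-coordinate)
    reading start from the contig end.
    """
    if start <= end:
        return (start - 1) % 3 + 1
    return -((contig_len - start) % 3 + 1)


def mutate_motif(
    ref: ReferenceMotif | str,
    sub_rate: float,
    protect_conserved: bool = True,
    seed: int | np.random.Generator = 0,
    conserved_sites: Sequence[int] = DEFAULT_CONSERVED_SITES,
) -> str:
    """Independently substitute each unprotected site with prob. *sub_rate*."""
    if not 0.0 <= sub_rate <= 1.0:
        raise SimulationError("sub_rate must be in [0, 1]")
    seq = ref.sequence if isinstance(ref, ReferenceMotif) else ref
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    protected = set(conserved_sites) if protect_conserved else set()
    out = list(seq)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < sub_rate:
            choices = AMINO_ACIDS.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_intron(length: int, rng: np.random.Generator, gc: float) -> str:
    """Spliceosomal intron with realistic boundary signals: the extended
    donor consensus GTAAG, a polypyrimidine tract, and the terminal AG."""
    if length < MIN_INTRON_BP:
        raise SimulationError(f"intron length {length} < {MIN_INTRON_BP}")
    tract = "".join("CT"[rng.integers(2)] for _ in range(8))
    interior = random_background(length - 15, rng, gc)
    return "GTAAG" + interior + tract + "AG"


def random_background(length: int, rng: np.random.Generator, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def realize_gene(
    spec: SyntheticGeneSpec,
    background: str,
    rng: np.random.Generator | None = None,
    gc: float = 0.42,
    occupied: Sequence[tuple[int, int]] = (),
) -> tuple[str, RealizedGene]:
    """Embed one planted gene in *background*, returning the new contig and
    the realised ground-truth entry.

    The coding sequence is the fixed reverse translation of the motif;
    introns are inserted at the planned codon boundaries with ``GT..AG``
    termini.  Minus-strand genes are embedded as the reverse complement; the
    recorded segment coordinates then run in descending order so that the
    printed-table gap formula |downstream_start - upstream_end| - 1
    reproduces each planned intron length on either strand.
    """
    rng = rng or np.random.default_rng(0)
    cds = reverse_translate(spec.motif_seq)
    pieces: list[str] = []
    exon_spans: list[tuple[int, int]] = []  # 0-based within gene string
    cursor = 0
    prev = 0
    for codon_idx, intron_len in spec.intron_plan:
        exon = cds[prev * 3: codon_idx * 3]
        pieces.append(exon)
        exon_spans.append((cursor, cursor + len(exon)))
        cursor += len(exon)
        pieces.append(_random_intron(intron_len, rng, gc))
        cursor += intron_len
        prev = codon_idx
    exon = cds[prev * 3:]
    pieces.append(exon)
    exon_spans.append((cursor, cursor + len(exon)))
    cursor += len(exon)
    gene = "".join(pieces)

    off = spec.insertion_offset
    if off < 0 or off + len(gene) > len(background):
        raise SimulationError(
            f"{spec.gene_id}: gene of {len(gene)} bp does not fit at offset "
            f"{off} in background of {len(background)} bp"
        )
    for a, b in occupied:
        if off < b and a < off + len(gene):
            raise SimulationError(
                f"{spec.gene_id}: placement overlaps an existing gene"
            )

    if spec.strand == "+":
        contig = background[:off] + gene + background[off + len(gene):]
        segs = [(off + a + 1, off + b) for a, b in exon_spans]
    else:
        contig = (
            background[:off] + reverse_complement(gene)
            + background[off + len(gene):]
        )
        L = len(background)
        # gene-string position p maps to contig coordinate (1-based):
        # off + len(gene) - p  (reading 5'->3' on the minus strand)
        segs = [
            (off + len(gene) - a, off + len(gene) - (b - 1))
            for a, b in exon_spans
        ]
    frames = tuple(segment_frame(s, e, len(contig)) for s, e in segs)
    return contig, RealizedGene(spec=spec, segments=tuple(segs), frames=frames)


#: Intron-count frequencies matching the surveyed repertoire (107 members:
#: 60 / 26 / 19 / 2 with zero / one / two / three motif introns).
DEFAULT_INTRON_COUNT_PROBS = (60 / 107, 26 / 107, 19 / 107, 2 / 107)


@dataclass(frozen=True)
class GenomeParams:
    sub_rate: float = 0.05
    protect_conserved: bool = True
    intron_count_probs: tuple[float, ...] = DEFAULT_INTRON_COUNT_PROBS
    min_intron_bp: int = MIN_INTRON_BP
    max_intron_bp: int = 3000
    flank_bp: int = 400
    background_gc: float = 0.42
    minus_strand_prob: float = 0.5


def generate_genome(
    refs: Sequence[ReferenceMotif],
    n_genes: int = 20,
    family_weights: Mapping[str, float] | None = None,
    params: GenomeParams = GenomeParams(),
    seed: int = 0,
) -> tuple[dict[str, str], GroundTruth]:
    """Generate contigs (one planted gene per contig) plus ground truth.

    Deterministic for a fixed seed.  ``n_genes = 0`` yields a single
    background-only contig and empty truth.
    """
    if not refs:
        raise SimulationError("reference set required")
    rng = np.random.default_rng(seed)
    refs_by_family: dict[str, list[ReferenceMotif]] = {}
    for r in refs:
        refs_by_family.setdefault(r.family, []).append(r)
    families = sorted(refs_by_family)
    if family_weights:
        wts = np.array([family_weights.get(f, 0.0) for f in families])
        if wts.sum() <= 0:
            raise SimulationError("family weights sum to zero")
    else:
        wts = np.ones(len(families))
    wts = wts / wts.sum()

    contigs: dict[str, str] = {}
    truth = GroundTruth(background_gc=params.background_gc)
    if n_genes == 0:
        cid = "synctg000"
        contigs[cid] = random_background(2000, rng, params.background_gc)
        truth.contig_lengths[cid] = 2000
        return contigs, truth

    for g in range(n_genes):
        fam = families[rng.choice(len(families), p=wts)]
        members = refs_by_family[fam]
        ref = members[rng.integers(len(members))]
        motif = mutate_motif(
            ref, params.sub_rate, params.protect_conserved, rng
        )
        n_introns = int(
            rng.choice(len(params.intron_count_probs),
                       p=np.asarray(params.intron_count_probs))
        )
        n_codons = len(motif)
        # interior codon indices, kept >=4 codons from either motif end and
        # from each other so every exon carries enough signal to anchor
        lo, hi = 4, n_codons - 4
        idxs: list[int] = []
        if n_introns:
            while True:
                draw = sorted(
                    int(x)
                    for x in rng.choice(np.arange(lo, hi), size=n_introns,
                                        replace=False)
                )
                if all(b - a >= 4 for a, b in zip(draw, draw[1:])):
                    idxs = draw
                    break
        plan = tuple(
            (int(k), int(np.exp(rng.uniform(
                np.log(params.min_intron_bp), np.log(params.max_intron_bp)))))
            for k in idxs
        )
        strand = "-" if rng.random() < params.minus_strand_prob else "+"
        gene_bp = 3 * n_codons + sum(n for _, n in plan)
        bg_len = gene_bp + 2 * params.flank_bp
        background = random_background(bg_len, rng, params.background_gc)
        offset = int(rng.integers(params.flank_bp // 2,
                                  params.flank_bp * 3 // 2))
        cid = f"synctg{g + 1:03d}"
        spec = SyntheticGeneSpec(
            gene_id=f"gene{g + 1:03d}",
            family=fam,
            motif_seq=motif,
            intron_plan=plan,
            strand=strand,
            contig_id=cid,
            insertion_offset=offset,
        )
        contig, realized = realize_gene(
            spec, background, rng, params.background_gc
        )
        contigs[cid] = contig
        truth.contig_lengths[cid] = len(contig)
        truth.genes.append(realized)
    return contigs, truth


# ---------------------------------------------------------------------------
# truth / contig IO (plain-text formats only)


def write_contigs_fasta(contigs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for cid, seq in contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_truth_gff3(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rg in truth.genes:
            s = rg.spec
            coords = [c for seg in rg.segments for c in seg]
            lo, hi = min(coords), max(coords)
            fh.write(
                f"{s.contig_id}\tbhlh_survey\tgene\t{lo}\t{hi}\t.\t{s.strand}"
                f"\t.\tID={s.gene_id};family={s.family}\n"
            )
            for k, (a, b) in enumerate(rg.segments):
                lo, hi = min(a, b), max(a, b)
                fh.write(
                    f"{s.contig_id}\tbhlh_survey\tCDS\t{lo}\t{hi}\t.\t"
                    f"{s.strand}\t.\tID={s.gene_id}.cds{k + 1};"
                    f"Parent={s.gene_id};frame_label={rg.frames[k]}\n"
                )


def write_truth_tsv(truth: GroundTruth, path) -> None:
    """Table-2-shaped mirror: one row per coding segment, the intron that
    follows a segment annotated on that segment's row."""
    with open(path, "w") as fh:
        fh.write("family\tgene\tcontig\tframe\tstart\tend\t"
                 "intron_region\tintron_length\n")
        for rg in truth.genes:
            s = rg.spec
            regions = s.intron_regions()
            for k, (a, b) in enumerate(rg.segments):
                reg = regions[k] if k < len(s.intron_plan) else ""
                ln = str(s.intron_plan[k][1]) if k < len(s.intron_plan) else ""
                frame = rg.frames[k]
                fh.write(
                    f"{s.family}\t{s.gene_id}\t{s.contig_id}\t"
                    f"{'+' if frame > 0 else ''}{frame}\t{a}\t{b}\t{reg}\t{ln}\n"
                )


def spliced_motif(contig: str, segments: Sequence[tuple[int, int]]) -> str:
    """Extract reading-order segments, splice and translate; the inverse of
    :func:`realize_gene` (exact for generated genes)."""
    from Bio.Seq import Seq

    parts = []
    for a, b in segments:
        if a <= b:
            parts.append(contig[a - 1: b])
        else:
            parts.append(reverse_complement(contig[b - 1: a]))
    cds = "".join(parts)
    if len(cds) % 3:
        raise SimulationError("spliced length not divisible by 3")
    return str(Seq(cds).translate())
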