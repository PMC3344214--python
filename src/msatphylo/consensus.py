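"""Flank alignment, IUPAC consensus construction, and site-variation census.

Intraspecific flanks at a locus are near-identical, so a global
Needleman–Wunsch aligner with linear gap costs (match +1, mismatch −1,
gap −2 by default) extended center-star-wise ("once a gap, always a gap")
is sufficient and fully deterministic: trace-back prefers diagonal, then
up, then left.  The 5' and 3' flanks are aligned separately and joined at
a recorded junction so the repeat tract never contaminates the flank
alignment.

The per-column consensus is plurality-based; ties and (optionally) minority
variants are encoded with IUPAC ambiguity letters, which is how a
polymorphic site such as G/T appears as ``K`` in a published consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from Bio import Align
from Bio.Data.IUPACData import ambiguous_dna_values

logger = logging.getLogger(__name__)

#: frozenset of bases -> IUPAC ambiguity letter (single bases map to themselves).
IUPAC_FOR_BASES: dict[frozenset[str], str] = {}
for _code, _bases in ambiguous_dna_values.items():
    if _code == "X":  # alias of N
        continue
    IUPAC_FOR_BASES[frozenset(_bases)] = _code

#: IUPAC letter -> frozenset of bases it denotes.
BASES_FOR_IUPAC: dict[str, frozenset[str]] = {
    code: frozenset(bases) for code, bases in ambiguous_dna_values.items() if code != "X"
}


class AlignmentError(ValueError):
    """Raised on invalid alignment inputs (empty sets, ragged rows)."""


@dataclass(frozen=True)
class AlignScores:
    """Linear-gap alignment weights."""

    match: int = 1
    mismatch: int = -1
    gap: int = -2


class PairwiseAlignment(NamedTuple):
    a: str
    b: str
    score: int


def _biopython_aligner(scores: AlignScores) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scores.match
    aligner.mismatch_score = scores.mismatch
    aligner.open_gap_score = scores.gap
    aligner.extend_gap_score = scores.gap
    return aligner


def alignment_score(a: str, b: str, scores: AlignScores = AlignScores()) -> int:
    """Optimal global alignment score (score only; no trace-back)."""
    if not a or not b:
        raise AlignmentError("sequences must be nonempty")
    return int(_biopython_aligner(scores).score(a, b))


def _dp_matrix(a: str, b: str, scores: AlignScores) -> np.ndarray:
    """Full Needleman–Wunsch score matrix via a vectorized row scan.

    The in-row (leftward) gap dependency is resolved with a running maximum:
    H[i, j] = g*j + cummax_k<=j(candidate[k] - g*k).
    """
    n, m = len(a), len(b)
    g = scores.gap
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    H = np.empty((n + 1, m + 1), dtype=np.int64)
    jg = g * np.arange(m + 1, dtype=np.int64)
    H[0] = jg
    col0 = g * np.arange(n + 1, dtype=np.int64)
    base = np.empty(m + 1, dtype=np.int64)
    for i in range(1, n + 1):
        sub = np.where(b_arr == a_arr[i - 1], scores.match, scores.mismatch)
        base[0] = col0[i]
        np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + g, out=base[1:])
        H[i] = jg + np.maximum.accumulate(base - jg)
    return H


def pairwise_align(
    a: str, b: str, scores: AlignScores = AlignScores()
) -> PairwiseAlignment:
    """Optimal global alignment with deterministic trace-back.

    Trace-back preference at each cell: diagonal, then up (gap in ``b``),
    then left (gap in ``a``).
    """
    if not a or not b:
        raise AlignmentError("sequences must be nonempty")
    H = _dp_matrix(a, b, scores)
    g = scores.gap
    i, j = len(a), len(b)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = scores.match if a[i - 1] == b[j - 1] else scores.mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                out_a.append(a[i - 1])
                out_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        if i > 0 and H[i, j] == H[i - 1, j] + g:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), int(H[-1, -1]))


def _merge_into_msa(
    center_gapped: str, rows: list[str], gc: str, gs: str
) -> tuple[str, list[str], str]:
    """Merge a new (center, seq) pairwise alignment into an existing MSA.

    Gaps already present in the MSA are preserved ("once a gap, always a
    gap"); new center gaps introduce all-row gap columns.
    """
    i = j = 0
    new_center: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_s: list[str] = []
    len_c, len_g = len(center_gapped), len(gc)
    while i < len_c or j < len_g:
        c_ch = center_gapped[i] if i < len_c else None
        g_ch = gc[j] if j < len_g else None
        if c_ch == "-" and g_ch == "-":
            new_center.append("-")
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append(gs[j])
            i += 1
            j += 1
        elif c_ch == "-":
            new_center.append("-")
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append("-")
            i += 1
        elif g_ch == "-":
            new_center.append("-")
            for r in new_rows:
                r.append("-")
            new_s.append(gs[j])
            j += 1
        else:
            new_center.append(c_ch)
            for r, row in zip(new_rows, rows):
                r.append(row[i])
            new_s.append(gs[j])
            i += 1
            j += 1
    return "".join(new_center), ["".join(r) for r in new_rows], "".join(new_s)


def center_star_align(
    seqs: Sequence[str], scores: AlignScores = AlignScores()
) -> list[str]:
    """Center-star progressive multiple alignment.

    The center is the sequence with the maximal summed pairwise score
    against all others (ties broken by input order); every other sequence is
    aligned to the center pairwise and merged.  Rows are returned in input
    order.
    """
    if not seqs:
        raise AlignmentError("no sequences to align")
    if any(not s for s in seqs):
        raise AlignmentError("sequences must be nonempty")
    k = len(seqs)
    if k == 1:
        return [seqs[0]]
    if len(set(seqs)) == 1:
        return list(seqs)

    sums = np.zeros(k)
    for i in range(k):
        for j in range(i + 1, k):
            s = alignment_score(seqs[i], seqs[j], scores)
            sums[i] += s
            sums[j] += s
    center = int(np.argmax(sums))

    center_gapped = seqs[center]
    order = [center]
    rows: list[str] = []
    for idx in range(k):
        if idx == center:
            continue
        gc, gs, _ = pairwise_align(seqs[center], seqs[idx], scores)
        center_gapped, merged_rows, new_row = _merge_into_msa(center_gapped, rows, gc, gs)
        rows = merged_rows + [new_row]
        order.append(idx)

    all_rows = [center_gapped] + rows
    by_input = [""] * k
    for row, idx in zip(all_rows, order):
        by_input[idx] = row
    return by_input


@dataclass(frozen=True)
class FlankAlignment:
    """Joined intraspecific alignment of 5' and 3' flanks at one locus.

    ``junction`` is the number of columns belonging to the 5' side; ungapping
    ``row[:junction]`` / ``row[junction:]`` reproduces the original flank pair.
    """

    locus: str
    species: str
    rows: tuple[str, ...]
    junction: int

    def __post_init__(self) -> None:
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise AlignmentError(f"ragged alignment rows: widths {sorted(widths)}")

    @property
    def columns(self) -> int:
        return len(self.rows[0])


def progressive_align(
    flank_pairs: Sequence[tuple[str, str]],
    locus: str = "",
    species: str = "",
    scores: AlignScores = AlignScores(),
) -> FlankAlignment:
    """Center-star alignment of flank pairs; 5' and 3' sides aligned separately."""
    if not flank_pairs:
        raise AlignmentError("no flank pairs to align")
    rows5 = center_star_align([p[0] for p in flank_pairs], scores)
    rows3 = center_star_align([p[1] for p in flank_pairs], scores)
    rows = tuple(r5 + r3 for r5, r3 in zip(rows5, rows3))
    return FlankAlignment(locus=locus, species=species, rows=rows, junction=len(rows5[0]))


@dataclass(frozen=True)
class ConsensusSequence:
    """IUPAC consensus over one or more loci for one species.

    ``junctions`` holds the 1-based start position of each locus after the
    first (strictly increasing).
    """

    species: str
    loci: tuple[str, ...]
    sequence: str
    junctions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("consensus sequence must be nonempty")
        if list(self.junctions) != sorted(set(self.junctions)):
            raise ValueError("junctions must be strictly increasing")

    @property
    def length(self) -> int:
        return len(self.sequence)


def _column_consensus(bases: list[str], ambiguity_threshold: float) -> str:
    """Consensus call for the non-gap residues of one column."""
    counts: dict[str, int] = {}
    for b in bases:
        counts[b] = counts.get(b, 0) + 1
    total = len(bases)
    if ambiguity_threshold > 0:
        kept = {b for b, c in counts.items() if c / total >= ambiguity_threshold}
        if not kept:  # threshold above every frequency: keep the plurality set
            top = max(counts.values())
            kept = {b for b, c in counts.items() if c == top}
    else:
        top_base, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        if top / total > 0.5:
            return top_base
        kept = set(counts)
    if len(kept) == 1:
        return next(iter(kept))
    expanded: set[str] = set()
    for b in kept:
        expanded |= BASES_FOR_IUPAC[b]
    return IUPAC_FOR_BASES[frozenset(expanded)]


def build_consensus(
    aln: FlankAlignment,
    ambiguity_threshold: float = 0.0,
) -> ConsensusSequence:
    """Collapse an intraspecific flank alignment to a single IUPAC consensus.

    Per column: a residue with frequency > 1/2 is emitted directly; otherwise
    the IUPAC code of all residues at frequency >= ``ambiguity_threshold``
    (default: all observed) is emitted.  Columns where gaps are the majority
    are dropped — they represent insertions private to a minority of alleles.
    """
    out: list[str] = []
    n = len(aln.rows)
    for col in range(aln.columns):
        column = [row[col] for row in aln.rows]
        gaps = column.count("-")
        if gaps == n:
            logger.warning(
                "all-gap column %d dropped (%s/%s)", col + 1, aln.species, aln.locus
            )
            continue
        if gaps > n / 2:
            continue
        out.append(_column_consensus([b for b in column if b != "-"], ambiguity_threshold))
    return ConsensusSequence(
        species=aln.species, loci=(aln.locus,), sequence="".join(out)
    )


def concatenate_consensus(
    per_locus: Sequence[ConsensusSequence],
    locus_order: Sequence[str],
) -> ConsensusSequence:
    """Concatenate one species' per-locus consensus flanks in ``locus_order``."""
    if not per_locus:
        raise ValueError("no consensus sequences to concatenate")
    species = {c.species for c in per_locus}
    if len(species) > 1:
        raise ValueError(f"mixed species in concatenation: {sorted(species)}")
    by_locus: dict[str, ConsensusSequence] = {}
    for c in per_locus:
        if len(c.loci) != 1:
            raise ValueError("inputs must be single-locus consensus sequences")
        by_locus[c.loci[0]] = c
    missing = [loc for loc in locus_order if loc not in by_locus]
    if missing:
        raise ValueError(
            f"species {next(iter(species))!r} is missing consensus for loci: {missing}"
        )
    parts = [by_locus[loc].sequence for loc in locus_order]
    junctions = []
    pos = 1
    for part in parts[:-1]:
        pos += len(part)
        junctions.append(pos)
    return ConsensusSequence(
        species=next(iter(species)),
        loci=tuple(locus_order),
        sequence="".join(parts),
        junctions=tuple(junctions),
    )


@dataclass(frozen=True)
class SiteCensus:
    """Column-level variation census of a cross-species consensus alignment."""

    columns: int
    substitution_sites: int
    indel_sites: int
    indel_monomorphic: int
    indel_polymorphic: int
    pct_substitution: float
    pct_indel: float
    at_content: float
    gc_content: float
    no_variation: bool = False

    @property
    def variable_sites(self) -> int:
        return self.substitution_sites + self.indel_sites


def _sets_incompatible(residues: Iterable[str]) -> bool:
    """True if some pair of IUPAC residues has disjoint base sets."""
    sets = [BASES_FOR_IUPAC[r] for r in residues]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if not sets[i] & sets[j]:
                return True
    return False


def census_variation(rows: Sequence[str]) -> SiteCensus:
    """Census substitution and indel sites across aligned consensus rows.

    A column with any gap is an indel site (monomorphic when the non-gap
    residues are mutually compatible, polymorphic otherwise).  A gap-free
    column is a substitution site when two rows carry disjoint IUPAC base
    sets — overlapping ambiguity codes are compatible, not variable.
    Percentages are taken over variable sites; base composition over
    unambiguous non-gap residues.
    """
    if len(rows) < 2:
        raise ValueError("census requires at least two rows")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"row length mismatch: {sorted(widths)}")
    ncol = widths.pop()

    subs = indel_mono = indel_poly = 0
    at = gc = 0
    for col in range(ncol):
        column = [row[col] for row in rows]
        for b in column:
            if b in "AT":
                at += 1
            elif b in "GC":
                gc += 1
        nongap = [b for b in column if b != "-"]
        if len(nongap) < len(column):
            if _sets_incompatible(nongap):
                indel_poly += 1
            else:
                indel_mono += 1
        elif _sets_incompatible(nongap):
            subs += 1

    indels = indel_mono + indel_poly
    variable = subs + indels
    if variable:
        pct_sub = 100.0 * subs / variable
        pct_indel = 100.0 * indels / variable
    else:
        pct_sub = pct_indel = 0.0
    residues = at + gc
    return SiteCensus(
        columns=ncol,
        substitution_sites=subs,
        indel_sites=indels,
        indel_monomorphic=indel_mono,
        indel_polymorphic=indel_poly,
        pct_substitution=pct_sub,
        pct_indel=pct_indel,
        at_content=100.0 * at / residues if residues else 0.0,
        gc_content=100.0 * gc / residues if residues else 0.0,
        no_variation=variable == 0,
    )
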