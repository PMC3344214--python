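"""Published reference data for the four-species *Anguilla* microsatellite survey.

Six conserved dinucleotide loci cloned from the *Anguilla japonica* genome
(EMBL accessions AJ845112, AJ845113, AJ844913, AJ297601, AJ297603, AJ297605)
were amplified and cloned across four freshwater-eel species.  This module
transcribes the published per-species repeat-region notations and sequence
counts, and the published summary statistics of the flanking-region
consensus comparison (pairwise K2P distances, difference counts, Ts/Tv
extremes, site census).  These values serve as inputs for desk-scale
re-analysis and as calibration anchors for the simulator defaults.
"""

from __future__ import annotations

from .repeats import RepeatDecomposition, parse_notation_cell

#: Species codes used throughout.
SPECIES: dict[str, str] = {
    "J": "Anguilla japonica",
    "M": "Anguilla marmorata",
    "A": "Anguilla anguilla",
    "B": "Anguilla bicolor pacifica",
}

#: Locus -> repeat motif (cloned-strand orientation).
LOCUS_MOTIFS: dict[str, str] = {
    "AJ-1": "TG",
    "AJ-8": "TG",
    "AJ-9": "TG",
    "AJMS-3": "TG",
    "AJMS-6": "TG",
    "AJMS-10": "GA",
}

LOCUS_ORDER: tuple[str, ...] = tuple(LOCUS_MOTIFS)

#: (locus, species) -> (number of cloned sequences, repeat-region notation cell).
REPEAT_SURVEY: dict[tuple[str, str], tuple[int, str]] = {
    ("AJ-1", "J"): (11, "(TG)_7~13"),
    ("AJ-1", "M"): (17, "(TG)_6, 7, 8, 10; TC(TG)_6"),
    ("AJ-1", "A"): (10, "(TG)_5~10"),
    ("AJ-1", "B"): (11, "(TG)_7~9"),
    ("AJ-8", "J"): (12, "(TG)_14~18, 20"),
    ("AJ-8", "M"): (2, "(TG)_14, 15"),
    ("AJ-8", "A"): (11, "(TG)_12, 13, 15, 17, 19; (TG)_6(TA)(TG)_11"),
    ("AJ-8", "B"): (3, "(TG)_13, 22"),
    ("AJ-9", "J"): (11, "(TG)_8, 9, 11, 12, 14, 15; (TG)_8AG(TG)_10"),
    ("AJ-9", "M"): (9, "(TG)_14, 15, 17, 18, 19, 23, 27"),
    ("AJ-9", "A"): (
        12,
        "(TG)_12; (TG)_10, 19, 21AG(TG)_4\n(TG)_3CG(GT)_10,11\n(TG)_7CG(TG)_4AG(TG)_6",
    ),
    ("AJ-9", "B"): (8, "(TG)_9, 10, 13, 14(AG)_1, 2(TG)_9~12\n(TG)_5TA(TG)_3AG(TG)_11"),
    ("AJMS-3", "J"): (12, "(TG)_7~10"),
    ("AJMS-3", "M"): (9, "(TG)_7, 9, 10"),
    ("AJMS-3", "A"): (8, "(TG)_7, 10, 11; (TG)_3, 8CG(TG)_1, 4"),
    ("AJMS-3", "B"): (8, "(TG)_7, 8, 10"),
    ("AJMS-6", "J"): (18, "(TG)_9, 12~16, 18"),
    ("AJMS-6", "M"): (12, "(TG)_12, 13, 14, 16, 18, 19"),
    ("AJMS-6", "A"): (14, "(TG)_7, 10, 13, 14, 15"),
    ("AJMS-6", "B"): (16, "(TG)_12~18TA(TG)_0, 2"),
    ("AJMS-10", "J"): (12, "(GA)_10, 12, 14~16, 18~22, 35, 36, 39"),
    ("AJMS-10", "M"): (14, "(GA)_8~12, 14, 15, 17"),
    ("AJMS-10", "A"): (15, "(GA)_22\n(GA)_9, 12, 13, 15, 16, 17GG(GA)_6, 9, 10, 11,12"),
    ("AJMS-10", "B"): (
        19,
        "(GA)_13~15,17,19, 20, 22, 23, 26\n(GA)_6, 7GG(GA)_5, 12\n"
        "(GA)_7CA(GA)_12, 13; (GA)_9AT(GA)_9",
    ),
}

#: Consensus taxa in published order.
TAXA: tuple[str, ...] = ("J", "M", "B", "A")

#: Published pairwise K2P distances among concatenated consensus flanks.
K2P_DISTANCES: dict[frozenset[str], float] = {
    frozenset({"J", "M"}): 0.050,
    frozenset({"J", "B"}): 0.055,
    frozenset({"J", "A"}): 0.053,
    frozenset({"M", "B"}): 0.044,
    frozenset({"M", "A"}): 0.061,
    frozenset({"B", "A"}): 0.057,
}

#: Published pairwise total difference counts (Ts + Tv).
PAIRWISE_DIFFERENCES: dict[frozenset[str], int] = {
    frozenset({"J", "M"}): 22,
    frozenset({"J", "B"}): 24,
    frozenset({"J", "A"}): 23,
    frozenset({"M", "B"}): 20,
    frozenset({"M", "A"}): 27,
    frozenset({"B", "A"}): 25,
}

#: Smallest published pairwise Ts / Tv counts (M vs B) and the longest
#: concatenated consensus length.
MIN_PAIR: tuple[str, str] = ("M", "B")
MIN_PAIR_TS: int = 8
MIN_PAIR_TV: int = 12
CONSENSUS_LENGTH_RANGE: tuple[int, int] = (458, 469)

#: Published site census of the cross-species consensus comparison.
SUBSTITUTION_SITES: int = 44
INDEL_SITES: int = 27
INDEL_MONOMORPHIC: int = 23
INDEL_POLYMORPHIC: int = 4
AT_CONTENT_PCT: float = 51.16


def survey_decompositions(
    locus: str, species: str | None = None
) -> frozenset[RepeatDecomposition]:
    """Parse the survey notations for one locus (optionally one species)."""
    motif = LOCUS_MOTIFS[locus]
    decomps: frozenset[RepeatDecomposition] = frozenset()
    for (loc, sp), (_, cell) in REPEAT_SURVEY.items():
        if loc == locus and (species is None or sp == species):
            decomps |= parse_notation_cell(cell, motif)
    if not decomps:
        raise KeyError(f"no survey rows for locus {locus!r}, species {species!r}")
    return decomps


def sequence_count(locus: str | None = None) -> int:
    """Number of cloned sequences for one locus, or across all loci."""
    return sum(n for (loc, _), (n, _) in REPEAT_SURVEY.items() if locus in (None, loc))
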