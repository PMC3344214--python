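"""Repeat-region grammar, major-region detection, and Weber classification.

A microsatellite allele is modelled as ``flank5 + major + flank3`` where the
major region is an ordered list of motif runs — e.g. ``(TG)_8`` — and short
interruption literals (1–2 nt, e.g. ``AG``, ``TA``).  The notation dialect
used in published locus surveys is supported directly:

* ``(TG)_8AG(TG)_10``   — runs with integer subscripts, bare literals
* ``(TG)_7~13``         — a range of alternative alleles
* ``(TG)_6, 7, 8, 10``  — a comma list of alternative alleles
* ``(TA)``              — a parenthesized motif without subscript (count 1)

A comma list or range denotes alternative alleles.  When a pattern carries
several multi-valued subscripts of equal length they are read as positionally
paired alleles by default (``(TG)_3, 8CG(TG)_1, 4`` → two alleles, 3↔1 and
8↔4); otherwise the Cartesian product is expanded.  ``list_mode`` overrides
this.
"""

from __future__ import annotations

import itertools
import re
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .seq_io import LocusConfig, SequenceRecord


class NotationParseError(ValueError):
    """Raised when a repeat-notation string does not conform to the grammar."""


class NoMajorRegionError(ValueError):
    """Raised when no tandem array of the locus motif is found in an allele."""


class LocusMismatchError(ValueError):
    """Raised when alleles from different loci are mixed in one tabulation."""


@dataclass(frozen=True)
class RepeatRun:
    """A tandem array: ``count`` copies of a dinucleotide ``motif``."""

    motif: str
    count: int

    def __post_init__(self) -> None:
        if len(self.motif) != 2:
            raise ValueError(f"motif must be 2 nt, got {self.motif!r}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


Element = RepeatRun | str  # literal interruptions are plain strings


@dataclass(frozen=True)
class RepeatDecomposition:
    """Canonical decomposition of a major region into runs and literals.

    Canonical form: zero-count runs removed, adjacent runs of the same motif
    merged, and at least one run with count >= 1 present.
    """

    elements: tuple[Element, ...]
    locus_motif: str

    def __post_init__(self) -> None:
        if not any(isinstance(e, RepeatRun) and e.count >= 1 for e in self.elements):
            raise ValueError("decomposition must contain at least one run with count >= 1")
        for a, b in zip(self.elements, self.elements[1:]):
            if isinstance(a, RepeatRun) and isinstance(b, RepeatRun) and a.motif == b.motif:
                raise ValueError("adjacent runs of the same motif are not canonical")

    @property
    def runs(self) -> tuple[RepeatRun, ...]:
        return tuple(e for e in self.elements if isinstance(e, RepeatRun))

    @property
    def literals(self) -> tuple[str, ...]:
        return tuple(e for e in self.elements if isinstance(e, str))

    @property
    def total_units(self) -> int:
        """Total number of motif repeat units across all runs."""
        return sum(r.count for r in self.runs)

    def expand(self) -> str:
        return expand_decomposition(self)

    def serialize(self) -> str:
        return serialize_decomposition(self)

    def __len__(self) -> int:
        """Expanded nucleotide length."""
        return sum(2 * r.count for r in self.runs) + sum(len(s) for s in self.literals)


@dataclass(frozen=True)
class AlleleRecord:
    """A cloned allele split into 5' flank, major region, and 3' flank.

    ``major_span`` is the 1-based closed interval of the major region in the
    raw sequence.
    """

    record: SequenceRecord
    flank5: str
    major: RepeatDecomposition
    flank3: str
    major_span: tuple[int, int]

    def __post_init__(self) -> None:
        if self.flank5 + self.major.expand() + self.flank3 != self.record.sequence:
            raise ValueError(
                f"allele {self.record.id!r}: flank5 + expand(major) + flank3 "
                "does not reproduce the raw sequence"
            )
        start, end = self.major_span
        if start != len(self.flank5) + 1 or end != len(self.record.sequence) - len(self.flank3):
            raise ValueError(f"allele {self.record.id!r}: major_span inconsistent with flanks")


RepeatClass = Literal["perfect", "interrupted", "compound"]


# --- notation grammar -------------------------------------------------------

_RUN_RE = re.compile(r"\(([ACGT]{2})\)(?:_?((?:\d+(?:~\d+)?)(?:\s*,\s*\d+(?:~\d+)?)*)_?)?")
_LITERAL_RE = re.compile(r"[ACGT]+")


def _parse_spec(spec: str | None, pos: int) -> tuple[int, ...]:
    """Expand a subscript spec (integer, ``~``-range, comma list) to counts."""
    if spec is None:
        return (1,)
    counts: list[int] = []
    for part in re.split(r"\s*,\s*", spec.strip()):
        if "~" in part:
            lo_s, hi_s = part.split("~", 1)
            lo, hi = int(lo_s), int(hi_s)
            if hi < lo:
                raise NotationParseError(f"position {pos}: descending range {part!r}")
            counts.extend(range(lo, hi + 1))
        else:
            counts.append(int(part))
    return tuple(counts)


def _tokenize(text: str) -> list[tuple[str, str | tuple[int, ...]]]:
    """Split a notation string into ('run', (motif, counts)) / ('lit', str) tokens."""
    tokens: list[tuple[str, object]] = []
    pos = 0
    n = len(text)
    while pos < n:
        ch = text[pos]
        if ch.isspace() or ch == "_":
            pos += 1
            continue
        if ch == "(":
            m = _RUN_RE.match(text, pos)
            if not m:
                raise NotationParseError(
                    f"position {pos}: malformed run term near {text[pos:pos + 12]!r}"
                )
            motif, spec = m.group(1), m.group(2)
            tokens.append(("run", (motif, _parse_spec(spec, pos))))
            pos = m.end()
        elif ch == ")":
            raise NotationParseError(f"position {pos}: unbalanced ')'")
        else:
            m = _LITERAL_RE.match(text, pos)
            if not m:
                raise NotationParseError(f"position {pos}: unexpected character {ch!r}")
            tokens.append(("lit", m.group(0)))
            pos = m.end()
    if not tokens:
        raise NotationParseError("empty notation string")
    return tokens  # type: ignore[return-value]


def canonicalize(elements: Iterable[Element], locus_motif: str) -> RepeatDecomposition:
    """Drop zero-count runs and merge adjacent same-motif runs."""
    out: list[Element] = []
    for el in elements:
        if isinstance(el, RepeatRun) and el.count == 0:
            continue
        if (
            out
            and isinstance(el, RepeatRun)
            and isinstance(out[-1], RepeatRun)
            and out[-1].motif == el.motif
        ):
            out[-1] = RepeatRun(el.motif, out[-1].count + el.count)
        else:
            out.append(el)
    return RepeatDecomposition(elements=tuple(out), locus_motif=locus_motif)


def parse_repeat_notation(
    text: str,
    locus_motif: str,
    list_mode: Literal["auto", "paired", "cartesian"] = "auto",
) -> frozenset[RepeatDecomposition]:
    """Parse one notation pattern into the set of alleles it denotes.

    ``list_mode='auto'`` pairs multi-valued subscripts positionally when they
    all have the same length and otherwise expands the Cartesian product;
    ``'paired'`` and ``'cartesian'`` force one behaviour (``'paired'`` falls
    back to Cartesian when lengths differ).
    """
    tokens = _tokenize(text)
    choices: list[tuple[tuple[int, ...] | None, object]] = []
    for kind, payload in tokens:
        if kind == "run":
            motif, counts = payload  # type: ignore[misc]
            choices.append((counts, motif))
        else:
            choices.append((None, payload))

    multi_lengths = [len(c) for c, _ in choices if c is not None and len(c) > 1]
    paired = (
        list_mode in ("auto", "paired")
        and len(multi_lengths) >= 2
        and len(set(multi_lengths)) == 1
    )

    decomps: set[RepeatDecomposition] = set()
    if paired:
        width = multi_lengths[0]
        for k in range(width):
            elements: list[Element] = []
            for counts, payload in choices:
                if counts is None:
                    elements.append(payload)  # type: ignore[arg-type]
                else:
                    count = counts[k] if len(counts) > 1 else counts[0]
                    elements.append(RepeatRun(payload, count))  # type: ignore[arg-type]
            decomps.add(canonicalize(elements, locus_motif))
    else:
        pools = [
            [(payload, c) for c in counts] if counts is not None else [(payload, None)]
            for counts, payload in choices
        ]
        for combo in itertools.product(*pools):
            elements = [
                payload if count is None else RepeatRun(payload, count)  # type: ignore[list-item]
                for payload, count in combo
            ]
            decomps.add(canonicalize(elements, locus_motif))
    return frozenset(decomps)


def parse_notation_cell(
    text: str,
    locus_motif: str,
    list_mode: Literal["auto", "paired", "cartesian"] = "auto",
) -> frozenset[RepeatDecomposition]:
    """Parse a survey cell that may hold several ``;``/newline-separated patterns."""
    decomps: set[RepeatDecomposition] = set()
    for pattern in re.split(r"[;\n]", text):
        pattern = pattern.strip()
        if pattern:
            decomps |= parse_repeat_notation(pattern, locus_motif, list_mode)
    return frozenset(decomps)


def serialize_decomposition(d: RepeatDecomposition) -> str:
    """Serialize to the notation dialect; ``parse(serialize(d)) == {d}``."""
    parts = []
    for el in d.elements:
        if isinstance(el, RepeatRun):
            parts.append(f"({el.motif})_{el.count}")
        else:
            parts.append(el)
    return "".join(parts)


def expand_decomposition(d: RepeatDecomposition) -> str:
    """Concatenate motif repeats and literals into the nucleotide string."""
    return "".join(
        el.motif * el.count if isinstance(el, RepeatRun) else el for el in d.elements
    )


# --- major-region detection -------------------------------------------------


def _maximal_arrays(seq: str, motif: str) -> list[tuple[int, int, int]]:
    """All maximal exact tandem arrays of ``motif``: (start, end, units)."""
    out = []
    for m in re.finditer(f"(?:{motif})+", seq):
        units = (m.end() - m.start()) // 2
        out.append((m.start(), m.start() + 2 * units, units))
    return out


def decompose_major_region(record: SequenceRecord, cfg: LocusConfig) -> AlleleRecord:
    """Locate the major region of a raw allele and split off the flanks.

    Seeds are exact tandem arrays of the locus motif with at least
    ``cfg.min_seed_units`` units.  Arrays are merged across single
    interruption literals of <= 2 nt when a run of >= 1 unit flanks the
    literal on both sides.  Among merged candidate regions containing a seed,
    the one with the greatest nucleotide length wins; ties go to the leftmost.
    """
    seq = record.sequence
    if set(seq) - set("ACGT"):
        raise ValueError(f"allele {record.id!r}: raw sequence must be over ACGT")
    arrays = _maximal_arrays(seq, cfg.motif)
    if not any(units >= cfg.min_seed_units for _, _, units in arrays):
        raise NoMajorRegionError(
            f"no tandem array of ({cfg.motif})x{cfg.min_seed_units} found in allele "
            f"{record.id!r} at locus {cfg.name!r}"
        )

    # chain arrays separated by 1-2 nt interruptions
    chains: list[list[tuple[int, int, int]]] = []
    for arr in arrays:
        if chains and 1 <= arr[0] - chains[-1][-1][1] <= 2:
            chains[-1].append(arr)
        else:
            chains.append([arr])

    best: tuple[int, int, list[tuple[int, int, int]]] | None = None
    for chain in chains:
        if not any(units >= cfg.min_seed_units for _, _, units in chain):
            continue
        span = chain[-1][1] - chain[0][0]
        if best is None or span > best[1] - best[0]:
            best = (chain[0][0], chain[-1][1], chain)
    assert best is not None
    start, end, chain = best

    elements: list[Element] = []
    for i, (a_start, a_end, units) in enumerate(chain):
        if i > 0:
            elements.append(seq[chain[i - 1][1] : a_start])
        elements.append(RepeatRun(cfg.motif, units))
    major = canonicalize(elements, cfg.motif)
    return AlleleRecord(
        record=record,
        flank5=seq[:start],
        major=major,
        flank3=seq[end:],
        major_span=(start + 1, end),
    )


def classify_decomposition(d: RepeatDecomposition) -> RepeatClass:
    """Weber-style repeat typing from the canonical decomposition.

    perfect: a single run of the locus motif, no literals.  compound:
    adjacent runs of two different motifs, both >= 3 units, with no literal
    between them.  Everything else (literal interruptions, or a short <= 2
    unit run of another motif separating locus-motif runs) is interrupted.
    """
    runs = d.runs
    if len(d.elements) == 1 and isinstance(d.elements[0], RepeatRun):
        return "perfect"
    for a, b in zip(d.elements, d.elements[1:]):
        if (
            isinstance(a, RepeatRun)
            and isinstance(b, RepeatRun)
            and a.motif != b.motif
            and a.count >= 3
            and b.count >= 3
        ):
            return "compound"
    return "interrupted"


# --- per-locus summaries ----------------------------------------------------


def tabulate_locus(alleles: Sequence[AlleleRecord]) -> pd.DataFrame:
    """Summarize one locus per species: counts, patterns, repeat-number range.

    Columns: species, n_alleles, n_patterns, perfect_counts (sorted repeat
    numbers of perfect alleles), patterns (serialized decompositions),
    min_units, max_units, length_counts (allele-length histogram).
    """
    if not alleles:
        raise ValueError("empty allele list")
    loci = {a.record.locus for a in alleles}
    if len(loci) > 1:
        raise LocusMismatchError(f"mixed loci in one tabulation: {sorted(loci)}")

    rows = []
    for species in sorted({a.record.species for a in alleles}):
        mine = [a for a in alleles if a.record.species == species]
        decomps = [a.major for a in mine]
        perfect = sorted(
            {d.runs[0].count for d in decomps if classify_decomposition(d) == "perfect"}
        )
        patterns = sorted({d.serialize() for d in decomps})
        units = [d.total_units for d in decomps]
        lengths = Counter(len(a.record.sequence) for a in mine)
        rows.append(
            {
                "species": species,
                "n_alleles": len(mine),
                "n_patterns": len(patterns),
                "perfect_counts": perfect,
                "patterns": "; ".join(patterns),
                "min_units": min(units),
                "max_units": max(units),
                "length_counts": dict(sorted(lengths.items())),
            }
        )
    return pd.DataFrame(rows)


def max_run_count(
    decomps: Iterable[RepeatDecomposition],
    perfect_only: bool = False,
) -> int:
    """Largest run count across decompositions (optionally perfect ones only)."""
    best = -1
    for d in decomps:
        if perfect_only and classify_decomposition(d) != "perfect":
            continue
        best = max(best, max(r.count for r in d.runs))
    if best < 0:
        raise ValueError("no decompositions matched")
    return best
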