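"""Forward-time simulator of microsatellite allele pools on a 4-taxon tree.

The repeat tract evolves under the stepwise mutation model (SMM): each
generation a whole motif unit is gained or lost with probability
``slip_rate`` each, reflecting at one unit.  No sub-unit indel is ever
introduced into the major region; interrupted architectures arise only as
point substitutions inside the tract, which split a run into
run + 2 nt literal + run (e.g. ``(TG)_n AG (TG)_m``).  Flanks evolve by a
K2P substitution process (transition:transversion rate ratio ``kappa``)
plus rare 1-2 nt indels.

A species tree with two cherries and an internal edge drives interspecific
divergence; within-species allele pools are produced by additional
short-branch (star) evolution from each species ancestor.  The generating
split, ancestral sequences, and every allele's true decomposition are kept
as ground truth for recovery tests.

Default settings mirror the published four-eel study design: sampling
depths equal the published per-locus clone counts, branch lengths are a
least-squares fit of the published consensus distance matrix, base
composition is 51.16% A+T, and flank lengths put the concatenated consensus
near 467 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import reference_data
from .repeats import Element, RepeatDecomposition, RepeatRun, canonicalize
from .seq_io import LocusConfig, SequenceRecord, write_fasta, write_locus_config

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
#: K2P partner tables: index by current base.
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class LocusSim:
    """Per-locus simulation settings."""

    name: str
    motif: str
    ancestral_units: int
    flank5_len: int
    flank3_len: int


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation parameters; defaults reproduce the published study design.

    Branch lengths are expected substitutions per flank site.  The slippage
    and interruption clocks run in generations: a branch of length ``d``
    spans ``round(d * generations_per_branch)`` generations.
    """

    seed: int
    cherries: tuple[tuple[str, str], tuple[str, str]] = (("M", "B"), ("J", "A"))
    leaf_lengths: Mapping[str, float] = field(
        default_factory=lambda: {"J": 0.023, "A": 0.030, "M": 0.022, "B": 0.022}
    )
    internal_length: float = 0.008
    loci: tuple[LocusSim, ...] = (
        LocusSim("AJ-1", "TG", 9, 40, 38),
        LocusSim("AJ-8", "TG", 15, 45, 35),
        LocusSim("AJ-9", "TG", 12, 38, 38),
        LocusSim("AJMS-3", "TG", 8, 36, 40),
        LocusSim("AJMS-6", "TG", 14, 42, 36),
        LocusSim("AJMS-10", "GA", 15, 40, 39),
    )
    slip_rate: float = 0.005
    slip_min_units: int = 5
    interruption_rate: float = 1e-5
    flank_sub_rate: float = 0.004
    kappa: float = 1.5
    flank_indel_rate: float = 0.33
    alleles_per_species: Mapping[tuple[str, str], int] | None = None
    generations_per_branch: int = 20000
    at_fraction: float = 0.5116

    def __post_init__(self) -> None:
        for name, rate in (
            ("slip_rate", self.slip_rate),
            ("interruption_rate", self.interruption_rate),
            ("flank_sub_rate", self.flank_sub_rate),
            ("flank_indel_rate", self.flank_indel_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise SimulationConfigError(f"{name} must be in [0, 1], got {rate}")
        species = [s for cherry in self.cherries for s in cherry]
        if len(species) != 4 or len(set(species)) != 4:
            raise SimulationConfigError("cherries must name 4 distinct species")
        for sp in species:
            if sp not in self.leaf_lengths:
                raise SimulationConfigError(f"missing leaf length for species {sp!r}")
        for locus in self.loci:
            if locus.ancestral_units < 3:
                raise SimulationConfigError(
                    f"locus {locus.name!r}: ancestral_units must be >= 3"
                )
        for (loc, sp), n in self.depths_for_all().items():
            if n < 1:
                raise SimulationConfigError(f"depth for {loc}/{sp} must be >= 1")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for cherry in self.cherries for s in cherry)

    def depths_for_all(self) -> dict[tuple[str, str], int]:
        """Sampling depth per (locus, species); defaults to the published counts."""
        if self.alleles_per_species is not None:
            return dict(self.alleles_per_species)
        return {
            (locus.name, sp): reference_data.REPEAT_SURVEY[(locus.name, sp)][0]
            for locus in self.loci
            for sp in self.species
            if (locus.name, sp) in reference_data.REPEAT_SURVEY
        }

    def depths_for(self, locus: str) -> dict[str, int] | None:
        return {sp: n for (loc, sp), n in self.depths_for_all().items() if loc == locus}

    @property
    def split(self) -> frozenset[str]:
        """Generating unrooted split, normalized to exclude the smallest species."""
        species = set(self.species)
        smallest = min(species)
        side = set(self.cherries[0])
        return frozenset(species - side if smallest in side else side)


@dataclass
class TruthRecord:
    """Ground truth emitted alongside a simulated dataset."""

    split: frozenset[str]
    ancestral_flanks: dict[str, tuple[str, str]]
    species_flanks: dict[tuple[str, str], tuple[str, str]]
    species_major: dict[tuple[str, str], RepeatDecomposition]
    allele_major: dict[tuple[str, str], RepeatDecomposition]
    mutation_counts: dict[str, int]


@dataclass
class SimulatedDataset:
    """Per-locus allele pools plus ground truth and locus configuration."""

    config: SimulationConfig
    records: dict[str, list[SequenceRecord]]
    truth: TruthRecord
    locus_configs: dict[str, LocusConfig]


def evolve_repeat(
    count: int,
    steps: int,
    slip_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """SMM trajectory of a repeat number over ``steps`` generations.

    Each generation the count moves +1 or -1 with probability ``slip_rate``
    each; the walk reflects at one unit (a downward step from 1 is
    suppressed).  Returns the trajectory including the starting count
    (length ``steps + 1``).
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    deltas = rng.choice(
        [-1, 0, 1], size=steps, p=[slip_rate, 1.0 - 2.0 * slip_rate, slip_rate]
    )
    traj = np.empty(steps + 1, dtype=np.int64)
    traj[0] = count
    cur = count
    for i, delta in enumerate(deltas, start=1):
        cur = max(1, cur + int(delta))
        traj[i] = cur
    return traj


def evolve_flank(
    seq: str,
    branch_length: float,
    kappa: float,
    flank_indel_rate: float,
    rng: np.random.Generator,
) -> str:
    """Evolve a flank along a branch: K2P substitutions plus rare 1-2 nt indels.

    ``branch_length`` is the expected number of substitution events per
    site; per-site event counts are Poisson, and each event is a transition
    with probability ``kappa / (kappa + 2)``, otherwise a random
    transversion.  Indels strike each site with probability
    ``flank_indel_rate * branch_length`` and insert or delete 1-2 nt; they
    never touch the major region (which this function never sees).
    """
    if not seq:
        raise ValueError("flank must be nonempty")
    bases = list(seq)
    n_events = rng.poisson(branch_length, size=len(bases))
    p_ts = kappa / (kappa + 2.0)
    for site in np.nonzero(n_events)[0]:
        b = bases[site]
        for _ in range(int(n_events[site])):
            if rng.random() < p_ts:
                b = _TRANSITION[b]
            else:
                b = _TRANSVERSIONS[b][rng.integers(2)]
        bases[site] = b

    p_indel = flank_indel_rate * branch_length
    if p_indel > 0:
        hits = np.nonzero(rng.random(len(bases)) < p_indel)[0]
        for site in hits[::-1]:  # right to left keeps earlier indices valid
            length = int(rng.integers(1, 3))
            if rng.random() < 0.5 and len(bases) > length:  # deletion
                del bases[site : site + length]
            else:  # insertion
                ins = rng.choice(_BASES, size=length)
                bases[site:site] = list(ins)
    return "".join(bases)


def _evolve_major(
    decomp: RepeatDecomposition,
    generations: int,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    counters: dict[str, int],
) -> RepeatDecomposition:
    """Slippage (whole units, weighted by run length) plus rare interruptions.

    Slippage only strikes runs of at least ``cfg.slip_min_units`` units —
    replication slippage requires a misalignable array, so short tracts are
    effectively immobile and slippage frequency grows with repeat number.
    """
    elements: list[Element] = list(decomp.elements)

    def pick_run(rng: np.random.Generator, min_units: int = 1) -> int | None:
        idxs = [
            i
            for i, e in enumerate(elements)
            if isinstance(e, RepeatRun) and e.count >= min_units
        ]
        if not idxs:
            return None
        weights = np.array([elements[i].count for i in idxs], dtype=float)
        weights /= weights.sum()
        return idxs[rng.choice(len(idxs), p=weights)]

    n_slips = rng.binomial(generations, 2.0 * cfg.slip_rate)
    for _ in range(int(n_slips)):
        i = pick_run(rng, cfg.slip_min_units)
        if i is None:
            continue
        run = elements[i]
        step = 1 if rng.random() < 0.5 else -1
        elements[i] = RepeatRun(run.motif, max(1, run.count + step))
        counters["slips"] += 1

    total_sites = 2 * sum(e.count for e in elements if isinstance(e, RepeatRun))
    p_int = min(1.0, generations * cfg.interruption_rate)
    n_ints = rng.binomial(total_sites, p_int)
    for _ in range(int(n_ints)):
        i = pick_run(rng)
        if i is None:
            continue
        run = elements[i]
        unit = int(rng.integers(run.count))
        pos = int(rng.integers(2))
        old = run.motif[pos]
        new = rng.choice([b for b in "ACGT" if b != old])
        literal = run.motif[:pos] + new + run.motif[pos + 1 :]
        left = RepeatRun(run.motif, unit)
        right = RepeatRun(run.motif, run.count - unit - 1)
        replacement: list[Element] = []
        if left.count:
            replacement.append(left)
        replacement.append(literal)
        if right.count:
            replacement.append(right)
        elements[i : i + 1] = replacement
        counters["interruptions"] += 1
        if not any(isinstance(e, RepeatRun) and e.count >= 3 for e in elements):
            # The event would leave no detectable tandem array: such a lineage
            # would no longer be typed as a microsatellite at this locus
            # (ascertainment), so the event is rejected.
            elements[i : i + len(replacement)] = [run]
            counters["interruptions"] -= 1
    return canonicalize(elements, decomp.locus_motif)


def _random_flank(
    length: int,
    at_fraction: float,
    rng: np.random.Generator,
    motif: str,
    side: str,
) -> str:
    """Random flank that does not continue the repeat motif at the tract
    boundary (otherwise those bases would be part of the tract itself)."""
    p = np.array(
        [at_fraction / 2, (1 - at_fraction) / 2, (1 - at_fraction) / 2, at_fraction / 2]
    )
    while True:
        seq = "".join(rng.choice(_BASES, size=length, p=p))
        boundary = seq[-4:] if side == "5" else seq[:4]
        if motif not in boundary:
            return seq


def simulate_dataset(
    cfg: SimulationConfig,
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Simulate per-locus allele pools for four species along the species tree.

    Deterministic given ``cfg.seed``.  When ``out_dir`` is given, one FASTA
    per locus, a locus configuration file, a truth table, and a seed log are
    written there.
    """
    rng = np.random.default_rng(cfg.seed)
    depths = cfg.depths_for_all()
    records: dict[str, list[SequenceRecord]] = {}
    counters = {"slips": 0, "interruptions": 0}
    truth = TruthRecord(
        split=cfg.split,
        ancestral_flanks={},
        species_flanks={},
        species_major={},
        allele_major={},
        mutation_counts=counters,
    )
    locus_configs: dict[str, LocusConfig] = {}

    def gens(branch_length: float) -> int:
        return int(round(branch_length * cfg.generations_per_branch))

    for locus in cfg.loci:
        locus_configs[locus.name] = LocusConfig(name=locus.name, motif=locus.motif)
        root_f5 = _random_flank(locus.flank5_len, cfg.at_fraction, rng, locus.motif, "5")
        root_f3 = _random_flank(locus.flank3_len, cfg.at_fraction, rng, locus.motif, "3")
        truth.ancestral_flanks[locus.name] = (root_f5, root_f3)
        root_major = RepeatDecomposition(
            elements=(RepeatRun(locus.motif, locus.ancestral_units),),
            locus_motif=locus.motif,
        )

        def evolve_state(
            state: tuple[str, RepeatDecomposition, str], branch_length: float
        ) -> tuple[str, RepeatDecomposition, str]:
            f5, major, f3 = state
            f5 = evolve_flank(f5, branch_length, cfg.kappa, cfg.flank_indel_rate, rng)
            f3 = evolve_flank(f3, branch_length, cfg.kappa, cfg.flank_indel_rate, rng)
            major = _evolve_major(major, gens(branch_length), cfg, rng, counters)
            return f5, major, f3

        root_state = (root_f5, root_major, root_f3)
        # the root sits at the midpoint of the internal edge
        cherry_states = [
            evolve_state(root_state, cfg.internal_length / 2.0) for _ in cfg.cherries
        ]

        locus_records: list[SequenceRecord] = []
        for cherry, cherry_state in zip(cfg.cherries, cherry_states):
            for sp in cherry:
                sp_state = evolve_state(cherry_state, cfg.leaf_lengths[sp])
                truth.species_flanks[(locus.name, sp)] = (sp_state[0], sp_state[2])
                truth.species_major[(locus.name, sp)] = sp_state[1]
                depth = depths.get((locus.name, sp), 1)
                for i in range(depth):
                    f5, major, f3 = evolve_state(sp_state, cfg.flank_sub_rate)
                    allele_id = f"{sp}{i + 1:02d}"
                    seq = f5 + major.expand() + f3
                    locus_records.append(
                        SequenceRecord(
                            id=allele_id, species=sp, locus=locus.name, sequence=seq
                        )
                    )
                    truth.allele_major[(locus.name, allele_id)] = major
        records[locus.name] = locus_records

    dataset = SimulatedDataset(
        config=cfg, records=records, truth=truth, locus_configs=locus_configs
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: SimulatedDataset, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for locus, recs in dataset.records.items():
        write_fasta(recs, out_dir / f"{locus}.fasta")
    write_locus_config(dataset.locus_configs, out_dir / "loci.cfg")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("locus\tallele\ttrue_pattern\ttrue_units\n")
        for (locus, allele_id), major in sorted(dataset.truth.allele_major.items()):
            fh.write(f"{locus}\t{allele_id}\t{major.serialize()}\t{major.total_units}\n")
    with open(out_dir / "seed.log", "w") as fh:
        fh.write(f"seed={dataset.config.seed}\n")
        fh.write(f"split={'|'.join(sorted(dataset.truth.split))}\n")


def validate_major_regions(dataset: SimulatedDataset) -> None:
    """Assert the no-sub-unit-indel invariant on every emitted allele.

    Every allele must decompose as flank5 + expand(true major) + flank3 with
    the true major present verbatim, every interruption literal must be 1-2
    nt, and every run must hold at least one whole unit.
    """
    for locus, recs in dataset.records.items():
        for rec in recs:
            major = dataset.truth.allele_major[(locus, rec.id)]
            if major.expand() not in rec.sequence:
                raise AssertionError(
                    f"allele {rec.id} at {locus}: major region corrupted"
                )
            for lit in major.literals:
                if not 1 <= len(lit) <= 2:
                    raise AssertionError(
                        f"allele {rec.id} at {locus}: literal {lit!r} outside 1-2 nt"
                    )
            if any(r.count < 1 for r in major.runs):
                raise AssertionError(f"allele {rec.id} at {locus}: empty run")
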