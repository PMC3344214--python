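# msatphylo

Microsatellite repeat-architecture analysis and flanking-region phylogenetics
for *Anguilla* freshwater eels.

Cross-species microsatellite panels carry two signals at once. The tandem
repeat tract (the **major region**) mutates rapidly by replication slippage —
whole-unit gains and losses under the stepwise mutation model (SMM) — and by
occasional point substitutions that turn a perfect array such as `(TG)_19`
into an interrupted one such as `(TG)_8AG(TG)_10`. The unique **flanking
regions** on either side evolve slowly, by point substitutions and rare 1–2 nt
indels, and behave like ordinary phylogenetic sequence. `msatphylo` separates
and exploits both: it decomposes cloned allele sequences into
`flank5 + major + flank3`, classifies repeat architectures
(perfect / interrupted / compound), collapses intraspecific allele pools into
IUPAC consensus flanks, concatenates homologous flanks across loci, and infers
an unrooted phylogeny from Kimura two-parameter (K2P) distances

d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

(P, Q the transition and transversion proportions over the pairwise-comparable
length) with neighbor-joining and bootstrap support. The motivating dataset is
a panel of six conserved GA/TG dinucleotide loci (AJ-1, AJ-8, AJ-9, AJMS-3,
AJMS-6, AJMS-10; EMBL AJ845112, AJ845113, AJ844913, AJ297601, AJ297603,
AJ297605) cloned across four eels: *A. japonica* (J), *A. marmorata* (M),
*A. bicolor pacifica* (B) and *A. anguilla* (A) — 274 cloned sequences whose
published per-species repeat notations and consensus summary statistics ship
with the package (`msatphylo.reference_data`).

Because the individual cloned sequences are not published, the package also
includes a forward-time simulator (`msatphylo.synthetic_data`) that evolves
allele pools along a known 4-taxon species tree — SMM slippage in the tract,
transition-biased K2P substitutions and rare short indels in the flanks — and
keeps full ground truth, so every stage of the pipeline can be validated on
data with the same statistical structure as the study's.

## Worked example

```python
from msatphylo.pipeline import RunConfig, run_pipeline
from msatphylo.synthetic_data import SimulationConfig, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=11))   # 274 alleles, 6 loci
report = run_pipeline(RunConfig(
    locus_configs=dataset.locus_configs,
    locus_order=[l.name for l in dataset.config.loci],
    records_by_locus=dataset.records,
    bootstrap_reps=100, seed=3,
))
print(report.newick)
```

prints

```
((A:0.026,J:0.023)94:0.008,B:0.038,M:0.022);
```

an unrooted quartet whose single internal edge (bootstrap support 94) joins
*A. japonica* with *A. anguilla* on one side — equivalently, pairs
*A. marmorata* with *A. bicolor pacifica* — with branch lengths in
substitutions/site. The same run reports a Ts/Tv-resolved distance matrix
(K2P distances above the diagonal, raw difference counts below), a site
census of the cross-species consensus alignment (here 50 substitution and 28
indel sites over 480 columns), and per-locus repeat-architecture tables.

The same analysis is scriptable from a shell:

```bash
msatphylo simulate --seed 11 --out sim/
msatphylo run --loci sim/loci.cfg \
    --fasta AJ-1 sim/AJ-1.fasta ... --out run/ --reps 1000 --seed 3
msatphylo decompose --loci sim/loci.cfg --locus AJ-1 sim/AJ-1.fasta
msatphylo tree run/consensus_aligned.fasta --reps 1000 --seed 5
```

Running neighbor-joining directly on the published four-species distance
matrix reproduces the study-level conclusion:

```python
from msatphylo import reference_data as ref
from msatphylo.distphylo import DistanceMatrix, neighbor_joining
tree = neighbor_joining(DistanceMatrix.from_pairs(ref.TAXA, ref.K2P_DISTANCES))
print(tree.splits())   # {frozenset({'M', 'B'})}
```

the tropical species pair, i.e. a *japonica* + *anguilla* sister grouping is
rejected in the unrooted 4-taxon sense.

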