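# netkd — discrete signed-network simulation of receptor knockdowns

`netkd` is a pipeline for qualitative, discrete-time simulation of gene
interaction networks assembled from KEGG pathways. It was built to study how
the insulin receptor (INSR) and the IGF1 receptor (IGF1R) — two receptors
that share most of their downstream signaling machinery yet drive different
biology — differ in the genes they control. The workflow: merge KEGG KGML
pathway files into one weighted signed network, discretize baseline
expression (e.g. microarray intensities of untreated cells) onto a 0–9
grayscale of integer levels, simulate a ligand-boosted control scenario and
two in-silico receptor knockdowns for 100 synchronous steps, and report
which genes' simulated trajectories diverge from the control run.

## Model

The network is a directed multigraph. Each edge carries an interaction kind
from KGML (activation, inhibition, expression, phosphorylation,
ubiquitination, binding/association, …) and an integer weight: +2 for
positive influences (activation, expression, phosphorylation,
binding/association), −1 for negative ones (inhibition, repression,
dephosphorylation, ubiquitination, dissociation), 0 for uninformative kinds.
Every node additionally carries a *self-inhibition* loop of weight −1
modeling degradation.

Node states are integer levels `x_i ∈ {0,…,9}` (0 = not detectable,
9 = maximal). All nodes update synchronously:

```
x_i(t+1) = clamp( x_i(t) + Σ_{e:(j→i)} w_e · 1[x_j(t) > 0] − 1[x_i(t) > 0],
                  0, max(9, x_i(t)) )
```

where the final −1 term is the degradation loop. Scenario overrides may set
initial values above 9 (a ligand forced to 20 stays active for 20 steps as
it decays by one per step); the clamp lets such values decay naturally but
never grow. The update is deterministic, so two runs with identical inputs
are identical to the last integer.

A *knockdown scenario* overrides a receptor and its ligand to 0; the
*control* boosts both ligands (INS, IGF1) to 20 so the signal reaches deep
into the network before fading. A gene is *changed* when its trajectory
differs from the control at any step; changed sets of the two knockdowns are
partitioned into a Venn diagram (KD-specific vs shared responders). Static
analyses complement the dynamics: multi-source shortest-path distances from
the ligands (which lower-bound how early a perturbation can reach a gene,
since influence travels one edge per step), and the induced subnetwork on
focal genes plus their direct interactors.

## Worked example

The package ships a 22-node miniature of the INS/IGF1 receptor system
(`netkd.ins_igf1_miniature`): two ligands feeding their receptors, a shared
HRAS→AKT3→MTOR core held below saturation by a constitutive RAS-GAP brake,
an IGF1R-specific JAK1→STAT3 branch, an INSR-specific SH2B2→CBLC branch, and
a TP53→ATM→CHEK2 checkpoint chain seven edges downstream of the ligands.

```python
from netkd import (ins_igf1_miniature, average_replicates,
                   normalize_to_levels, receptor_kd_scenarios,
                   run_simulation, changed_genes, venn_partition)

net, table = ins_igf1_miniature()
baseline = normalize_to_levels(average_replicates(table))
runs = {s.name: run_simulation(net, baseline, s)
        for s in receptor_kd_scenarios()}
igf = changed_genes(runs["control"], runs["IGF1R-KD"])
ins = changed_genes(runs["control"], runs["INSR-KD"])
venn = venn_partition(igf, ins)
print(len(igf.changed), len(ins.changed))
print(sorted(venn.only_a), sorted(venn.only_b))
```

prints

```
14 12
['CCND1', 'IGF1', 'IGF1R', 'JAK1', 'SOD2', 'STAT3'] ['CBLC', 'INS', 'INSR', 'SH2B2']
```

i.e. 14 genes respond to the IGF1R knockdown and 12 to the INSR knockdown;
each receptor's own branch appears only in its own knockdown's changed set,
while the 8 shared-core genes (HRAS, AKT3, MTOR, TP53, ATM, CHEK2, CDKN1A,
CASP3) change under both. The checkpoint gene CHEK2 tracks the control
trajectory exactly up to step 68 and then decays to zero two steps earlier
than in the control — the signature of a perturbation arriving through a
long cascade late in the run.

The same workflow runs from the shell on real inputs:

```sh
netkd build pathway1.xml pathway2.xml ... --out network.graphml
netkd simulate --network network.graphml --expression expr.tsv --out runs/
netkd compare --reference runs/trajectory_control.csv \
    --test runs/trajectory_IGF1R-KD.csv --test runs/trajectory_INSR-KD.csv \
    --out comparison.json
netkd distance --network network.graphml --source INS --source IGF1 --target CHEK2
netkd reduce --network network.graphml --seed-gene CHEK2 --seed-gene TP53 --out reduced.sif
```

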