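# cationet

Systematic enumeration of terpenoid carbocation rearrangement networks.

## The problem

Terpenoid synthases build most of the structural diversity of terpenes by
steering a single linear substrate cation through cascades of carbocation
rearrangements.  For monoterpenes the substrate is geranyl diphosphate;
ionization gives the linear allylic C10H17+ cation, and everything a
monoterpene synthase can make is, at the skeleton level, determined by
which carbocationic intermediates are reachable from it.  Because the vast
majority of putative terpene synthase sequences have no functional
annotation, a map of the *complete* reachable product space — known
skeletons and plausible-but-unobserved ones — is a prerequisite for
predicting or engineering function.

`cationet` builds that map.  Starting from one or more seed cations it
applies five rearrangement operators known from terpene synthase
mechanisms:

1. **intramolecular alkylation** of a C=C (ring formation),
2. **1,2-alkyl shifts** (excluding methyls; ring expansion/contraction),
3. **hydride shifts**,
4. **1,2-methyl shifts**,
5. **intramolecular proton transfers** (deprotonation β to the cation with
   concerted protonation of a remote alkene),

plus zero-step allylic **resonance** edges.  Each operator is a pure edit
on an explicit-hydrogen molecular graph.  Products are deduplicated by
canonical SMILES, optionally filtered for stability, and assembled into a
directed reaction network (nodes = cations, edges = virtual reactions)
closed breadth-first over rounds.  The network is then clustered into
**skeletons** — the neutralized carbon framework with saturated side
chains pruned — each classified by ring topology (monocyclic, bridged,
fused, spiro, separated) and annotated with the shortest reaction route
from the substrate.

Enumeration is validated against an independent brute-force oracle: with
the three shift operators alone, enumeration from a linear alkane cation
must reproduce every constitutional CnH(2n+1)+ isomer, which the oracle
constructs directly (all carbon trees × all H-bearing charge placements).

## Worked example

Validate the engine against the alkane-cation oracle:

```
$ cationet validate-alkanes --carbons 4..8
n       found   oracle  match
4       4       4       True
5       8       8       True
6       17      17      True
7       39      39      True
8       89      89      True
```

The counts are the constitutional alkyl-cation isomers (4 for butyl: 1-,
2-, iso- and tert-butyl), found identically by the reaction engine and by
direct construction.

Enumerate two rounds from the α-terpinyl-type cation (the 1,6-cyclization
intermediate) and cluster the result:

```
$ cationet enumerate --seed "CC1=CCC([C+](C)C)CC1" --rounds 2 --out run/
110 nodes, 420 edges -> run/
$ cationet skeletons run/
17 cyclic skeletons (17 total): bridged=5, fused=4, monocyclic=8
```

110 distinct C10H17+ cations are reachable in two steps, pooling into 17
cyclic skeletons.  The report (`run/skeletons.tsv`) starts:

```
framework_key  topology    n_carbocation  log10_n  min_step  is_ec_reference
C1=CCCCC1      monocyclic  25             1.398    2         True
C1=CCCCCC1     monocyclic  20             1.301    3         False
C=C1CCCCC1     monocyclic  11             1.041    3         False
```

The cyclohexene framework (`C1=CCCCC1`) is the menthane-type skeleton of
limonene and its relatives; `n_carbocation` counts member cations and
`min_step` the shortest route to the skeleton.  A route query prints the
reaction chain:

```
$ cationet route run/ "C[C+]1CCC2CC1C2(C)C"
step count: 3
CC1=CCC([C+](C)C)CC1
  --[alkylation]--> C[C+]1CCC2CC1C2(C)C
```

— the pinyl-type cation, one ring closure beyond α-terpinyl; its pruned
framework is the bicyclo[3.1.1]heptane (pinane) skeleton of α-pinene.

For the full study conditions, the default monoterpene run

```
$ cationet enumerate --out study/      # linear C10H17+ seed, 10 rounds
```

reaches 34445 cations connected by 718355 directed reaction events and
102 cyclic skeletons, including all five monoterpene skeletons associated
with EC numbers (menthane, pinane, bornane, thujane and carane frames).

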