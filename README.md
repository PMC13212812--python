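# esmscreen

Sequence-level screening for **electrostatic-switch** hallmarks in P-type
ATPase catalytic subunits — and, more generally, in any multi-pass membrane
protein with cytoplasmic terminal tails.

## The problem

Peripheral membrane proteins are often held at the negatively charged
cytoplasmic leaflet of a membrane by a polybasic cluster of lysines and
arginines; phosphorylation of nearby serine/threonine/tyrosine residues
neutralises the local positive charge and releases the protein — the
electrostatic switch. Integral membrane pumps such as the Na⁺,K⁺-ATPase may
use the same trick with their cytoplasmic N- or C-terminal tails. This
package finds the sequence hallmarks of such a switch:

1. a terminal tail on the cytoplasmic side of the membrane (derived from a
   transmembrane topology annotation, e.g. DeepTMHMM output);
2. a **polybasic cluster**: ≥ `min_basic` K/R residues (default 9) within a
   sliding window of `window_len` residues (default 30), scanned at step 1
   over the `search_depth` residues nearest the terminus (default 100);
3. a **potential phosphosite**: an S/T/Y inside the qualifying window union
   or within `phospho_flank` residues of it (default 5), clipped to the
   tail.

A terminus satisfying all three is a *candidate*. Per tail the screen also
reports the K+R density (#K + #R divided by full tail length) and a
Henderson–Hasselbalch net side-chain charge at pH 7. A distance-based
phylogenetic stage (gap-fraction column trimming at the > 25% rule, p or
Poisson distances, neighbor joining, nonparametric bootstrap) places
candidates in their family context.

Because real inputs are external (curated sequences plus a topology
predictor), the package ships a synthetic-data generator that emulates
P-type-ATPase-like architectures with ground-truth topology and planted
clusters, plus an exact binomial null model for how often a qualifying
window arises by chance.

## Worked example

Generate a small cohort with two detectable plants (one N-terminal, one
C-terminal) and one decoy cluster lacking a phosphosite, then screen it:

```sh
cat > demo.yaml <<'EOF'
n_proteins: 8
seed: 11
background_basic_prob: 0.0
background_phospho_prob: 0.0
plants:
  0: {terminus: N}
  1: {terminus: C}
  2: {terminus: N, include_phospho: false}
EOF
esmscreen simulate --spec demo.yaml --outdir sim
esmscreen screen --sequences sim/cohort.fasta \
    --topology sim/cohort.topology.txt --out screen/report.tsv
```

The screen prints:

```json
{
  "config_hash": "eeb5c943a592",
  "n_only": 1,
  "c_only": 1,
  "both": 0,
  "unique_candidates": 2,
  "additional_candidates": 2,
  "n_screened": 8,
  "n_unscreened": 0,
  "unscreened": []
}
```

Two of the three planted clusters qualify; the third has nine basics but no
phosphosite within reach, so it is rejected — the phosphosite conjunct is
part of the candidate definition. The first report row shows protein
`SYN0000` with a 41-residue cytoplasmic N-tail, K+R density 0.219512, window
union 8–41, basic span 29–37 (9 basics) and an attached serine at position
39 (coordinates are 1-based protein positions):

```
protein_id  family  terminus  tail_start  tail_end  tail_length  cytoplasmic  kr_density  ...  cluster_basic_span  n_basic  phosphosites  is_candidate
SYN0000     unknown N         1           41        41           True         0.219512    ...  29-37               9        S39           True
```

The phylogenetic stage on a toy 4-sequence alignment:

```sh
esmscreen phylo --alignment aln.fasta --outdir phy --seed 3 --replicates 50
```

```
trimmed 0 of 18 columns (gap fraction > 0.25)
```

yielding `phy/tree.nwk` with a fully supported split:

```
((A:0.000000,B:0.091408)100:0.757709,C:0.000000,D:0.034249);
```

The `100` is the bootstrap percentage of the A,B | C,D bipartition; branch
lengths are substitutions per site under the chosen distance model.

As a library:

```python
from esmscreen import ScreenConfig, read_fasta, read_topology, screen_proteome

records = read_fasta("proteins.fasta")
topologies = read_topology("topology.txt", dialect="threeline")
result = screen_proteome(records, topologies, ScreenConfig())
print(result.summary)          # candidate counts by terminus
result.table                   # per-terminus pandas DataFrame
```

## What this package does not do

It does not predict topology (DeepTMHMM output is consumed, not produced),
align sequences, run maximum-likelihood tree inference or model selection,
predict structures, or compute electrostatic surface maps; the net-charge
column is a sequence-only scalar, not a Poisson–Boltzmann result. It never
accesses the network.
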