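# Methods

## Screen definition

A protein is screened one terminal tail at a time. Tails are derived from a
transmembrane topology annotation: the N-tail runs from residue 1 to the
residue before the first TM helix, the C-tail from the residue after the
last TM helix to the end of the chain. A tail is *cytoplasmic* when every
non-membrane region it spans is annotated `inside`; only cytoplasmic tails
are eligible, since the switch requires contact with the inner membrane
leaflet. A zero-length tail is absent, and an N-terminal signal peptide
means the mature protein has no N-tail. Re-entrant/beta regions are treated
as non-membrane for boundary purposes but flag the tail for manual review:
P-type ATPases are alpha-helical, so beta topology calls indicate a suspect
prediction. All coordinates are 1-based inclusive (UniProt/GFF3 convention).

The screen itself is a sliding window at step 1. With defaults
`window_len = 30`, `min_basic = 9`, a window qualifies when it contains at
least nine K/R residues; scanning is restricted to the `search_depth = 100`
residues nearest the terminus (prefix of an N-tail, suffix of a C-tail),
and tails shorter than one window are excluded rather than erroneous.
Maximal runs of overlapping or abutting qualifying windows are merged into
one cluster, reported by both its window union and its basic span (first to
last K/R within the union); merging avoids reporting one cluster as a dozen
window positions, and the merge rule is covered by brute-force oracle
tests. Phosphosite attachment collects S/T/Y residues within the window
union widened by `phospho_flank = 5` on each side, clipped to the tail so a
membrane-buried residue never counts. The phosphosite residue set is
configurable (`STY` by default; `SY` reproduces the stricter reading some
summaries use). A curated phosphosite list, when supplied, is intersected
with the sequence-predicted sites — curation can narrow but never invent.
`X` residues occupy positions but never count as basic or phospho-acceptor.

Per tail the screen reports K+R density over the *whole* tail (the density
is a composition metric, deliberately not restricted to the searched
region) and a net side-chain charge at pH 7 from Henderson–Hasselbalch
fractions with fixed side-chain pKa values (K 10.5, R 12.5, H 6.0, D 3.9,
E 4.1, C 8.3, Y 10.1); free termini are excluded because the tail is part
of a chain. This scalar is a convenience summary only — it is not a
substitute for structure-based electrostatics.

A terminus is a candidate iff it is cytoplasmic and carries at least one
cluster with at least one attached phosphosite. Cohort summaries count
candidate proteins as N-only, C-only or both, and separately report how
many are new relative to a user-supplied list of previously proposed
candidates.

## Phylogenetic stage

The alignment (consumed, not computed) is trimmed by the gap rule: a column
is removed iff its gap fraction is strictly greater than 0.25. Distances
use pairwise gap deletion with either the p-distance or the Poisson
correction −ln(1 − p) (substitutions per site); a saturated pair (p ≥ 1) or
a pair with no gap-free sites is a named error. Trees come from Saitou–Nei
neighbor joining: Q-criterion agglomeration, ties broken by the
lexicographically lowest pair of cluster representative labels, negative
branch-length estimates clamped to zero (logged). On an additive matrix NJ
returns the unique additive tree exactly, which the tests verify to 1e-9
against path-sum oracles. Supports are standard nonparametric bootstrap:
columns resampled with replacement, distances + NJ per replicate, and each
internal edge of the point tree labelled with the percentage of replicates
containing the same bipartition. This whole stage is a deliberate
desk-scale, fully-testable substitute for maximum-likelihood inference with
BIC model selection and ultrafast bootstrap; the trimming rule is the part
of the published procedure implemented verbatim, and users wanting ML can
export the trimmed alignment for an external tool.

## Synthetic data

The generator emulates the screen's real inputs: multi-pass membrane
proteins with an even number of TM helices (so both termini are
cytoplasmic), ground-truth topology emitted alongside the sequence, and
optional planted clusters. Defaults model P-type ATPase catalytic subunits:
total length 800–1300 residues, 8–10 TM helices of 19–23 hydrophobic
residues, terminal tails of 30–120 residues, internal loops receiving the
remaining length. Background residues are drawn i.i.d.: K/R with
per-residue probability 0.11 and S/T/Y with probability 0.15 — approximate
human proteome composition — and uniformly over the remaining fifteen
amino acids otherwise. A plant overwrites a span of the designated tail
(inside the search depth) with exactly `k` basics, span endpoints always
basic so the planted span equals the recovered basic span, and optionally
writes one serine a fixed offset past the span. Everything is a pure
function of (spec, seed); cohorts rewritten with the same seed are
byte-identical.

What the generator does *not* emulate: realistic hydrophobicity profiles,
position-specific composition, signal peptides, splice isoforms, topology
prediction error (topology is ground truth by design, isolating the screen
from the predictor), and evolutionary correlation between cohort members.
Passing tests therefore demonstrate the correctness of the detection
machinery under known truth, not the biological accuracy of any particular
topology predictor or database annotation. Deterministic recall/false-
positive guarantees hold at zero background rates; at realistic background
rates, chance clusters are expected and quantified instead by the null
model: the probability that a single 30-residue window of i.i.d. residues
contains ≥ 9 basics is the exact binomial tail
Σ_{j=9}^{30} C(30,j) p^j (1−p)^{30−j} (≈ 0.002 at p = 0.1), which
Monte-Carlo runs reproduce within sampling error.

## Numerical and design choices

- Window step is 1; a tail exactly one window long has exactly one window.
- The scanned region is clipped to the tail; windows must lie fully inside
  it, so a cluster straddling the search-depth boundary is found only if
  some fully-contained window still holds nine basics.
- Cluster merging joins windows that overlap *or abut*; two clusters are
  distinct only when separated by at least one uncovered residue.
- Distance ties in NJ are broken lexicographically to make tree output
  independent of input order at equal Q; with continuous data ties are
  measure-zero, so this matters mainly for constructed matrices.
- Bootstrap replicates that produce an undefined distance (possible under
  the Poisson model on gappy resamples) are redrawn up to a logged cap of
  100, then fail loudly.
- Sizes used by the test and acceptance runs — 1000 random tails for the
  scan oracle, a 200-protein planted cohort, 10,000 null windows, 200
  bootstrap replicates on the clear-split fixture — were chosen as the
  smallest cohorts at which every check is decisive (recall and false
  positives are deterministic at zero background; the null check has a
  3-standard-error band).
- The CLI hashes the resolved configuration into every output header and
  refuses to run the phylogenetic stage on an input stamped with a
  different hash, so artifacts from different configurations cannot be
  silently combined. YAML config keys are validated strictly; unknown keys
  are fatal.

## Known limitations

The screen is sequence-only: it cannot see whether a tail is ordered,
whether basics are surface-exposed, or whether a kinase actually targets
the attached S/T/Y. Candidate status is a structural hypothesis, not
evidence of regulation — functional polybasic motifs (autoinhibitory
contacts, phosphoinositide binding) produce identical sequence signatures.
Topology quality bounds everything downstream; the package deliberately
trusts its input annotation. The phylogenetic stage is distance-based and
should not be quoted as a substitute for ML inference when branch support
matters beyond a desk-scale sanity check.
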