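# Methods

## Problem and model

Given two multiple sequence alignments of the same protein — one of curated
natural homologs, one of sequences produced by a backbone-conditioned design
network such as ProteinMPNN — the pipeline asks, position by position,
whether each source conserves a *chemical type* of residue, and combines the
two answers into a four-way annotation:

- **functional** — conserved by evolution but not by the design model.
  The chemistry matters for what the protein *does* (catalysis, cofactor
  binding, signaling), which a backbone-only design objective is blind to.
- **structural** — conserved by both. The chemistry is required to realize
  the fold itself.
- **adaptable** — conserved by the design model but free in evolution.
  Often an anchoring artifact of the input geometry (glycines, prolines,
  capping residues); evolution apparently tolerates, or selects for,
  variability there.
- **unlabeled** — neither source shows a significant preference.

All statistics operate on position-specific scoring matrices (PSSMs):
per-position relative frequencies `p_i(a)` over the 20 amino acids, either
parsed from psiblast-dialect ASCII files or computed from an alignment as

    p_i(a) = (count_i(a) + λ·q_a) / (n_i + λ)

with pseudocount `λ` (default 1.0) against a background `q` (default
uniform), counting only non-gap, non-X characters (`n_i` of them).
Positions are 1-based and anchored to the reference/query sequence;
alignment columns gapped in the reference are dropped so file-derived and
alignment-derived matrices share one coordinate system. Per-position
information content is `I_i = log2(20) − H(p_i)` in bits.

## Chemical classes

Amino acids are partitioned into six classes: acidic `{D,E}`, basic
`{K,R}`, hydrophilic `{S,T,N,Q,H,C,Y}`, hydrophobic `{A,V,L,I,M,F,W}`,
glycine `{G}`, proline `{P}`. Class frequencies are
`F_i(c) = Σ_{a∈c} p_i(a)`. Hard assignments are a simplification for
amphipathic and titratable residues — histidine is grouped as polar rather
than basic, tryptophan as hydrophobic — so the scheme is an explicit,
validated configuration object (any partition of the 20 residues is
accepted) and its definition is echoed into all output metadata.

## Enrichment testing

For each position `i` and class `c` a one-sided Mann-Whitney U test asks
whether the class is *enriched* relative to the whole-protein baseline.
The default `member` sampling mode takes the member frequencies
`{p_i(a) : a ∈ c}` as the test sample and the leave-one-out pool
`{p_j(a) : a ∈ c, j ≠ i}` as the baseline; leaving position `i` out keeps
the tested values from contaminating their own reference distribution.
The alternative `class_sum` mode compares the single summed value `F_i(c)`
against the other positions' sums, mirroring the "add up the members"
reading of class conservation; with one observation per test it has less
power. Significance is a raw `p < α` with `α = 0.01`. No multiple-testing
correction is applied by default — the decision rule is deliberately a raw
per-test threshold — but Benjamini–Hochberg across all L×K tests is
available.

For pooled sample sizes `n + m ≤ 20` the p-value comes from the exact
permutation distribution of U (exhaustive enumeration; ties handled by
construction; the one-observation case is enumerated directly). Larger
problems use the tie-corrected, continuity-corrected normal approximation.
A fully degenerate pooled sample yields `p = 1` with a warning, never an
exception. At least 5 positions are required so the baseline is
non-degenerate.

**Power depends on class size.** The maximum attainable evidence in
`member` mode is bounded by the number of class members `m`: with `m = 1`
(glycine, proline) the best one-sided normal-approximation p-value against
a leave-one-out baseline of ~119 positions is ≈ 0.04, and with `m = 2`
(acidic, basic) ≈ 0.008 — right at the α = 0.01 boundary — while the
7-member classes have orders of magnitude of headroom. Perfectly conserved
singleton-class positions can therefore go unflagged at the default α.
This is a property of the decision rule, not a bug; users tracking
glycine/proline conservation should consider `class_sum` mode with exact
testing (short proteins) or a larger α for those classes.

## Position filter

Per position the class-frequency deviation from the protein-wide mean,
`d_i = F_i − mean_j F_j`, is summarized by its Euclidean (Frobenius) norm
and scaled by information content into the filter score
`s_i = I_i·‖d_i‖`. Positions are ranked by `s_i` (ties broken by position
index ascending, making retained sets nest as the threshold loosens) and
only the top `⌈keep_fraction·L⌉` keep their enrichment flags; revoked flags
stay recorded. The default `keep_fraction = 0.8` is explicitly a tunable:
the right value depends on the depth and curation of the evolutionary
alignment and should be calibrated on residues with known roles (see
`examples/04_key_residue_benchmark.py`). Each branch is filtered
independently *before* the two maps are compared, matching the order of the
procedure (test → filter → compare); filtering after comparison would be
the other defensible order and would only differ for positions significant
in both sets but retained in one.

## Classification

A position is significant for a branch when any class is enriched and the
position is retained. The truth table is: natural-only → functional,
designed-only → adaptable, both → structural, neither → unlabeled. In
`same_class` convergence mode the structural call additionally requires at
least one class enriched in both branches; doubly-significant positions
with disjoint class sets then remain unlabeled, with both class sets kept
in the provenance columns — the conservative choice for a cell the truth
table does not otherwise cover. Positions whose natural enrichment excludes
the query residue's own class are flagged `query_deviates`: the family
conserves a chemistry the query itself departs from, which is worth manual
inspection rather than a different label.

## Synthetic benchmark

`simulate_paired_alignments` draws both sets column-i.i.d. from a
background (uniform by default; a Swiss-Prot-like composition is provided),
except at planted positions where with probability `strength` the residue
is drawn uniformly from a target class's members. The per-column modal
residue of the natural draws is prepended to both alignments as the shared
query row. Correlations present in real data — phylogeny among homologs,
backbone-mediated coupling among designs — are deliberately not emulated;
the pipeline only consumes column compositions, so recovery results
transfer to the statistical structure, not to the biology, of real inputs.

The benchmark conditions are 120 positions, 200 sequences per set,
`strength = 0.9`, and ten planted positions per label type. Plants default
to the two seven-member classes (hydrophilic, hydrophobic), where the
member-mode test has full power (see the class-size note above); the
planted positions are spread evenly along the sequence with the three label
types interleaved. Under these conditions the pipeline recovers ≥ 90 % of
planted labels (typically 100 %), and on null alignments (no plants) the
per-test flag rate at α = 0.01 stays far below 3 %: the rank test on
column frequencies is conservative because exchangeable positions rarely
produce extreme leave-one-out rank sums.

Problem sizes in the test suite and acceptance script (L = 120–170, 150–200
sequences, ~10⁴ null tests) were chosen as the smallest sizes at which the
planted-signal and null-rate statements are stable across seeds.

## Numerical and I/O choices

- All downstream statistics use the frequency matrix, never the file's
  log-odds block, whose units are dialect-dependent (psiblast writes
  half-bits; internally computed log-odds are bits against the declared
  background).
- psiblast percentage rows that do not sum to 100 (the format rounds down)
  are renormalized on read and the affected positions recorded in metadata.
- Columns with gap fraction above 50 % (configurable) are flagged
  low-coverage but still computed.
- ProteinMPNN multi-chain records default to keeping the first chain
  (protomers of a homodimer design are near-copies; pooling would double
  count); pooling every chain or concatenating are options.
- The exact/asymptotic crossover at `n + m = 20`, the α, the keep fraction,
  the sampling mode, and the tie-break rule are all recorded in output
  metadata so a run is reproducible from its summary JSON alone.

## Limitations

- Labels are per-position and ignore couplings between positions
  (co-evolution, design covariation).
- The class partition is one of several defensible chemistries; published
  analyses with a different partition (notably for H, C, Y, W) will differ
  at the margins.
- Singleton-class enrichment is statistically hard to flag at α = 0.01
  (see above), which depresses the adaptable count in glycine/proline-rich
  regions relative to visual inspection of the design alignment.
- The synthetic generator validates the statistics, not the biology;
  claims about real proteins require real curated alignments and design
  outputs.
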