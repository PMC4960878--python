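# Methods

This note documents the models and procedures implemented in `famsig`, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Class-signature scoring

The family alignment is analysed one class at a time. Columns in which the
studied class contributes no residue are removed; the remaining columns are
profiled separately for the class and for all other classes pooled ("rest").
A profile column maps each residue to its conservation rate — the fraction
of the partition's sequences carrying that residue there.

**Denominators.** Rates are computed over the partition's *non-missing*
residues at the column: gaps and non-standard codes (X, B, Z) are treated as
missing data and excluded from the denominator. This makes 100 %
conservation attainable in the presence of fragment sequences, which is the
behaviour the score relies on; the alternative (total partition size) would
silently cap rates below 1 for any column with a fragment. Missing data
never contributes to any rate.

**The score.** With `m` the class's maximum rate at a column, `aa` the
residue achieving it and `q` that residue's rate in the rest profile:

    s = m^3 / q                        if q > 0
    s = m^3 / ((1 / seqs_rest) / 2)    if q = 0

`seqs_rest` is the number of sequences outside the studied class (the
partition size, not the column's non-missing count). The zero branch
assigns an unseen residue half the rate of a single rest sequence, so the
score stays finite and the boundary between the branches is an exact factor
2: at `q = 1/seqs_rest` the score is `seqs_rest * m^3`, in the zero case
`2 * seqs_rest * m^3`. Cubing `m` sharpens the preference for near-perfect
within-class conservation.

**Ties.** When two residues share the class maximum, each is scored and the
higher score wins; residual ties go to the alphabetically first residue.
This is deterministic and favours the most class-distinctive residue.

**Reporting.** The report ranks columns by score (descending, then lower
column first), maps columns to reference-sequence numbering (count of
non-gap reference residues up to the column, first residue = 1), and
attaches, for every other class, its modal residue and prevalence at the
column. The full per-column score track is exported for plotting. The rest
partition is pooled for scoring, as the single rest profile in the formula
implies; per-class modal residues are recomputed separately only for the
report table.

## Intra-class identity statistics

Each class is aligned separately (inter-class columns would otherwise
deflate identities), trimmed of columns whose non-gap fraction falls below
`min_occupancy` (default 0.2 — "sparsely occupied trailing ends"), and every
sequence pair is compared. Identity is `100 * matches / co-occupied
columns`, where a co-occupied column has a residue in both sequences; pairs
with no co-occupied column are undefined and excluded from summaries. An
alignment-length denominator is available as a configurable alternative for
sensitivity analysis. Summaries are median, mean and min over the defined
off-diagonal values; an even count of pairs gives the midpoint median.

## Selection pressure (dN/dS)

The estimator is the Nei–Gojobori (1986) counting method, not a
maximum-likelihood codon model — output is labelled "counting" accordingly.
Per sense codon, each position contributes the fraction of its non-stop
single-nucleotide changes that are synonymous to the synonymous site count S
and the complement to N, so S + N = 3 exactly for every sense codon
(implementations differ here; the renormalization after stop exclusion is
deliberate and tested against exhaustive enumeration). Observed differences
between codon pairs are averaged over all minimal substitution pathways that
avoid stop codons, with equal pathway weights (the classic choice; a
transition/transversion weighting hook would slot into the pathway weights).
Codons containing gaps or ambiguity in either member of a pair are skipped
for that pair only. Proportions pS = Sd/S and pN = Nd/N receive the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); a ratio below 1 flags
purifying pressure.

Degenerate cases: dS = 0 leaves the ratio undefined (reported, not thrown);
a saturated synonymous proportion (pS ≥ 3/4, inevitable on tiny toys with a
synonymous difference) maps to dS = ∞ so the ratio is still bounded (0 when
dN = 0); saturation of the nonsynonymous proportion raises an error, since
no ratio can be recovered.

The alignment-level estimate pools Sd, Nd, S, N over all pairs before
correction (primary, more stable) and also reports the mean of defined
pairwise ratios.

## Structure screen

**Hydrogen bonds.** The Kabsch–Sander electrostatic model:
E = 27.888·(1/r(ON) + 1/r(CH) − 1/r(OH) − 1/r(CN)) kcal/mol, clamped below
at −9.9, bond declared when E < −0.5. Amide hydrogens are reconstructed at
1.0 Å from N, anti-parallel to the preceding residue's carbonyl; the first
residue of a chain and prolines never donate. Distances below 0.5 Å are a
clash error.

**Assignment.** Runs of ≥ 2 consecutive i→i+4 bonds mark 4-helices (H);
parallel/antiparallel bridge patterns mark β-bridges, ladders of ≥ 2
consecutive bridges become E, isolated bridges B; everything else — 3/5
turns, bends — collapses to '-'. The census needs only strand run lengths
and helix presence, so the reduced alphabet {H, E, B, -} is used throughout;
isolated bridges do not extend E-runs. Helix takes priority where patterns
overlap.

**Mapping.** Each chain sequence is globally aligned (BLOSUM62, gap open
−11 / extend −1, free end gaps) against every family sequence; the best
identity over aligned pairs wins and the mapping is composed through that
member's alignment columns, giving a collinear chain-residue → column map.
Chains below `min_identity` (default 0.3 — family members share roughly 60 %
identity, so 0.3 separates family chains from contaminants) or shorter than
30 residues are excluded.

**Dimer filter.** A structure is kept iff at least two chains map and some
chain pair has ≥ `min_contacts` (default 5) inter-chain CA–CA contacts
≤ 8 Å between residues mapping inside the interface window. Reasons
("non-dimeric" / "orientation") are recorded per structure so the
operationalization is auditable — no published criterion exists for
"incorrect subunit orientation".

**Window.** The interface window is given in reference numbering and
defaults to 282–320, the subunit-interaction segment of the motivating
family (the narrower 290–320 usage also appears in the literature; the
window is a config value). Metrics per chain: length of the longest E-run
with at least one residue mapped inside the window, and presence of an
H-run of ≥ 4 residues touching the window. Per-structure aggregation takes
the maximum-length chain; per-chain values are also exported, since it is
ambiguous whether a published census of this kind counts structures or
chains.

## Synthetic data

**Families.** A root sequence is drawn uniformly; each column receives a
small residue repertoire (default 4 residues including the root),
emulating per-site chemical constraints. Class consensuses diverge from the
root by in-repertoire substitutions at rate `inter_class_divergence`
(default 0.4 ≈ 60 % inter-class identity); members diverge from their
consensus at `intra_class_divergence` (default 0.15 ≈ 85 % intra-class
identity, within the 70–93 % range typical of such families), occasionally
(10 %) stepping outside the repertoire. A fraction of members (default
0.05) are end-trimmed fragments. Planted signature sites overwrite member
residues so the realized class and rest prevalences hit the requested
values exactly after rounding to counts; the planted residue is excluded
from the column repertoire and scrubbed elsewhere, so ground truth is exact
by construction. Keeping consensus divergence inside the repertoire is what
makes a planted signature meaningful: a residue conserved in one class and
absent from 250 pooled others should be a biological signal, not a routine
accident of uniform substitution. Columns evolve independently (no
within-class phylogeny beyond the star from the consensus) — sufficient
because the score is column-wise, and it keeps ground truth exact. The
generator does not emulate indels within the aligned core, rate
heterogeneity, or phylogenetic correlation between classes; recovery results
on it therefore demonstrate correctness of the scoring machinery, not
robustness to alignment error.

**Codon alignments.** Star-tree evolution from a stop-free root of uniform
sense codons: single-nucleotide proposals accepted with probability 1 if
synonymous and ω if nonsynonymous (inverted above ω = 1), stop-creating
proposals always rejected; each lineage receives Poisson(branch_length ×
n_codons) accepted substitutions. Defaults: 10 sequences, 500 codons,
branch length 0.5 substitutions per codon per lineage — deep enough that
the pooled counting estimate's sampling error is small relative to the
recovery bands while pairwise nucleotide divergence (~0.2/site) stays in
the comfortably correctable regime, and comparable to intra-class mammalian
divergence. The transition/transversion ratio defaults to 1 because the
generator is a parameter-recovery harness for an estimator that assumes no
such bias; the field is exposed for sensitivity studies. The realized ω is
estimated, never assumed.

**Geometry.** Chains are built residue by residue from ideal internal
coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, ω 180°)
with per-residue φ/ψ targets (NeRF construction); recomputing dihedrals
from the coordinates returns the targets within 1°, verified against an
independent dihedral routine. For dimers, the second chain is rigidly
placed into antiparallel register by least squares on the planted H-bond
geometry (N···O 2.9 Å, H···O 1.9 Å at every other register pair), seeded by
a superposition-based initial guess and guarded by a clash check. Planted
E-run lengths terminate exactly: for bare strand pairs the chain ends
terminate the ladder (any length ≥ 2); for mid-chain interface strands the
strand-entering φ and strand-leaving ψ are bent away from ideal values so
the flanking residues cannot bridge (odd lengths; the census uses 3 and 5).
Census chains carry a real family subsequence (prolines substituted, as
they cannot donate the planted bonds) so that alignment mapping works on
the same code path as for real structures.

## Determinism and sizes

All generators are pure functions of (spec, seed); every stage re-run with
the same configuration and seed is byte-identical (timestamps live only in
the run manifest). The test suite and the acceptance script use reduced
problem sizes chosen to keep full runs in the tens of seconds: 20 seeded
families of 300 × 380 for signature recovery, 20 simulations per ω of
10 × 500 codons for dN/dS recovery, and a 12-structure census batch of
~37-residue chains.

## Known limitations

- The signature score presumes a trustworthy alignment; misaligned columns
  masquerade as signatures. No alignment uncertainty is propagated.
- The counting dN/dS estimator ignores transition/transversion bias and
  codon frequencies; against biased real data it is conservative relative
  to ML codon models, and values are not comparable to published ML
  estimates beyond the <1 decision rule.
- The secondary-structure assigner implements the helix/strand subset of
  the Kabsch–Sander rules (no 3/5-helices, bends, or β-bulges); on real
  structures its E-runs can fragment where a full implementation would
  bridge a bulge.
- The dimer filter's contact criterion is an operationalization; borderline
  crystal packings may be kept or discarded differently from a curated set.
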