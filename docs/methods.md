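# Methods

This note documents the models and procedures implemented in
`ringsurvey`, the defaults and why they were chosen, what the synthetic
data emulate, and the numerical conventions that make runs reproducible.

## RING octet grammar and scanning

A RING finger domain binds two zinc ions through eight Cys/His residues
(metal ligands M1–M8). The scanner treats the domain as a pattern with
gap constraints: a residue set per ligand position and an integer
interval per spacer (residues strictly between consecutive ligands). The
default grammar is the canonical RING consensus

| element | default | notes |
|---|---|---|
| M1, M2, M3, M6, M7, M8 | {C} | conserved cysteines |
| M4, M5 | {C, H} | the subtype-discriminating positions |
| s1 | [2, 2] | C-X2-C |
| s2 | [9, 39] | the long loop 1 |
| s3 | [1, 3] | |
| s4 | [2, 3] | |
| s5 | [2, 2] | |
| s6 | [4, 48] | the long loop 2 |
| s7 | [1, 6] | kept wide; HC-subfamily spacing is a *classification* decision |

Subtype surveys report which ligand positions are conserved but not
numeric spacer bounds, so the bounds above follow the consensus commonly
used for this domain family and every value is overridable in the run
config. `X` (unknown residue) never matches a ligand position: an
unconfirmed residue must not create a RING call.

Scanning enumerates all octets compatible with the grammar via
backtracking over per-position candidate lists; a property test asserts
set-equality with an independent naive enumerator. Redundancy among raw
octets is then resolved deterministically: per shared M1 the smallest
total spacer sum wins, and among overlapping spans the leftmost start,
then smallest spacer sum, then lexicographic position tuple. This yields
one call per domain region while preserving genuinely disjoint domains
(multi-RING proteins). All coordinates are 1-based inclusive.

When HMMER3 per-domain hits are supplied, scanning can be restricted to
the hit envelopes extended by a flank (default 10 residues); matches are
reported in full-sequence coordinates. An empty hit list deliberately
selects nothing (the hits are then the candidate source of record).

## Subtype signatures

Classification uses an ordered, first-match-wins signature table over the
M4/M5 residues and the s7 spacer:
H2 = (H, H); HCa = (H, C, s7 = 2); HCb = (H, C, s7 = 4); C2 = (C, C);
v = (C, H); G = (H, C, s7 ∉ {2, 4}). Exhaustive enumeration over the
grammar's (M4, M5, s7) range verifies the six default rows are pairwise
disjoint, so each octet gets exactly one label (or `unclassified` under a
user-edited table; overlapping user rows are reported as warnings).

Two readings are possible for the HCa/HCb spacing rule ("two and four
amino acids" between ligands 7 and 8): HCa = 2 and HCb = 4, or HCa
admitting both. The implementation uses the first reading and does not
guess further. The G subtype has no published signature at all; its row
is a provisional catch-all for the remaining H/C spacings and is
config-replaceable.

Family composition is reported both domain-level (every classified
octet) and protein-level (each protein once per subtype it carries),
because survey literature mixes the two conventions; percentages are the
domain-level share of classified domains.

## Redundancy collapse

Exact duplicates collapse to the lexicographically smallest id. Near
duplicates — global-alignment identity ≥ 0.99 with mutual coverage ≥ 0.9
(both configurable; the defaults are conservative, aimed at assembly
artifacts rather than paralogs) — are clustered by single linkage and
each cluster collapses to its longest member (ties: smallest id). The
procedure is idempotent, conserves ids (kept + removed = input), and its
kept-id set is independent of input order.

Identity is defined on a global alignment with match +1, mismatch 0,
linear gap −1, refined to the score-optimal alignment with the maximum
number of identical pairs. The refinement makes identity *unique*: with
score S and matches m fixed, gap columns g = m − S and alignment length
L = (|a| + |b| + g) / 2 are determined, so identity = m / L does not
depend on traceback tie-breaking. Candidate pairs are prescreened with a
banded edit distance using the lossless bound
edit ≤ (1 − threshold)·(|a| + |b|) (every non-identical alignment column
is one edit), so the screen can only discard pairs the exact DP would
reject anyway; final decisions always come from the DP.

## Stress-response calling and Venn decomposition

Per (gene, stress, timepoint) the pipeline computes
log2((treatment + p) / (control + p)) with pseudocount p = 0.1
expression units (guards zero values; the survey data carry no stated
zero-handling rule). A gene is responsive to a stress when |log2 ratio|
≥ threshold (default 1) at **any** timepoint; the boundary is inclusive
because "twofold" states no strictness. Direction is `up`/`down` when all
threshold-reaching timepoints agree, else `mixed`.

By default the screen is applied to the genes classified RING-H2 — the
convention of the survey this package generalizes, where the responsive
analysis covered the H2 subfamily — with a config switch (`gene_subset:
all`) for family-wide screens.

Responsive sets over k stresses (default 4: cold, salt, drought, MeJA;
supported to k = 6) are decomposed into their 2^k − 1 exact-membership
cells. Cells are disjoint and sum to the union by construction; a
property test checks equality with direct set algebra. Candidate
selection modes: the all-stress intersection, per-stress exclusive cells,
arbitrary cells, or the union.

## 2^−ΔΔCt quantification

ΔCt = Ct_target − Ct_housekeeping per replicate (replicate indices must
pair target and housekeeping measurements); per sample the replicate ΔCt
values are averaged, ΔΔCt subtracts the calibrator sample's mean ΔCt,
and fold = 2^−ΔΔCt. Amplification efficiency is fixed at 2 per cycle
(classic ΔΔCt; no efficiency correction). With balanced technical ×
biological replicate counts the grand mean over a flat replicate index
equals the mean of per-biological-replicate means, so a flat index is
used. Replicate dispersion is reported as the standard deviation of
per-replicate ΔCt (labelled sd). The calibrator's fold is exactly 1, and
folds are invariant to adding a constant to all of one sample's Ct
values — both enforced by tests.

## Synthetic data: what it emulates, and what it does not

The generators produce the pipeline's complete input surface with known
planted truth:

* **Proteome** — planted octets built directly from the active grammar
  and signature table, embedded in flanks. In the default `clean`
  background mode, flanks, spacers and decoys draw only from the 18
  residues that are neither Cys nor His, so the planted ligands are the
  *only* ligand candidates and recovery is guaranteed combinatorially; a
  `realistic` mode uses all 20 letters with scanner-verified rejection
  sampling. Decoys are background sequences plus "near-miss" sequences
  violating exactly one grammar constraint (one ligand mutated away or
  one spacer out of range) — the hard negatives for the scanner.
* **Expression** — per (gene, stress) a control level (uniform 20–100
  units) and per-timepoint log2 effects: members of a planted Venn cell
  get one timepoint with |effect| in [1.5, 3.0], all other effects stay
  within ±0.3. Gaussian log2 noise (sd 0.05) is *clipped at ±3 sd*, so
  the margins around the call threshold of 1 are hard bounds and planted
  memberships are recovered exactly for every seed; the generator
  additionally verifies this self-consistency and refuses specs whose
  margin is below 4 × noise sd.
* **Ct tables** — Ct_target = Ct_housekeeping + ΔCt_base − log2(fold) +
  noise, with housekeeping held at its baseline (18 cycles, ΔCt_base 5)
  and clipped Gaussian noise (sd 0.05) on the target measurements; 3
  biological × 3 technical replicates.

The family-scale preset plants the published composition — 335 RING
proteins: 214 H2, 3 HCb, 1 G, with the HCa/C2/v split (104/7/6) a free
choice because only those three subtype counts and the total are
published — plus 500 decoys. The expression preset plants the published
Venn configuration over the 214 H2 genes: per-stress totals
128/134/121/82, four-way intersection 53, single-stress cells 5 (cold),
26 (salt), 0, 0. The pair and triple cells are not published; the preset
fixes them once (CS 16, CD 24, CM 2, SD 8, SM 3, DM 10, CSD 18, CSM 6,
CDM 4, SDM 4) so that all per-stress marginals hold, giving a responsive
union of 179 of 214 genes. The qPCR preset plants the published
strongest salt response, fold 3.28 at 12 h for the validated target
gene.

What passing on synthetic data shows: the algorithms are exact on inputs
satisfying their stated assumptions (clean margins, grammar-generated
motifs). What it does not show: performance on real proteomes, where
spacer distributions, degenerate domains, isoforms and noisy expression
values violate those margins — real-data family counts depend on the
proteome release and on HMM sensitivity and are not reproducible from
the algorithms alone.

## Numerical and reproducibility conventions

All randomness flows through `numpy.random.default_rng` seeds carried in
the spec objects; identical spec + seed gives byte-identical files.
Pipeline outputs are sorted (ids lexicographically, JSON keys sorted) so
re-runs are byte-identical; the run report embeds a config hash covering
analysis parameters and input paths (not the output directory). Ties are
broken deterministically everywhere (documented per module). The
acceptance script derives independent child seeds from its single
`--seed` via `numpy.random.SeedSequence`. Problem sizes used by the test
and acceptance runs are the family-scale preset (835 proteins, 214
genes, 3×3 replicates) and 1,000 random sequences of length ≤ 200 for
the scanner-oracle equivalence check; random oracle sequences keep
Cys/His at 10% each because ligand-dense random strings make the number
of raw octets grow combinatorially without exercising anything new.

## Known limitations

* The scanner targets the single-octet RING grammar; interleaved or
  atypical RING variants (mH2, mHC, S/T, D types) are out of scope.
* The G-subtype signature is provisional (see above).
* Dedup identity uses one fixed scoring scheme; no isoform/locus
  awareness.
* No differential-expression statistics: the screen is a deterministic
  fold-change rule, as in the survey design it reproduces (single
  expression value per condition, no replicates).
* qPCR efficiency is assumed exactly 2; no standard-curve correction.
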