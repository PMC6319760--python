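# Methods

## Observable

All analysis is anchored to a reference structure, normally the crystal
structure of the domain. A *native contact* is an unordered pair of heavy
atoms with reference distance r⁰ < 4.5 Å whose residues satisfy
|i − j| > 3 in (internal, contiguous) sequence numbering. Both thresholds
are strict: a pair at exactly the cutoff, or at separation exactly 3, is
not a contact. Strictness costs nothing physically (the boundary is a
measure-zero event) and buys bitwise determinism.

For a frame with pair distances rᵢⱼ the soft fraction of native contacts is

    Q = (1/N) Σ 1 / (1 + exp[β (rᵢⱼ − λ r⁰ᵢⱼ)])

Each term is a logistic switch centred at λ r⁰: a pair still near its
native distance contributes ≈ 1, a separated pair ≈ 0, with β controlling
the width of the transition. The logistic is evaluated through
`scipy.special.expit`, which saturates instead of overflowing, so fully
unfolded frames are safe at any distance.

Parameter defaults, units, and why:

| parameter | default | unit | role |
|---|---|---|---|
| cutoff | 4.5 | Å | native-contact distance threshold (strict <) |
| min_residue_separation | 3 | residues | keep pairs with \|i−j\| > 3; removes trivially maintained local contacts |
| β | 5.0 | Å⁻¹ | logistic smoothing; transition width ≈ 1/β |
| λ | 1.8 | — | tolerance factor; a contact survives thermal breathing up to ≈ λ r⁰ |
| window_fraction | 0.3 | — | averaging window, the final 30 % of each replica's own time span |
| q_threshold | 0.6 | — | per-residue final-window mean below this flags a (residue, replica) as unstable (strict <) |
| min_contacts | 30 | pairs | residues with fewer native contacts are excluded from flagging (strict <) |

These are the standard numerics of the soft-Q contact definition; every
report embeds the full parameter block, and comparisons between reports
computed under different parameters are refused rather than silently mixed.

Internal length unit is Å everywhere; readers for nm-native binary formats
convert on read (logged once). Backbone RMSD alone is reported in nm,
matching the field's plotting convention.

## Decomposition

Residue types partition into three groups — hydrophilic (Asp, Glu, Gln,
Asn, Arg, Lys, His), hydrophobic (Phe, Tyr, Trp, Leu, Val, Ile, Met, Cys,
Pro) and small (Gly, Ala, Ser, Thr) — and contacts are masked by unordered
group pairs (six disjoint pairs plus each group against "all") and by
residue. Two algebraic identities pin the implementation down and are
enforced in tests at 1e-10 per frame:

- N_all · Q_all = Σ over the six disjoint group pairs of N · Q;
- the contact-count-weighted mean of per-residue Q (each pair counted once
  for each of its two residues) equals Q_all.

Internally, one (frames × pairs) matrix of logistic contributions is
computed per replica and every selection's series is a column-subset mean,
so the identities hold by construction up to floating-point reassociation.

## Averaging and decision rules

Per replica, frames with t ≥ (1 − f) · t_end enter the final window (f =
0.3 of the replica's *own* span, so shortened runs scale; an absolute-ns
mode exists). The headline mean and SD pool the selected frames of all
replicas — the pooled SD captures inter- plus intra-replica spread, which
is what makes error bars grow visibly when some replicas unfold and others
do not. Per-replica means are kept alongside; per-residue flagging uses
them directly: a (residue, replica) pair is flagged when the replica's
final-window per-residue mean is strictly below 0.6. Residues with fewer
than 30 native contacts in the reference are excluded from flagging and
listed separately — their Q rests on too few pairs to be meaningful.

Flag monotonicity holds by construction: raising the Q threshold can only
add flags, raising the contact minimum can only remove residues from
consideration.

Composition of the unstable set is reported per group, weighting each
residue by the number of replicas in which it was flagged; the three
percentages sum to 100 whenever any residue is flagged and are undefined
(reported as such) otherwise. A group's stability percentage is
100 · [1 − flagged(residue, replica) pairs in the group / (group size after
exclusions × replicas)].

Cross-system, the per-system final-window Q means are correlated with
experimental melting temperatures by plain Pearson r (at least three
systems, pairwise-complete with a logged note when a selection is missing;
zero-variance inputs reported as undefined, never coerced). No multiple-
testing correction is applied — the correlations are descriptive, and n is
always reported next to r. The per-system mean of per-residue Q uses an
unweighted mean over residues by default, with a contact-weighted option.

Wild-type/mutant comparisons lay out RMSD and the hydrophilic–all, all–all
and hydrophobic–small Q means (SD in parentheses in the CLI rendering) with
deltas against the wild type, and hard-fail on any provenance mismatch.

## Superposition

Backbone RMSD (N, Cα, C, O; carbonyl O included by convention,
configurable) uses the Kabsch algorithm: SVD of the covariance matrix with
a determinant correction restricting to proper rotations. An independent
quaternion (Horn) superposition serves as the test oracle at 1e-9.

## Synthetic generator

The generator exists to give the analysis stages inputs with known ground
truth; it emulates the *phenomenology* of unfolding trajectory ensembles,
not their physics.

Structure: residues are laid on serpentine strands (10 residues per
strand, 3 strands per sheet, 2 sheets) with lattice spacings 3.2 / 3.8 /
4.0 Å chosen so that default contact parameters give core residues well
over 30 native contacts; each residue carries a 5-atom heavy-atom cluster
(N, Cα, C, O, Cβ pattern) with a small seeded placement jitter (0.06 Å) and
a 1.0 Å steric floor enforced by bounded retries. The two chain termini are
displaced 3.2 Å radially outward so they dangle like real termini — and
drop below the 30-contact threshold, keeping the exclusion rule exercised
on every default system. Residue names cycle deterministically through the
20 standard types so all three groups are populated.

Ensemble: frame k (time (k+1)·dt) is native coordinates plus i.i.d.
Gaussian jitter (σ₀ = 0.25 Å default), plus, for each residue whose onset
fraction τᵢ has passed, a coherent displacement of all its atoms growing as
a smoothstep from 0 at τᵢ to the residue's amplitude sᵢ at the end of the
run, along a direction drawn once per (residue, replica). An optional
rigid-body mode superimposes a growing random rotation and translation on
every frame, which superposition must remove exactly. Replicas draw from
`SeedSequence` substreams of the master seed: identical spec + seed
reproduces the ensemble bitwise, different replicas are independent.

Defaults mirror the study design the analysis targets: 10 replicas per
system, 200 frames spanning a 100 ns run (0.5 ns spacing — the realistic
10 ps save interval scaled down to desk size), 60 residues.

The 7-system benchmark assigns each system an instability level from a
strictly monotone gradient (default 1 → 0): the number of designed-unstable
residues scales with the level (up to 12, at fixed 12 Å amplitude, drawn
from the chain interior), onsets shift later for more stable systems, and
pseudo-Tm values are laid on an increasing 47–85 °C grid. Designed
instability therefore decreases as pseudo-Tm increases; reversing the
gradient reverses the relationship and must flip the sign of the Q–Tm
correlation.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: force-field energetics, cooperative unfolding
pathways, refolding events, solvent effects, and realistic backbone
geometry. A designed residue's contacts break because it is carried away
geometrically; real unstable residues lose contacts gradually and partially.
Tests against the generator validate the bookkeeping, decision rules and
statistics of the pipeline, not the MD itself.

## Problem sizes

The test suite and the acceptance script run everything at desk scale:
60-residue systems, 10 replicas × 200 frames for the recovery and benchmark
runs, 100+ random frames for the kernel oracle, 50 random structures (≤ 200
atoms) for the contact-map oracle. These sizes were chosen so the full
pipeline exercises every rule in seconds while remaining large enough that
window statistics are stable across seeds.

## Known limitations

- Per-residue Q of low-contact residues is intrinsically noisy; the
  exclusion rule hides rather than fixes this, exactly as the protocol
  specifies.
- No minimum-image handling by default: trajectories are assumed whole and
  unwrapped (single solute). A box-aware mode is out of scope.
- The NME/ACE capping-group convention (atoms merged into the terminal
  residue, cap-only pairs excluded from per-residue tables) matters only
  for capped MD topologies; synthetic structures carry no caps.
- mmCIF input, structure repair and mutant side-chain modelling are out of
  scope; mutants are consumed as ready-made structures plus ensembles.
- Pearson r on seven systems is descriptive; the package deliberately
  reports no significance tests and claims no absolute Tm prediction.
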