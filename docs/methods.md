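# Methods

This note documents the model, the parameters that matter, the numerical
choices, what the synthetic benchmark generator does and does not emulate,
and the known limitations.

## Problem statement

Given two protein C-alpha traces (query of length N, model of length M),
find a proper rigid transform of the model and a one-to-one set of residue
pairs maximizing a TM-score-like similarity, with no constraint that
equivalent regions appear in the same sequence order. Circular
permutations, arbitrary segment shuffles and — in mixed mode —
anti-parallel (reverse) SSE matches are all inside the search space. The
alignment is built only from geometry: no sequence information, no
hydrogen bonds, no side chains.

## Secondary structure assignment

Labels (H/E/C) come from the C-alpha distance-pattern test over the
five-residue window i−2..i+2: the six intra-window distances are compared
with ideal helix values (5.45 Å at separation 2, 5.18 Å at 3, 6.37 Å at 4;
tolerance 2.1 Å) and ideal strand values (6.1 / 10.4 / 13.0 Å; tolerance
1.42 Å). Residues whose window leaves the continuous stretch (chain break
or terminus) are coil. A single smoothing pass (on by default,
flag-controlled) relabels a residue whose two neighbors agree with each
other but not with it. This is the standard fast assignment for
C-alpha-only models; it is *not* DSSP-equivalent, and agreement with
hydrogen-bond-based assignments is approximate by design. Elements
shorter than 6 residues (helix) or 3 (strand) are ignored at the SSE
level; their per-residue labels still enter the residue-level similarity.

A practical consequence of the windowing is that the two residues at each
end of an element cannot be classified, so an element must be 10 (helix)
or 7 (strand) residues long before it is detected in isolation; in real
structures flanking quasi-extended loop residues usually make up the
difference.

## SSE descriptors and reference frames

Each element is scanned with overlapping windows (6 residues for helices,
3 for strands), giving n−5 and n−2 descriptors respectively for an
element of length n. For a window starting at residue k:

* helix window ends: r_init = (0.74 r_k + r_{k+1} + r_{k+2} + 0.74 r_{k+3})/3.48
  and the analogous average over k+2..k+5 — the weights place the end
  points on the local helix axis;
* strand window ends: midpoints of (r_k, r_{k+1}) and (r_{k+1}, r_{k+2});
* representative point: midpoint of the two ends; axis vector v_para:
  unit vector from r_init to r_end (N→C);
* perpendicular vector v_perp: unit component, orthogonal to v_para, of
  the vector from the representative point to the window center
  ((r_{k+2}+r_{k+3})/2 for helices, r_{k+1} for strands).

If that perpendicular component is numerically zero (possible only for
exactly straight synthetic strands; < 1e-6 Å) the global +z axis, or +y
when the axis is parallel to z, is substituted to keep the frame
deterministic. Each descriptor anchors a right-handed orthonormal frame
(x = v_para, y = v_perp re-orthogonalized, z = x × y). Windows never
cross chain breaks.

## Geometric hashing

Preprocessing stores, for every ordered pair (i, j), i ≠ j, of model
descriptors, the position of j in frame i — binned by componentwise
floor(coordinate/h), h = 3.2 Å — together with j's SSE type and both
vectors expressed in frame i (n(n−1) entries). Recognition repeats the
construction for the query; when a query descriptor lands in an occupied
cell, entries of matching SSE type vote for their (model frame, query
frame) pair with S = Θ + Φ, each term mapping the angle between the
paired vectors from [0°, 60°] onto [1, 0] and zero beyond 60°. Because
one query descriptor corresponds to at most one model descriptor per
basis, only the best-scoring entry of each basis frame in the cell votes;
this also caps any pair's total vote at 2 (min(n_model, n_query) − 1).
In reverse-allowing mode the axis term uses |cos θ|, so anti-parallel
matches vote equally.

No neighbor-cell probing is done (a flag enables nothing further in this
version); quantization misses are absorbed by the seed redundancy and the
residue-level refinement. Ties in the vote ranking break
lexicographically by (model frame, query frame).

The top K = 50 frame pairs are converted to seed superpositions by
superposing frames (rotation = B_query · B_modelᵀ with axis columns). In
mixed mode each pair also emits the seed with the model frame's x and z
axes negated — a proper rotation — because the |cos θ| vote cannot
distinguish parallel from anti-parallel axis matches. Seeds that are
near-duplicates (rotation equal to 2 decimals, translation to 0.5 Å) are
collapsed, keeping the highest-voted representative: adjacent windows of
the same SSE pair generate essentially identical transforms, and
refinement from identical seeds cannot produce different alignments.

## Residue-level alignment

Under a fixed superposition the N×M similarity matrix is
M_ij = [1/(1 + d_ij²/d0²)]·[(δ_ij + w)/(1 + w)] for d_ij ≤ d_R, else 0,
where δ_ij = 1 iff the three-state labels agree, w = 1.0, and
d0 = max(1.24 (L − 15)^{1/3} − 1.8, 0.5) with L the query length (the
clamp keeps d0 positive for L ≤ 19, mirroring common TM-score practice;
`normalization="shorter"` switches L and the mTM normalization to the
smaller protein). The alignment is grown at d_1 = R0, d_2 = 1.5 R0,
d_3 = 2.5 R0 (R0 = 3.2 Å) under the *same* superposition, carrying
accepted segments forward and blocking their rows and columns.

At each cutoff, segments are selected greedily: the highest-scoring run
of strictly positive, unblocked entries along a forward diagonal (and
anti-diagonals in mixed mode; runs also stop at chain breaks of either
structure) is accepted while its summed score reaches S_min = 2.2, then
its rows and columns are blocked. Because every in-run entry is positive
and the score is their sum, the best segment on a diagonal is always a
*maximal* positive run — an exact simplification, not a heuristic — so
the search is a run-sum dynamic program over diagonals rather than an
enumeration of sub-segments. Since no cell exceeds 1, S_min = 2.2 forces
every accepted segment to span at least 3 residues; emitted alignments
therefore contain no 1–2 residue fragments and N′_ali always equals
N_ali. Score ties prefer forward direction, then the smallest (alpha,
beta) start; reverse segments pair (α+m, β−m).

Each seed's alignment is scored with mTM = (1/N) Σ M_ij(d_3) over aligned
pairs and refined: superpose by least squares on the current pairs
(Kabsch with proper-rotation correction — protein chirality forbids
reflections), re-run the three-step sweep, and keep the best-scoring
iterate; iteration stops when mTM improves by ≤ 1e-6 or after 30 rounds
(convergence is typically observed within a handful of iterations; the
cap is a safety net, and the keep-best contract means the result is never
worse than the seed's initial alignment). Alignments from all seeds are
deduplicated by exact segment-set equality and ranked by mTM, ties broken
by larger pair count, then seed rank. The best is returned first;
alternatives are available for inspection of sub-optimal solutions.

## Evaluation statistics

Q-score = 100 · |test ∩ reference| / |reference| over residue-index
pairs. Reference-independent statistics decompose the pair set into
maximal runs consecutive in both structures (model step +1 or −1):
N_ali = 100 · pairs / (smaller protein length); N′_ali additionally drops
runs shorter than 3; N_gap is defined connectivity-free as (number of
runs − 1) — for non-sequential alignments the per-sequence "gap opening"
notion is ill-defined, and the fragment count is the only reading that
survives arbitrary segment order (the definition is stated and kept
configurable). RMSD is the Kabsch optimum over all pairs. The TM-score of
a fixed mapping is maximized by iterating superposition on the subset of
pairs closer than max(d0, 4.8 Å) until the subset stabilizes, keeping the
best value; it is an in-repo implementation checked in the tests against
an independent single-shot scorer, not a port of any external program.

## Synthetic benchmark generator

Toy folds are built from ideal alpha-helices (radius 2.3 Å, rise
1.5 Å/residue, 100°/residue) and near-straight strand zigzags (axial rise
3.3 Å, lateral alternation ±0.9 Å), laid out as an antiparallel
bundle/sheet with seeded orientation jitter and connected by bulged
quadratic loop arcs. A deterministic sub-0.2 Å seeded perturbation is
applied to all generated coordinates: ideal helices place their window
points exactly on the element axis and planar arcs make consecutive
windows exactly coplanar, and either degeneracy parks hash coordinates
exactly on grid-cell boundaries — a measure-zero situation real
structures never produce. The default sampler draws 3–6 elements
(helices 11–16 residues, strands 8–12, loops 4–6) and clamps totals to
40–120 residues.

Segment permutation cuts the chain at the midpoint of every loop between
detected SSEs, shuffles the segment order with a seeded generator
(resampling until the order changes), leaves every coordinate untouched,
renumbers residues with a numbering gap at each junction (so the breaks
survive a PDB round trip), and records the ground-truth bijection. Loop
identification uses the package's own C-alpha assignment; no external
secondary-structure program is involved, and no loop remodeling is done —
the permuted structure is the same rigid body with a re-threaded chain,
so the unique zero-RMSD alignment is the recorded bijection.

What passing these tests shows — and does not. Ideal-geometry folds with
exact permuted copies test the search machinery (hashing, seeding, greedy
selection, refinement, reverse handling) under a known optimum; they do
not exercise conformational change, distorted or frayed SSEs, sparse
C-alpha-only experimental artifacts, or genuinely ambiguous similarity.
Scores on real analogous pairs will be lower and alignment choices less
clear-cut. Validation against curated external benchmarks (e.g. the
MALIDUP/MALISAM families of manually aligned pairs and their permuted
derivatives) requires downloading that data and is deliberately outside
the test suite; the CLI makes such a run straightforward.

## Parameters

| parameter | default | meaning |
|---|---|---|
| R0 | 3.2 Å | base distance cutoff; sweep uses (1, 1.5, 2.5)·R0 |
| h | 3.2 Å | hashing grid resolution |
| w | 1.0 | weight softening the SSE-type agreement factor |
| S_min | 2.2 | minimum accepted segment score (⇒ segments ≥ 3 residues) |
| K | 50 | seed superpositions carried to the residue level |
| max_refine_iters | 30 | refinement cap (typical convergence ≪ cap) |
| mode | forward | `mixed` additionally allows reverse fragments |
| normalization | query | length used in d0 and mTM; `shorter` available |

Problem sizes used by the test suite and the acceptance script (20
self-alignment folds, 50 permuted pairs, 10×5–10×10 rigid-invariance
trials, ≤12×12 matrices against exhaustive enumeration) keep a full run
in the low minutes on a single CPU while every pipeline stage is
exercised end to end.

## Known limitations

* Secondary structure is geometric and three-state; π/3₁₀ helices and
  frayed strand edges blur into coil, and assignment near chain breaks is
  conservative (coil), which slightly shortens detectable elements.
* Pairs whose similarity lies entirely in loops (no shared SSE type) are
  outside the model: the SSE-level stage finds no seed and the aligner
  reports an empty result rather than guessing.
* The greedy segment selection approximates the NP-hard segment-set
  optimization; each accepted segment is provably optimal on the current
  matrix, but the set as a whole is not guaranteed globally optimal.
* N_gap counts fragment breaks, not per-sequence gap openings; comparing
  against tools that report the latter requires care.
* mmCIF input is not supported in this version; PDB only.
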