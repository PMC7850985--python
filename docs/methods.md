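# Methods

## Problem and model

The input is a bait-centered interactome: a table of proteins co-purifying
with a bait in a pull-down, identified by LC-MS/MS, together with
protein–protein interactions among them from a STRING-style resource. The
goal is a ranked shortlist of the topologically most important members,
screened against annotation databases to nominate follow-up candidates.

The interaction network is an undirected simple graph on gene symbols.
Confidence scores (STRING combined scores, 0–1000, normalized to [0, 1])
decide only which edges exist; every topological quantity is computed on
the unweighted graph. Self-loops are dropped and reciprocal duplicate rows
are merged keeping the maximum confidence.

## Evidence filter

A protein enters the network when it has at least `min_unique_peptides`
unique peptides and at least `min_psms` PSMs (defaults 2 and 2). Published
per-protein tables carry only the total PSM count, so the default filter is
protein-level: `unique_peptides ≥ 2 AND total PSMs ≥ 2`. When a per-peptide
PSM table is available, a strict mode applies the sharper reading — at
least two peptides *each* supported by at least two PSMs; both modes are
provided because the two readings cannot be distinguished from protein-level
tables alone. Duplicate gene symbols (isoforms) are collapsed onto the
record with the most PSMs, since network nodes are symbols. The bait, never
detected in its own pull-down after immunodepletion, is added back
explicitly; it joins the network by default but is excluded from the final
ranked list (configurable), mirroring how such analyses report bait-free
rank tables.

## Node scores

Let *G* be the network, *n = |V|*. Per node:

- degree *k(v)*;
- local clustering coefficient *CC(v)* (0 when *k < 2*);
- betweenness *B(v)*, normalized by *(n−1)(n−2)/2*;
- closeness *Cl(v)*: **harmonic** closeness, the mean of *1/d(v,u)* over the
  other *n−1* nodes (unreachable nodes contribute 0). Harmonic rather than
  classical closeness is used throughout because node deletions routinely
  disconnect a sparse interactome, and the harmonic form stays finite and
  meaningful on disconnected graphs.

The **network centrality index** is
*C(G) = mean over v of (CC(v) + B(v) + Cl(v))/3*, a number in [0, 1]
(defined as 0 for a single-node graph). The **perturbation score** of *v*
is *P(v) = |C(G) − C(G∖v)|*: how much removing *v* shifts the network-level
average of the three centralities. The **disruption score** *D(v)* averages
the increase in shortest-path length over all pairs *(u, w)*, *u, w ≠ v*,
that are connected in *G*; when the deletion severs a pair, the pair
contributes the penalty *n − d_G(u,w)* — one more than the longest possible
finite distance, so fragmentation is always penalized more than any mere
detour — and the raw count of severed pairs is reported alongside (it is
positive exactly when *v* is an articulation point). These two scores exist
in the literature only as verbal descriptions; the formulas above are this
package's declared definitions, chosen to use exactly the named ingredients
while remaining finite on all graphs.

Per-deletion quantities are recomputed exactly on the deleted graph — no
incremental approximation — which is affordable at interactome scale
(~350 nodes) because centralities and distance matrices run in igraph's C
core. Pure-Python brute-force oracles (BFS distance matrices, betweenness
by exhaustive simple-path enumeration) live in `netprio.oracles` and verify
the fast paths to 1e−9 on hundreds of random graphs of up to 8 nodes.

## Rank aggregation

Each analysis (hub = degree, perturbation, disruption; higher is better)
yields dense ranks: tied values share a rank, the next distinct value takes
the next integer. The average of the three ranks is computed exactly — ties
are detected on the integer rank sum, never on the rounded display value —
and dense-ranked ascending into the cumulative (final) rank. The printed
average is rounded half-up to 2 decimals (28/3 → 9.33).

The shortlist takes whole cumulative-rank classes in order until at least
`ceil(fraction · N)` nodes are covered (default fraction 0.05). Tie classes
are never split, so the shortlist can exceed the nominal 5 % — with 347
proteins the floor is 18 and tie expansion can yield 20, matching how a
rank list with dense ties naturally overshoots a percentage cutoff.

## Annotation screen

Annotations are three-valued: a symbol absent from a table (or a blank
cell) is *unannotated*, distinct from false — database lookups are
incomplete, and treating absence as a negative would fabricate evidence.
Final candidates must be annotated **true** for every criterion of the
configured conjunction; unannotated symbols are reported separately and
never qualify. The report carries per-criterion provenance labels because
the criteria come from different sources (tissue atlas, disease database,
apoptosis resources).

The embedded 20-protein reference annotation table gives, over the
shortlist: prostate expression 16, prostate cancer 15, metastasis 2,
apoptosis 15; prostate-cancer ∧ apoptosis is 14 by these flags although the
accompanying narrative states 13 — the table is taken as authoritative and
the discrepancy is documented here rather than resolved.

## Synthetic data

The generators emulate the structure the analysis assumes, not the
underlying measurements:

- `generate_network` — preferential attachment by default (heavy-tailed
  degrees, like real interactomes; default m = 2 edges per new node),
  with Erdős–Rényi and ring-lattice topologies retained for symmetric and
  degenerate oracle cases. An optional planted hub wires one node to a
  chosen fraction of all others, giving a known ground-truth top node.
  Edge confidences are uniform on [0.4, 1.0] — the STRING medium-or-better
  band — quantized to 3 decimals so files round-trip exactly.
- `generate_identifications` — exactly `round(pass_fraction·n)` records
  satisfy the default thresholds; failures split between too-few-peptides
  and single-PSM modes. The study-scale configuration (n = 672, pass
  fraction 347/672) mirrors the real reduction from 672 identifications to
  a 347-protein interactome.
- `generate_annotations` — independent Bernoulli draws per criterion at
  stated prevalences.

All generators are fully determined by their seed. What passing tests on
synthetic data do **not** show: real interactomes have correlated
annotations, degree-dependent study bias, and STRING's own evidence
structure; the generators make no attempt at spectra, peptide sequences or
those correlations. The embedded published tables are therefore the
fixtures for exact-reproduction checks, and the synthetic generators cover
scale, determinism and recovery properties only.

## Numerical choices and edge cases

- Node iteration is lexicographic by gene symbol everywhere, so score
  tables, rank tables and written files are byte-stable across runs.
- Betweenness normalization for *n < 3* and closeness for *n < 2* are
  defined as 0; the centrality index of a single-node or edgeless graph
  is 0.
- Perturbation requires ≥2 nodes, disruption ≥3; a node with no eligible
  connected pairs (e.g. every leaf) has disruption 0 and 0 severed pairs.
- Proteins with no interactions are kept as isolated nodes by default so
  they receive (worst) ranks instead of vanishing from the ranked list.
- Half-up decimal rounding is used for displayed averages; comparisons
  never use the rounded value.
- The STRING cutoff default is 0.4 and is recorded in network metadata and
  the run manifest, since no single cutoff is canonical.

## Problem sizes used in checks

Oracle equivalence runs 200 random graphs of 2–8 nodes (brute-force path
enumeration is exponential, so oracle graphs stay tiny); planted-hub
recovery runs 20 seeded 200-node preferential-attachment networks with the
hub at 50 % connectivity and requires cumulative rank 1 in at least 18
runs; shortlist tie semantics are exercised on 347-node rank tables with
integer-valued tied metrics. These sizes keep the full suite and the
acceptance script to well under a minute each while exercising every code
path at study scale.

## Known limitations

- The perturbation/disruption definitions are declared substitutes for
  verbally described scores; other formalizations (e.g. classical
  closeness, different severed-pair penalties) would change absolute values
  though rarely the induced ranking of clear hubs.
- All centralities are unweighted; confidence-weighted variants are out of
  scope.
- The screen performs no live database queries; annotation tables are
  user-supplied files with user-chosen truth tokens.
- Per-deletion recomputation is quadratic-ish in nodes times edges and is
  not intended for networks beyond a few thousand nodes.
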