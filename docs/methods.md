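# Methods

## Model

The pipeline treats pathway membership as the only trustworthy relation
between genes and biology-level function: the inputs are curated gene sets
and a differential-expression table, neither of which documents gene–gene
interactions. The network is therefore strictly bipartite — gene nodes on
one side, pathway nodes on the other, an edge when a *retained* gene (below)
belongs to the pathway. No gene–gene or pathway–pathway edges are inferred;
pathway crosstalk is summarised separately in a weighted projection whose
edge weight is the exact count of retained genes two pathways share.

**Retention.** A feature is retained when its adjusted p-value is strictly
below `alpha_deg` (default 0.05). Significant genes that belong to no loaded
pathway are excluded from the graph rather than kept as isolates — isolates
depress global efficiency uniformly without carrying ranking information —
and their count is reported. Pathways with no retained gene are absent from
the network. The anchor pathway must retain at least one gene; otherwise the
analysis is refused rather than silently degraded.

**Connectedness.** Global efficiency, E(G) = mean over unordered node pairs
of 1/d(u,v) with 1/∞ = 0. It is bounded in [0,1], equals 1 exactly on
complete graphs and 0 exactly on edgeless ones, and — decisive here — varies
continuously as a graph fragments, so removal of a cut vertex is penalised
in proportion to how much it severs. The obvious alternative,
largest-component fraction, is piecewise constant and cannot rank genes
within a component; it was rejected for that reason. The metric sits behind
one function (`connectedness`) so an alternative can be swapped without
touching the centrality code. Shortest paths are computed by
`scipy.sparse.csgraph` over a deterministically ordered node list; the test
suite carries an independent pure-Python BFS implementation and requires
agreement to 1e-12.

**Node-removal centrality.** s(g) = E(M − g) − E(M), computed by full
recomputation per gene (no incremental shortcut; networks here are
desk-scale, hundreds of nodes). Negative scores mark central genes, positive
scores peripheral ones — removing a leaf raises the mean inverse distance of
the remainder. Pathway nodes are never removal candidates. Ordering is by
ascending score; ties break by higher membership degree, then lexicographic
id, making every ordering reproducible.

**Ordered enrichment.** For each pathway with K members inside the universe
(size N), and each prefix length k of the central-gene ordering, the
hypergeometric upper tail P(X ≥ x_k | N, K, k) is evaluated and the minimum
over k is reported with its arg-min prefix k*. This is the standard
formalization of ordered-query enrichment; the minimum-over-prefixes
statistic is intentionally anti-conservative and is used for ranking, with
Benjamini–Hochberg correction applied across pathways as a convention, not
as exact error control. Exactness of the tail itself is tested against
exhaustive enumeration of all C(N, K) membership placements for N ≤ 12.

## Pathway prioritization

The three parameters are deliberately simple, monotone, [0,1]-bounded and
deterministic; each sits behind its own function so alternates can be
substituted independently.

1. **Impact similarity.** impact(p) = mean over retained genes of
   (−s(g))·|log2fc(g)| — a pathway scores high when its genes are both
   structurally central and strongly regulated. Divergence from the anchor,
   |impact(p) − impact(anchor)|, is min–max normalized over non-anchor
   pathways and flipped: similarity = 1 − normalized divergence. The anchor
   is 1 by convention and excluded from the normalization (it is the
   reference, not a competitor). Degenerate spread (all divergences equal,
   including the single-pathway case) maps everything to 1.
2. **Connection strength.** raw(p) = w·Ochiai(sig(p), sig(anchor)) +
   (1−w)·1/(1 + hop(p, anchor)), default w = 0.5, where Ochiai =
   |∩|/√(|sig(p)|·|sig(anchor)|) and hop is the membership-graph distance
   between the pathway nodes (sharing a gene ⇒ hop 2; unreachable ⇒ the
   distance term is 0). Min–max normalized over non-anchor pathways; anchor
   = 1. If every raw value coincides, the common value 0 maps to 0 (nothing
   is connected) and any positive common value maps to 1.
3. **Key-regulator index.** Eigenvector centrality on the weighted pathway
   projection. Because the leading eigenvector of a disconnected graph is
   supported on one component only, components are solved separately by
   power iteration (tolerance 1e-10 in the max norm) and each component's
   max-normalized vector is scaled by its Perron value relative to the
   largest, so hubs of equally strong components tie at 1 and weaker
   components score proportionally lower. Plain power iteration can
   oscillate on bipartite-structured components (eigenvalues come in ±λ
   pairs), so the iteration runs on A + cI — same eigenvectors, strictly
   dominant top eigenvalue — and the shift is subtracted afterwards.
   Isolated pathways score 0.

**Combined coefficient.** The weighted arithmetic mean of the three
components (default weights 1/3 each, configurable, must sum to 1), ranked
descending; ties break by similarity then name; the anchor is excluded from
the ranked list. The listing rule is strict: a pathway passes only when
combined > 0.35; a pathway at exactly 0.35 fails.

**Chains.** Minimum node distance from a query gene set to a target pathway
is a BFS over the membership graph, in membership-edge units (gene inside
the target pathway ⇒ distance 1). Among equally short chains the
lexicographically smallest node sequence is returned, found greedily by
descending the BFS distance labels. Query genes absent from the network are
reported and skipped; only an entirely absent query set is an error.

## Coordinated-expression scan

The scan walks the central (negative-score) sublist in importance order and
accumulates +1 per upregulated, −1 per downregulated gene; genes with
log2fc exactly 0 contribute 0 but stay in the list so ranks are preserved.
Zone detection: the windowed slope at offset i is
(S[i+window] − S[i])/window (defaults: window 10, threshold 0.6); offsets
with |slope| ≥ threshold form same-sign runs; runs of equal sign separated
by fewer than window/2 offsets are merged; a run [a, b] becomes the zone
[a, b + window] with strength |S[end] − S[start]|/(end − start) ∈ [0,1].
Zones are ranked by strength — the pipeline does not assign letters like
"zone A"; the strongest zone is simply first. A windowed-slope run rule was
chosen over maximum-subarray-style detection because the object of interest
is a *sustained* slope, not a maximal excursion. Per-pathway coordination
strength is |#up − #down|/#nonzero over the pathway's listed genes.

The detector's boundaries are accurate to roughly one window: windows that
straddle a block edge qualify whenever the adjacent background happens to
lean the same way, and the merge rule can attach a chance-coordinated
background run outright. On random ±1 backgrounds around a planted 30-gene
block, the median two-sided boundary error is about 6 ranks, but the
right tail is heavy — roughly one background in eight produces an error
beyond one window. This is a property of the detection rule on random
backgrounds, not an implementation artifact, and the acceptance measurements
report the boundary-error distribution (median and max) rather than
pretending a hard per-seed guarantee.

## Synthetic data

The generator emulates the study design the pipeline targets — a
proteome-wide treated-vs-vehicle contrast analysed against a pathway
database — at desk scale: 500 features, 40 pathways of 10–30 members,
overlap induced by copying a fraction (default 0.2) of members from an
earlier pathway, ~35% of features significant, significant |log2fc| around
scale 1.5 (folded normal + 0.1 offset, random sign), significant p-values
uniform on [1e-6, α) and non-significant uniform on [α, 1] — the flag, not
the p-value's distribution, is what matters downstream. Planted structure:

- *near-anchor pathway*: copies half its members from the anchor;
- *far pathway*: built from a private gene pool used by no other pathway,
  hence provably disconnected from the anchor (membership distance ∞ ≥ 4)
  and with connection strength and regulator index both 0, so its combined
  coefficient is at most 1/3 and can never pass the 0.35 rule;
- *regulator gene*: swapped into 70% of pathways (sizes stay in range);
- *zone*: a stored random ordering of the significant genes with a block of
  co-directed fold-change signs at known ranks;
- a few members of the anchor and of each planted pathway are forced
  significant so the planted structure survives the DEG filter (skipped
  when the requested significant fraction is 0).

What the generator does **not** model: mass-spec intensities, missing
values, quantification noise, identifier ambiguity, or realistic pathway
size/overlap distributions. Tests passing on synthetic universes show the
*algorithms* recover planted structure under the stated generative
assumptions; they do not certify behavior on real proteomes, where
significance calls and annotation coverage are far messier.

The motif fixture is a 400-residue synthetic receptor C-terminus (labelled
synthetic in its id) whose background alphabet excludes V and P, making the
five planted VxPx sites (212, 277, 300, 331, 377) the only possible matches
— the 5-hit count is analytically certain, not probabilistic.

## Problem sizes and numerical choices

Recovery measurements run 20 universes at n_genes = 250, n_pathways = 25,
frac_significant = 0.4 (≈100 significant genes, so the 30-gene block at
ranks 41–70 sits inside a 100-rank scan list); oracle cross-checks use 50
random bipartite networks of ≤ 40 nodes; enrichment enumeration covers
universes up to N = 12. Node-removal scoring is exact full recomputation;
all normalizations are min–max with the degenerate cases defined above;
floats in output tables are written with 6 significant digits and all
orderings (node lists, tie-breaks, dict iteration) are fixed, so repeated
runs with the same seed are byte-identical.

## Limitations

- The three prioritization parameters and their combination are this
  package's own formalization of an informally described scheme; rankings
  are meaningful relative to the stated formulas, not canonical.
- The min-prefix enrichment p is a ranking statistic, not a calibrated
  p-value (see above).
- Eigenvector centrality on near-degenerate projections (two components
  with nearly equal Perron values) can re-order under tiny weight
  perturbations; the power-iteration tolerance (1e-10) is far below any
  biologically meaningful difference.
- Pathway identifiers are opaque case-sensitive strings; mapping between
  gene and protein namespaces is the caller's responsibility.
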