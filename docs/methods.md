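# Methods

## Coordinate and format conventions

All coordinates are 0-based, half-open `[start, end)` (BED/BEDPE
convention). Pairs-format positions are 1-based on disk and converted on
read; each pair becomes a contact record with anchors of `anchor_width`
(default 1 kb, a conservative working resolution for MNase-digested
material — configurable) centered on the reported position. Species is
assigned by chromosome-name prefix (default `mm_` for the mouse spike-in),
the standard combined-reference idiom; chimeric target/spike pairs are
dropped with a logged count. Loops and contacts are order-normalized so
anchor1 ≤ anchor2; normalization is idempotent. The bedGraph reader requires
intervals aligned to the declared bin size — the writer guarantees this, and
rejecting foreign unaligned files keeps the round trip exact rather than
silently resampling.

## AQuA normalization

Each sample's scale factor is `10⁶ / N_spike`, where `N_spike` counts spike
pairs weighted by record count (counts, not records, are the unit of
signal). `aqua_cpm = raw_count × scale` is linear in the raw count and
inversely proportional to spike depth; ordering by AQuA-CPM within a sample
equals ordering by raw count. This spike-anchored scaling is this package's
convention for AQuA-CPM: it preserves the essential spike-in property —
absolute cross-sample comparability under equal spike input — and is
isolated in a single operation (`compute_aqua_factors`) so an alternative
factor involving the target total could be swapped in. Samples without
spike pairs raise an explicit error directing the user to disable AQuA mode.

## 3D element calling

**Filtering.** Cis loops pass when `min_distance ≤ distance ≤ max_distance`
(anchor-midpoint distance; defaults 5 kb–2 Mb) and `aqua_cpm ≥ min_aqua_cpm`.
Trans loops are dropped with a logged count, since distance and boundary are
undefined across chromosomes. Cis loops below `min_distance` are reported
separately as 2D-peak (self-contact) candidates rather than classified: no
independent threshold defines a 2D peak from the filtered set, so the
channel is isolated and the decision reversible.

**Clustering.** Two loops are connected when any pair of their anchors,
each expanded by `pad` bp (default 0 — shared/overlapping ends; exposed
because MNase anchors may abut), intersects. Components are computed by a
sorted-endpoint sweep feeding a union-find: anchors on one chromosome are
swept in coordinate order, runs of transitively overlapping (pad-expanded)
anchors are merged, and each loop unions its two anchor runs. This equals
the connected components of the pairwise-overlap graph; tests verify exact
partition equality against a brute-force transitive-closure oracle
(networkx over explicitly enumerated edges) on random instances at pads 0
and 500. Component ids are dense from 0 in leftmost-boundary order;
components with ≥ `min_loops` (default 3) members are labelled `cluster`,
smaller ones `loop`.

**Ranking.** Connectivity is the AQuA-CPM sum of target contacts whose
anchors *both* lie inside the component boundary (min to max member-anchor
coordinate, expandable by `pad`; default expansion 0). Both-anchor
containment is used because single-anchor containment would count contacts
leaving the cluster. Ties are broken by leftmost boundary, making the
ranking invariant to input order.

**APA.** For each loop the `n_bins × n_bins` (odd, default 21) grid of
`bin_size` (default 5 kb) cells centered on the anchor-midpoint pair is
accumulated in AQuA-CPM and divided by the loop count: units are contacts
per million spike pairs per loop, with the loop in the central cell.
Total matrix mass × loop count equals the AQuA-CPM sum of window-contained
contacts counted with multiplicity (conservation, tested).

## Pol2 metrics

The 1D view is a two-ended pileup: every contact record adds its count to
the bins overlapped by each of its two anchors (fractional by bp overlap),
so track mass = 2 × Σcounts exactly.

Windows are strand-oriented and derived from the gene model (TSS =
`start` on +, `end−1` on −):

| window    | definition (transcription direction)           | default |
|-----------|------------------------------------------------|---------|
| pause     | TSS−30 … TSS+300                               | 330 bp  |
| promoter  | TSS−1000 … TSS+300 (overlaps pause by design)  | 1300 bp |
| body      | TSS+300 … TES                                  | gene    |
| post-TES  | TES … TES+3000                                 | 3 kb    |

`pause_ratio = (d_pause + ε) / (d_body + ε)` and
`loading_ratio = (d_promoter∪body + ε) / (d_postTES + ε)`, where `d` are
mean per-bp densities; density, not summed signal, makes unequal window
lengths comparable (the standard traveling-index convention). The
pseudocount ε (default 0.1 density units) keeps silent genes finite and is
reported in every output header alongside the raw densities. With ε = 0 the
ratios are exactly invariant to multiplying the track by a positive
constant; the scale-invariance test asserts this in the ε = 0 limit since a
fixed additive ε is deliberately not scale-free. The post-TES window is
truncated at the track edge with a warning; genes shorter than the pause
extension have no body window and raise. Minus-strand genes are exact
mirrors: metrics on a reflected track and gene equal the forward values to
floating precision (tested). The post-TES window length and the summed-vs-
averaged convention are both parameterized, since reasonable alternatives
exist.

`tumor_volume(L, W) = 0.5 × L × W²` (caliper/MRI convention, L ≥ W, swapped
with a warning) and `fold_change(a, b) = a/b` support the small study
arithmetic around the main analysis.

## The synthetic experiment

`SimulationConfig` defaults define the study conditions: one 2 Mb target
chromosome and one spike chromosome; 20 genes (8–16 kb) in 100 kb slots;
5 planted clusters of 3–6 loops; 20 background loops; 100 000 pairs per
condition with spike fraction 0.09 (the 100 ng spike per ~1000 ng target
input proportion); coverage depth 100 000 expected reads per gene; pause
strength 4, loading ratio 2, condition effect 2.

**Contacts.** Each planted cluster is a chain of k+1 anchors with k
consecutive loops sharing ends, spaced 8–12 kb — inside the default distance
band and provably recoverable as one connected component. Planted loops
carry 20–60 raw counts, background loops 1–2; the generator also reports a
suggested `min_aqua_cpm` midway between those bands so background is
filtered out. Target pairs comprise the loop contacts (placed at anchor
midpoints, making boundary containment and APA centering exact) plus uniform
short-range scatter to reach the configured depth; spike pairs are binomial
at the spike fraction (deterministic rounding with noise off). The loop
structure is shared between conditions; draws differ by seeded stream.

**Coverage.** Per gene, segment densities are piecewise constant over
enhancers (two 1 kb elements 5/8 kb upstream, 2× body density), promoter
rest, pause window, body, and post-TES. Ground truth is defined as the
fixed point of the package's own estimators: pause density is
`p·(d_body+ε) − ε` and post-TES density `(d_num+ε)/R − ε`, so the measured
ε-pseudocount ratios equal the configured `p` and `R` exactly without noise.
The control body density is solved in closed form (the expected mass is
affine in it) so per-gene mass equals `coverage_depth`. Gene and window
coordinates land on a 10 bp grid matching the default coverage bin, so
noise-free window queries are exact. Noise is Poisson per bin — the standard
count model for sequencing data.

**Conditions.** The first half of genes is "crtf"-like, the second
"target"-like. In the treated condition, crtf genes get loading ratio ×
`condition_effect` with pause unchanged, plus a 1.5× body gain so
enhancer/promoter/body densities rise in absolute terms while the post-TES
density falls (the treated track is deliberately not renormalized to the
control mass — the absolute contrast is the point of spike-anchored
normalization); target genes get pause ratio × `condition_effect` with
loading unchanged.

**What the generator does not model**, hence what passing tests do not
show about real data: restriction/MNase fragment structure, distance-decay
of polymer contacts, reproducibility noise between biological replicates,
mappability and copy-number artifacts, overlapping or nested genes, trans
contacts, and any change in loop *number* between conditions. Recovery
results on this generator certify the algorithms' correctness on their
stated model, not robustness to those real-world effects.

## Pipeline

`run_pipeline` validates all inputs first, then per condition: species
split and AQuA factors (JSON report), normalization, filtering (filtered
and 2D-candidate BEDPE), clustering + ranking (component TSV), APA (TSV
grid), pairs-derived coverage (bedGraph), and gene metrics; then a
cross-condition delta report (per-gene ratio deltas and per-segment density
deltas). Gene metrics run on the manifest's coverage bedGraph when provided
— synthetic contact pairs encode loop structure, not 1D pause geometry — and
on the pairs pileup otherwise. Every table carries `#` headers naming the
thresholds, windows, ε and pad used; identical config + inputs give
byte-identical tables (timings live only in `run_summary.json`). Any stage
error aborts with the stage name and offending input. The demo (20 genes,
100k pairs) runs in a few seconds on one CPU; test problem sizes (≤ 50-loop
oracle instances, 100 replicates per grid point at 1e5 reads/gene) were
chosen to exercise each property at scales where the oracles are exact.

## Known limitations

- Binary `.hic`/`.cool` ingestion is out of scope; convert to pairs text or
  BEDPE upstream.
- No statistical loop calling or significance testing — the filter is
  threshold-based, as in the procedure it implements.
- The AQuA factor convention (per million spike pairs) is one of the
  reasonable choices; see the normalization section.
- Phosphorylation-state-specific Pol2 behavior and nascent-RNA dynamics are
  outside the 1D/3D signal model.
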