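# Methods

## Problem setting

Metazoan mitochondrial genomes encode 13 protein-coding genes (PCGs) in
compact, mostly tRNA-punctuated polycistronic units. Homology search
locates these genes approximately but systematically short of their true
boundaries, and the exact boundaries are genuinely ambiguous: stop codons
may be incomplete (`T`/`TA`, completed to `TAA` by polyadenylation of the
mRNA), start codons vary by lineage and are often non-canonical with
respect to the NCBI code tables, and AT-rich sequence offers many spurious
codon matches. `mitobound` treats boundary refinement as a scoring problem
over candidate start/stop positions, with all empirical parameters keyed
by (NCBI genetic code table, gene), since codon usage and gene length vary
strongly along both axes.

## Scoring model

For a hit with target codon interval `[s_s, s_e]`, profile columns
`[q_s, q_e]` (1-based amino-acid columns) and profile length `l_q`:

* **Candidate sets.** The in-frame center is `c = floor((s_s+s_e)/2)`.
  `S` holds the codons scanned upstream from `c` until the first full stop
  codon of the applicable table (the stop itself excluded) or, for linear
  sequences, the edge; `E` holds the codons scanned downstream from `c`
  through the nearest full stop codon (included). On circular genomes both
  scans wrap and are capped at one genome length so they always terminate.
  Candidates with zero ϕ are pruned. Codons containing ambiguity
  characters are neither candidates nor scan terminators.
* **δ (alignment projection).** Inside the hit,
  `r_s(p) = q_s + slope·(p−s_s)` with `slope = (q_e−q_s)/(s_e−s_s)`, and
  `δ_s(p) = 1 − r_s(p)/l_q`; for the stop, `r_e(p) = (l_q−q_e) +
  slope·(s_e−p)` and `δ_e(p) = 1 − r_e(p)/l_q`, so both factors approach 1
  as a candidate approaches the corresponding projected gene boundary.
  Outside `[s_s, s_e]` both are fixed at 1, reflecting the systematic
  under-coverage of hits. δ arithmetic runs in codon units so that `r` and
  `l_q` are commensurable. An alternative reading of the stop projection,
  `r_e(p) = (l_q−q_s) + slope·(p−s_s)`, *decreases* toward the 3′ end of
  the hit and can go negative at `p = s_e`; because that contradicts the
  stated role of δ it is not the default, but it is preserved behind
  `literal_delta_e=True` / `--literal-delta-e` for comparison.
* **ϕ (codon usage).** Empirical frequencies of annotated start, stop and
  internal codons per (table, gene). Start codons with frequency < 0.01
  (default `start_min_freq`) are treated as annotation noise and dropped.
  Codons whose internal frequency is ≥ 0.001 (default
  `internal_stop_max_freq`) cannot be stops. Incomplete stops are tallied
  under the pseudo-codons `TA-` and `T--` and stored *unadjusted*; at
  scoring time a `TA` candidate uses ϕ/3 and a `T` candidate ϕ/12,
  because the corresponding full codons (`TAA`, `TAN`) are already
  scored and a 2-mer/1-mer prefix matches by chance 3× and 12× more often
  than the specific full codons it subsumes. Incomplete-stop candidates
  are emitted at *every* in-frame window position with a matching prefix,
  not only next to tRNAs; the /3, /12 corrections together with δ and λ
  are the guards against chance hits.
* **λ (length plausibility).** `λ(l) = 2·min(L≤,l , L≥,l)/(L≤,l + L≥,l)`
  over the per-species reference CDS length multiset; species whose gene
  has length exactly `l` count on both sides (taken literally from the
  formula, so the denominator can exceed the species count). Lengths are
  in nucleotides including the (possibly incomplete) stop: reference CDS
  lengths are often not multiples of 3, so nucleotides is the only unit in
  which reference and candidate lengths are comparable. A species with
  several copies of a gene contributes its longest copy only.
* **Search.** The returned pair maximizes
  `δ_s·ϕ_s·δ_e·ϕ_e·λ(3·(e−s)+end_offset)` over `S×E`, skipping pairs
  whose span fully contains a tRNA locus (one locus per tRNA gene name is
  considered; partial overlaps are allowed, since real mitochondrial genes
  overlap tRNAs and each other). Ties are broken deterministically: longer
  gene, then start closer to `s_s`, then leftmost start. If `S` (or `E`)
  is empty the corresponding raw hit boundary is used and flagged; the two
  fallbacks are independent (an empty `S` still refines the stop by
  maximizing `δ_e·ϕ_e·λ` with the start pinned at `s_s`). If every
  admissible product is zero, both boundaries fall back.

The legacy baseline simply takes the nearest canonical start/stop codon
of the NCBI table within ±6 amino acids (configurable) of each raw
boundary, preferring the upstream position at equal distance, and keeps
the raw boundary when none is found. It models neither non-canonical
starts nor incomplete stops.

## Coordinates

Everything internal is 0-based half-open on the forward strand. Hits are
expressed in a gene-local frame: `frame_anchor` is the coordinate of codon
index 0 on the gene-local axis (the forward axis for `+` hits, the
reverse-complement axis for `−` hits), which keeps the δ/codon arithmetic
strand-agnostic; predictions are mapped back to forward coordinates at the
end. Features crossing the origin of a circular genome keep
`start < end` by letting `end` exceed the genome length, with modular
sequence extraction.

## Evaluation harness

Predicted and reference features are paired per gene symbol by
bidirectional largest overlap (each must be the other's maximal-overlap
partner, same strand). Signed boundary differences are strand-aware:
positive means the predicted boundary lies outside the reference gene.
The summary reports mean and standard deviation (population convention —
the convention is a free choice and divide-by-N keeps the single-pair case
well-defined) of absolute per-boundary differences, and the fraction of
genes whose *larger* absolute boundary difference is ≤ 0, 3, 9, 30 bp.
On circular genomes differences take the shorter arc when the genome
length is supplied. A cumulative-curve table on an arcsinh axis is
available for plotting.

## Synthetic data generator

`mitobound.synthetic` emulates exactly the structure the predictor
consumes: per species, the 13 PCGs in canonical order with (i) a start
codon drawn from a configurable categorical distribution (default 60% ATG,
20% ATA, 15% ATT, 5% GTG — an invertebrate-like mix), (ii) internal codons
drawn uniformly from the non-stop codons of the configured table, so true
frames are always stop-free, (iii) a stop drawn from a categorical over
full stops and the incomplete prefixes (default 55% TAA, 20% TAG, 15% T,
10% TA — T more common than TA, as observed in annotations), (iv) protein
lengths normal around realistic per-gene means (sd 5 aa by default), (v)
one ~70 bp tRNA locus before each gene and AT-rich spacers (5–40 bp,
base composition 35/15/15/35), plus a 100–300 bp control-region-like tail,
and (vi) `nad6` on the minus strand, vertebrate-style. Approximate hits
are the true genes truncated at each end by an independent uniform draw of
0–10 codons (hits never extend beyond the truth), with `q_s`, `q_e`, `l_q`
set consistently. One seed drives everything through per-species
substreams; fixed seed ⇒ byte-identical output.

What the generator does **not** model: sequence evolution or phylogenetic
correlation between species, compositional biases within genes, gene
overlaps, duplicated or missing genes, frameshifts/out-of-frame starts,
and annotation errors in the reference set. Tests passing on these
fixtures therefore validate the statistical and coordinate machinery, not
performance on real reference databases.

## Problem sizes and experiment design

The recovery experiment trains on 500 simulated species and evaluates on
100 held-out species (1300 genes), a size at which the empirical ϕ and λ
tables are stable while the whole experiment stays in the seconds range.
Under strictly canonical conditions (ATG-only starts, full stops, hit
shrink ≤ 10 codons) it recovers ≥ 90% of starts and > 99% of stops
exactly. With realistic mixed start codons, exact-start recovery drops to
roughly 75–85%: a rare true start (GTG, ATT) competes against chance ATGs
with far higher ϕ nearby, and λ cannot always break the tie. This mirrors
the inherent ambiguity of start-codon assignment; stop prediction is
nearly unambiguous when stops are complete because the candidate window
ends at the first in-frame stop. The exhaustive-oracle equivalence check
runs on 200 simulated genomes under 2 kb (two short genes each, one on the
minus strand) against an independently written brute-force scorer.

## Numerical and degenerate-input choices

* δ values are clamped to [0,1]; the analytic range is [0,1] under the
  hit invariants, but floating-point rounding can exceed it by one ulp
  (e.g. `q_e = l_q` at `p = s_e`).
* Candidate pairs with product exactly 0 are never selected; "no positive
  product" triggers the fallback.
* CDS shorter than 6 nt are skipped (with a warning) when counting
  codons; zero-total categories omit their key.
* Statistics files are versioned JSON; loading rejects unknown schema
  versions.
* Ambiguity codes: codons containing N translate to a distinguished
  UNKNOWN value, are never stops, and are excluded from candidate sets.

## Known limitations

* Out-of-frame starts (e.g. the *Drosophila* cox1 AUAA quadruplet) are
  out of scope, as is de novo gene finding — hits are inputs.
* Boundary refinement quality is bounded by the reference statistics; a
  gene/table key absent from the statistics is an error by design rather
  than a silent fallback.
* The tRNA-exclusion constraint assumes the provided tRNA set is already
  reduced to one best locus per tRNA type; deduplication here keeps the
  first locus per gene name, with no score to rank alternatives.
* The GenBank reader covers CDS/gene/tRNA spans and `/transl_table`; it
  is not a general feature-table parser.
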