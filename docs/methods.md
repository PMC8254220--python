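# Methods

## The annotation model

A proteome is annotated by matching each protein against a library of
profile HMMs, one per CAZy family or subfamily (dbCAN-style), and parsing
the per-domain tabular output (`--domtblout`). Both HMMER orientations are
supported and must be declared: `hmmsearch` (proteins are targets, the
default) and `hmmscan` (proteins are queries); the two differ only in which
name/length columns describe the protein versus the model. All coordinates
are 1-based inclusive, matching the file format.

Three rules turn raw domain hits into accepted annotations:

1. **E-value.** A hit is kept iff its *full-sequence* E-value is
   ≤ 10⁻¹⁵. The comparison is inclusive because HMMER's `-E` reporting
   threshold is inclusive; a hit at exactly 10⁻¹⁵ is kept.
2. **HMM coverage.** The domain must span ≥ 35% of the profile:
   (hmm_to − hmm_from + 1) / hmm_length ≥ 0.35, inclusive.
3. **Overlap resolution.** Among the survivors on one protein, hits are
   visited best per-domain i-Evalue first (ties: higher bit score, then
   left-most start, then family name) and accepted iff their overlap with
   every already-accepted hit is ≤ 20%. Overlap is shared protein residues
   divided by the shorter of the two aligned spans — the convention of the
   dbCAN parser lineage. With exactly two conflicting domains the greedy
   procedure reduces to "keep the better E-value"; the greedy extension is
   the natural generalization to three or more mutually overlapping
   domains and is verified against a brute-force pairwise-constraint
   replay in the tests.

Rules 1–2 use the full-sequence E-value (that is what `-E` thresholds);
rule 3 uses the independent per-domain i-Evalue, because resolving two
domains on one protein is a per-domain question. Rejections record the
first failed rule (E-value before coverage) for auditability, and proteins
whose every hit was rejected are retained in an audit table rather than
silently dropped.

## Counting and profiles

The counting unit is the distinct (protein, family) pair — a gene, not a
domain. A protein with two accepted GH5_22 domains contributes one GH5_22;
a protein with GH10 + CBM13 contributes to both families. The class of a
family is its letter prefix (GH5_7 → GH; CBM13 → CBM). Headline totals
exclude the GT class, which is dominated by biosynthetic transferases
rather than degradative enzymes; `total_excl_gt` drives species ranking
and tree heat annotation.

Substrate heatmap counts assign each family's genes to nine
polysaccharide-degradation categories (β-glucan, cellulose, chitin,
lignin, mannan, pectin, starch, xylan, xyloglucan; spelled `beta-glucan`
in the machine-readable map). Categories are not disjoint: a GH5 gene
counts once in each of cellulose, mannan, xylan and xyloglucan, and a GH3
gene in β-glucan, cellulose, xylan and xyloglucan — the published
assignments for these poly-specific families. The rest of the shipped map
is a conservative set of canonical family→substrate activities; it is a
plain TSV the user can replace wholesale, and it makes no claim to
reproduce any particular study's unpublished full table. Lookups are
subfamily-aware (GH5_7 falls back to GH5 unless listed). CBMs count toward
class totals but map to no substrate (non-catalytic). Families absent from
the map are reported as unmapped rather than silently ignored.

Tree heat annotation maps the minimum GT-excluded total to the lightest
palette color and the maximum to the darkest with linear RGB
interpolation; equal totals map everything to mid-palette with a warning,
and leaves without a profile get a neutral grey and a mismatch report.

## De-duplication

Public proteomes often carry near-identical isoforms. Representatives are
chosen by greedy longest-first clustering at 98% identity: sequences are
visited longest first (ties by id) and join the first accepted
representative whose identity is ≥ the threshold, else found a new
cluster. Identity is the maximum number of exactly matching residues under
a global alignment with cost-free gaps, divided by the shorter sequence's
length; `X` matches nothing, including itself. This mirrors the accepted
order of greedy-incremental clustering tools without their word-index
heuristics; near the default threshold only near-identical isoforms are
merged, so boundary behavior is not analysis-critical. The brute-force
all-pairs oracle in the tests confirms every member–representative pair
meets the threshold for small inputs.

## Xylanolytic reporting

The xylanolytic family set defaults to CE1/CE4/CE5/CE15 (de-acylating
esterases), GH3 and GH5 with all subfamilies (poly-specific
exo-glycosidases/hydrolases), GH10 and GH11 (endo-xylanases), GH30
(glucurono-/exo-xylanases), GH43/GH51/GH62 (arabinofuranosidases) and
GH67/GH115 (glucuronidases). Base names in the set match all their
subfamilies. Copy notation renders k gene copies as `FAMILY(k)` and
round-trips through the parser. Prevalence is the number of species
carrying ≥ 1 copy over the dataset size; a family is unique when that
number is 1.

The packaged reference table transcribes a published 12-species
xylanolytic comparison. Two of its printed per-species totals disagree
with the sum of their printed entries by exactly one (Sc. stipitis: 17
printed vs 18 summed; B. raffinosifermentans: 27 vs 28). Both readings are
stored; validation flags the rows instead of silently correcting either —
the source's arithmetic is not ours to fix.

## Assay arithmetic

The DNS end-point assay: absorbance is linear in reducing-sugar
concentration, so a least-squares line (scipy) through the calibration
points gives slope (absorbance per mM) and intercept. Sample
concentration is (A − blank − intercept) / slope, floored at zero with a
warning. Volumetric activity uses 1 U = 1 µmol reducing sugar per minute:

    U/mL = mM × total volume [L] / time [min] / sample volume [L]

(the mM→µmol and L→mL factors of 1000 cancel). Default geometry: 175 µL
substrate + 25 µL sample = 200 µL, 30 min, 30 °C; at this geometry 1 mM
released corresponds to 0.267 U mL⁻¹. Liquid-culture growth is scored
positive iff OD₆₀₀ ≥ 0.2, inclusive at the boundary.

Protein average mass is the sum of Expasy-style average residue masses
plus one water (18.0153 Da); it is additive under concatenation minus one
water per join. Average (not monoisotopic) masses are the convention for
predicted molecular weights in the 20–30 kDa range; ambiguity codes have
no defined mass and raise. The packaged 217-residue GH11 reference
sequence evaluates to 23.186 kDa, within conventional rounding of its
reported 23.19 kDa.

## Phylogenetic association

Trees are consumed as Newick (dendropy), with underscores preserved in
labels, internal-node/bootstrap labels ignored, and missing branch lengths
defaulted to 0 with a warning. Patristic distance is the sum of branch
lengths on the unique leaf-to-leaf path; it is root-invariant, so unrooted
inputs are fine, and the tests check it is a metric and agrees with a
shortest-path computation on the tree as a graph. Candidates are ranked
ascending by the `min` (default) or `mean` of their distances to the
labeled xylanolytic set, with alphabetical tie-breaks; because published
screens of this kind pick "closely related" taxa informally, no hard
distance cutoff is imposed — the full ranking is returned.

Pairwise percent identity uses a global alignment (match +1, mismatch 0,
linear gap −1) with identity = 100 × matches / alignment length including
gap columns. This is one of several conventions; absolute identities are
comparable only within the same convention.

## The synthetic generator

The generator emulates the *structure* of a multi-species CAZyme screen,
not protein biology: sequences are uniform random over the 20 canonical
residues (the filters act only on coordinates and E-values, so no motifs
are needed), and domain coordinates are arbitrary within their
invariants. Study conditions are fixed by `SyntheticConfig`; the defaults
describe a 12-species, 4-clade screen with 120 proteins per species
(protein lengths uniform in 250–600 aa), a planted rich clade whose
degradative-family counts are boosted 3×, 20% planted rule-violating
noise, and 40% of CAZyme carriers secreted.

Planted gene counts per species and family are Poisson (mean 2 for
degradative families, 1 for GT, degradative means multiplied by
`rich_boost` in the rich clade); each planted gene occupies its own
protein so pipeline counts are unambiguous. Good hits draw E-values
log-uniformly in [10⁻⁶⁰, 10⁻¹⁶] and coverage in [0.40, 1]. Noise hits are
planted to fail exactly one rule each, cycling through: E-value in
(10⁻¹⁴, 10⁻⁵] (fails rule 1), coverage < 0.35 (fails rule 2), and a
same-span duplicate of an existing hit under a *different* family with a
strictly worse i-Evalue (reaches rule 3 and is dropped there — using a
different family makes the drop observable in the counts). Splitting the
E-value ranges on either side of the threshold keeps every planted hit's
intended fate unambiguous after the limited precision of the text format.
Noise hits never enter the ground-truth table, so with any noise fraction
the post-filter pipeline counts must equal ground truth exactly — a
stronger check than noise-free equality. Edge-case hits sit exactly on the
boundaries (coverage 0.35/0.34, E-value 10⁻¹⁵ and just above, overlap
0.20/0.21 with a 100-residue shorter span so both fractions are exactly
representable).

The Newick tree nests each clade as a ladder so clades are monophyletic;
branch lengths are arbitrary positive draws. The SignalP table is written
in short eukaryote format with the planted secretion calls. Everything
derives from one `numpy` generator seeded by the config, so identical
configs produce byte-identical files.

What passing on synthetic data does **not** show: real proteomes have
correlated gene families, fragmented assemblies, shared domains on
multi-domain proteins and HMM-score idiosyncrasies none of which are
emulated; results on real data depend on the HMM library and the upstream
search, which this package deliberately does not run.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: the
overlap-resolution oracle covers 1000 random proteins with ≤ 10 hits,
clade recovery uses 20 seeded replicates of the 12-species default
configuration, and the assay round trip uses 6 exact wells plus 100 noisy
replicates (absorbance s.d. 0.01). Floating-point comparisons at rule
boundaries are exact by construction (0.35 = 35/100, 0.20 = 20/100 on
planted integer coordinates). Ties in overlap resolution are broken
deterministically (bit score, start, family) so results are reproducible
across platforms; domtblout E-values are written with six significant
digits, which preserves every planted pass/fail decision.

## Known limitations

- The de-duplication is not a bit-exact reimplementation of CD-HIT-style
  tools; word size and length-difference heuristics are deliberately out
  of scope.
- The default substrate map is a curated convenience, not a community
  standard; heatmap absolute values depend on it.
- The package never runs hmmsearch/SignalP/alignment/tree-inference
  binaries; it consumes their outputs. Orientation of a domtblout cannot
  be auto-detected reliably and must be declared by the caller.
- Percent-identity values depend on the alignment convention (documented
  above) and are not comparable across conventions.
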