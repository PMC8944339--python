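# Methods

This note documents the models, rules and numerical choices behind
`barcodeaudit`, and what the synthetic test corpus does and does not emulate.

## The audit procedure

The pipeline harmonizes DNA-barcode records from two sources — GenBank
flat-file entries and a BOLD-style tab-delimited export — with a Darwin-Core
style species-occurrence table, then quantifies three families of bias.

**Ingestion.** GenBank entries are split on `//` terminator lines and parsed
with tolerant line/regex extractors covering seven field groups: organism
name and lineage; publishing author; publishing institution; submission year
(from the `Submitted (DD-MON-YYYY) <institution>, <address>` journal line, or
from an undated direct-submission journal line naming only the institution);
source qualifiers (`/country` split into country and descriptive locality at
the first colon, `/lat_lon` with N/E positive and S/W negative,
`/collection_date` reduced to a year); the raw gene-marker string (gene
qualifier, then product qualifier, then the DEFINITION line — first match
wins); and the ORIGIN nucleotide block. Absent blocks yield absent fields,
never parse failures; malformed dates or coordinate strings yield absent
values (both coordinates at once, so missingness counts stay coherent).
Accepted collection-date grammars: `YYYY`, `Mon-YYYY`, `DD-Mon-YYYY`,
`YYYY-MM-DD`. After harmonization, GenBank copyright fields mirror the
publishing fields; BOLD keeps its copyright/storing columns. Institution
strings map to (country, region) through a deterministic institution table —
a mechanical replacement for per-record manual curation of publisher strings.

**Marker standardization.** Raw marker strings are matched case-insensitively
on whole keywords against the synonym sets used in the original database
searches (e.g. COI: `COI, co1, cox1, coxI, cytochrome oxidase, cytochrome c
oxidase`; rbcL includes `rubisco`; ITS2 includes bare `ITS`). The first
marker in COI, CYTB, rbcL, matK, ITS2 order with a matching keyword wins;
everything else is `OTHER`. The function is idempotent on canonical values.

**Locality resolution.** Free-text localities are tokenized on commas,
semicolons, slashes and the conjunctions "and"/"&", normalized (case fold,
diacritic and punctuation stripping, whitespace collapse) and matched against
canonical gazetteer names and their variants. Unmatched tokens fall back to a
fuzzy lookup: a token matches when exactly one canonical unit lies within a
restricted Damerau-Levenshtein (OSA) distance of 1 for names of ≤ 8
characters, 2 otherwise. Three base conditions are evaluated independently —
*misspelled* (a fuzzy-matched token), *multiple* (≥ 2 distinct provinces
named), *mismatch* (a matched municipality whose gazetteer parent is not
among the named or declared provinces). Two or more conditions give *mixed*;
none gives *none* (clean chain), *unspecified* (only a region matched) or
*unknown* (nothing matched). Administrative units are reported only for the
*none* and *misspelled* outcomes; on a declared-vs-text conflict the record
is classified *mismatch* and the province left absent, since neither source
can be trusted mechanically.

**Filters.** Applied in a fixed order so per-rule counts are stable:
(1) deduplicate on record id (GenBank accession / BOLD process id), keeping
the first occurrence — records with no id cannot be deduplicated and are kept
and counted; (2) keep only the five targeted markers; (3) drop foreign
records — an explicit foreign country, or a record claiming the audited
country whose locality resolves to nothing in the gazetteer while naming a
place on the foreign-place list; records with *no* country are kept in
`include_na_country` mode and dropped in `exclude_na_country` mode;
(4) drop *Homo sapiens* / *Homo luzonensis*. The filter log satisfies
input = output + Σ removals, and the exclude-mode survivor set is exactly the
include-mode set minus the country-absent survivors.

**Taxonomy.** Species labels containing the tokens `sp.` or `gen.` are
treated as unidentified. A species → (phylum/division, class, order, family,
genus) table is derived from the unique species in the occurrence data
(species with conflicting higher ranks are dropped and logged rather than
majority-voted, keeping the table deterministic); barcode records with a
species name but missing higher ranks have every absent rank backfilled from
this table, never overwriting present values. Phylum and division are treated
as one rank throughout, as animal and plant records share the column in the
source databases. Missing kingdoms are recovered from the species entry or a
phylum → kingdom map.

**Gap metrics.** Missingness is counted per category over the filtered record
set; a record lacks *any* location metadata exactly when coordinates,
locality text and all resolved administrative units are absent (so a resolved
province rescues a coordinate-less record). Within the no-coordinate subset,
the share with/without descriptive locality is reported. Identification
vs barcoding per taxon: `pct_identified` = identified records / records in
taxon; `pct_barcoded` = |barcoded species ∩ occurrence species| / |occurrence
species|, undefined (NaN, listed not dropped) when the denominator is zero.
The bounded (intersection) numerator keeps the ratio ≤ 100; an unbounded
variant counting all barcoded species is available as a switch.

**Bias metrics.** Counts are transformed with log₁₀, zero counts assigned −1
(log of zero being undefined). The 5th/95th-percentile thresholds use
numpy's linear-interpolation quantile definition and are computed on the
transformed values by default — the thresholds are drawn on transformed axes,
and the two choices differ only through the zero → −1 rule — with a config
switch (`quantiles_on="raw"`) for raw counts. Comparisons are inclusive: a
point at the 95th percentile is flagged high, at the 5th flagged low.
Spatial assignment: a point inside a province polygon takes that province
(boundary points go to the first containing polygon in the fixed province
order); otherwise the nearest polygon centroid by haversine great-circle
distance on WGS84 wins, ties broken by lexicographic name. Area-weighted
polygon centroids are computed once and cached. Contributor attribution uses
the copyright country (Philippines / Foreign / Unknown, with Unknown excluded
from the two-class percentage). The region matrix cross-tabulates the region
of the copyright-holding institution against the region sampled, restricted
to records with both known; the sampled region uses the same coordinate-first
province assignment as the per-province tallies.

**Smoothing.** Yearly counts per contributor class are smoothed with loess:
degree-1 locally weighted regression, tricube weights over the
`ceil(span · n)` nearest years (default span 0.75), evaluated at each
observed year. The implementation is in-package so the window definition is
explicit; degree-1 exactness on constant and linear series and agreement
with a directly solved weighted least-squares fit are tested, and
statsmodels' lowess serves as an independent cross-check. Classes with fewer
than three distinct years keep raw counts only and are flagged.

## The synthetic corpus

Real inputs are live database exports that cannot be redistributed, so the
generator emits all six inputs with planted structure recorded per record in
a TruthLedger (planted values, blanked fields, issue category, province,
contributor, duplicate/decoy/unidentified flags). Defaults define the study
conditions:

| knob | default | rationale |
|---|---|---|
| barcode records | 1,160 GenBank + 840 BOLD | ≈ 58:42 source split typical of national barcode sets |
| occurrence records | 5,000 | occurrence data an order of magnitude denser than barcodes |
| missing rates | coords 0.65, locality 0.45, collection yr 0.70, submission yr 0.22, institution 0.18, country 0.18 | majority of records lack coordinates and collection year; roughly a fifth lack attribution or country, with locality chosen so that over half of the no-coordinate subset has no descriptive locality either |
| issue mix | none 0.45, unspecified 0.20, misspelled 0.10, unknown 0.10, multiple 0.07, mismatch 0.05, mixed 0.03 | *unspecified* dominates among defects |
| marker mix | COI 0.62, rbcL 0.10, CYTB 0.08, ITS2 0.08, matK 0.07, OTHER 0.05 | COI-dominated, animal-heavy |
| contributor mix | US 0.40, PH 0.30, DE 0.08, CA 0.07, JP 0.05, AU 0.04, CN 0.03, FR 0.03 | foreign-majority with ≈ 30% local share |
| unidentified / duplicates / decoys / marine / taxonomy blanks | 0.25 / 0.02 / 0.02 / 0.15 / 0.18 | a quarter of records identified only to genus; small planted contamination; a noticeable marine fraction |
| years | collection 1990–2020, submission 2000–2020 | uniform; submission may precede collection (present in real data, deliberately not enforced) |

Geography is a grid of disjoint 1°×1° rectangular province polygons spaced
2° apart; the gaps are open sea, so marine records exist by construction.
Marine points are displaced outside their province's rectangle and the
nearest-centroid answer is verified by brute force at generation time.
Gazetteer names are generated with pairwise OSA distance ≥ 4 so a planted
single-character misspelling is always uniquely attributable; every planted
defect string (misspelling, unknown locality, foreign place) is verified
mechanically recoverable/unrecoverable before emission. Taxon sampling uses
separate barcode and occurrence weights so the pool contains occurrence-only
taxa (documented, never barcoded) and barcode-only orders/families (the
undefined-ratio case). Duplicates and decoys (direct foreign country,
foreign-locality mismatch, *Homo*) are emitted on top of the base counts.

What the generator does **not** emulate: realistic nucleotide evolution
(sequences are random letters of plausible length), realistic coastlines or
province shapes, multi-word or diacritic-bearing place names, free-text
locality grammars beyond the planted patterns, partially malformed GenBank
blocks, and collaboration structure among institutions. Passing recovery
tests therefore demonstrates that the pipeline's rules are implemented
exactly as specified and are internally consistent — not that the locality
classifier or parsers would reach the same accuracy on the messier free text
of real exports.

## Problem sizes and determinism

The test suite and the acceptance script use a 6-region × 4-province ×
3-municipality gazetteer with the default record counts above (2,000 barcode
+ 5,000 occurrence records), which exercises every rule while keeping a full
run in seconds. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical (config, seed) produce byte-identical
corpora and byte-identical report tables. Percentages are reported to two
decimals in tables; raw counts are preserved alongside so no information is
lost to rounding.

## Known limitations

* The locality classifier resolves only single-token-per-unit names; real
  multi-word toponyms would need n-gram tokenization.
* The misspelling threshold (OSA ≤ 1 for names ≤ 8 characters, ≤ 2
  otherwise, unique nearest match required) is a mechanical proxy for human
  judgment; borderline real-world misspellings may fall to *unknown*.
* Institution → country/region attribution relies on an exact-match mapping
  table; unmapped institutions are reported as Unknown rather than fuzzily
  matched.
* Great-circle distance to polygon *centroids* (not boundaries) defines the
  marine fallback; for strongly concave provinces the nearest centroid need
  not be the nearest province.
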