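# Methods

## The screening model

`rtindex` treats rigor screening as a sentence-classification problem over
the methods section only. The methods section is the part of a paper that
states checkable facts — which reagents were used, how animals were
allocated, who was blinded — so detection there is far better defined than
in results or discussion prose. Each article becomes a `Document`: methods
text, journal/year metadata, and a deterministic sentence segmentation with
exact character offsets (0-based, half-open). The segmenter is rule-based:
it splits at sentence punctuation followed by whitespace and an
uppercase/digit character, with an abbreviation whitelist ("Fig.",
"et al.", "i.m.", "No.", ...), a protection rule for single uppercase
initials, and one for RRID tokens. A rule-based splitter was chosen over a
learned model so that fixtures and downstream offsets are bit-reproducible.

### Detection

The default detector is a pattern engine: per-criterion keyword/phrase
lexicons with proximity constraints, shipped as editable JSON
(`rtindex/data/lexicons.json`). Two criteria need more than keywords:

- **Blinding** requires a blinding term ("blind(ed)", "unaware", "masked")
  in the same sentence as an investigator/analysis/assessment term, except
  for self-sufficient forms ("double-blind"). This suppresses anatomical
  uses such as "blind-ended duct".
- **Sex** matches subject-description terms (male/female/sex/mother/...)
  after masking an exclusion list of gene and domain names ("maleless",
  "sex-determining", "male-specific lethal"), the dominant false-positive
  class. Any sex statement counts — the criterion does not require both
  sexes to be reported.

Resource detection combines noun triggers ("X antibody", "anti-X", "X
cells"), registries of common cell lines and software tools, strain/
transgene patterns for organisms, plasmid-name morphology (`pXyz...`) with
a cloning-context requirement, and primer/sequence patterns for
oligonucleotides. Vendor names come from a vendor lexicon; catalog numbers
are extracted from the parenthetical (or trailing clause) nearest the
resource name using cue patterns ("#62988", "cat. no. X", "number TIB-67",
"ab12345", vendor-style codes), with RRID spans masked first. Pattern hits
are deterministic and carry confidence 1.0.

RRIDs follow the grammar `RRID:` + optional space + authority + `_`/`:` +
accession, accepting both printed dialects ("RRID:AB_777714" and
"RRID: AB_777714") and nested-colon accessions ("RRID:IMSR_JAX:000664").
Validity is syntactic only; resolving accessions against live registries is
an extension point, not a dependency.

### Identifiability

A mention is *identifiable* when its metadata suffices to pin down the
exact resource:

| type | rule |
|---|---|
| antibody | catalog number or RRID (vendor alone is not enough) |
| organism, cell line, plasmid | RRID, or vendor + catalog number |
| software | RRID, URL, or registry-listed distinct name |
| oligonucleotide | reported as identifiable, never scored |

A stricter clone-ID rule is configurable: by default a clone ID only helps
alongside a vendor, and even then only if explicitly enabled, since catalog
number/RRID is the operative criterion.

The **relaxed second pass** runs when document RRIDs remain unattached
after first-pass detection: an RRID is near-certain evidence of a key
resource, so the nearest preceding resource-like noun phrase in the same
sentence becomes a mention named by it, typed by the RRID authority
(AB→antibody, CVCL→cell line, SCR→software, Addgene→plasmid,
IMSR/BDSC/MGI/ZFIN/RGD→organism). The pass never removes a mention and
never lowers identifiability; afterwards every RRID belongs to exactly one
mention. The exact relaxation used by production screening tools is
unpublished, so nearest-phrase attachment is this package's own
reconstruction.

Mentions are de-duplicated per document on
(type, case-folded name, catalog-or-RRID), so repeated uses of one reagent
count as one entity.

## Scoring

Rigor blocks: ethics (IRB ∪ consent ∪ IACUC in the default *merged* mode),
randomization, blinding, power, sex, and cell-line authentication
(authentication ∪ contamination, applicable only when a cell line is
detected). *Strict* mode keeps human ethics (IRB/consent) and animal
ethics (IACUC) as separate blocks for studies where both are expected.
Merged mode is the default because purely human or purely animal studies
should not be penalized for the ethics statement they cannot have.

- `rigor_points = 5 × addressed/applicable` over blocks (weights
  configurable; equal by default — per-block weights of production scoring
  systems are unpublished, so equal weighting with renormalization to the
  5-point section cap is the neutral choice).
- `resource_points = 5 × mean over detected scoreable types` (antibody,
  organism, cell line, software) `of identifiable/detected`; averaging over
  types rather than mentions keeps one abundant type (typically software)
  from dominating the section.
- `total = rigor + resource ∈ [0, 10]`, continuous by default; an optional
  half-up integer rounding mode exists for league-table presentation.
  A paper with no criteria and no mentions is *not applicable* and scores 0.

Journal-year aggregation excludes zero-score (not-applicable) papers from
the RTI mean and all rates, reporting their count separately; groups with
fewer than `min_n` (default 10) scored papers are suppressed as too noisy.
League-table identifiability percentages round half-up to integers. The
impact-factor comparison averages each journal's RTI over the two years
preceding the impact-factor year (window configurable), then applies
Spearman's rank-order correlation with average ranks for ties — equal to
`1 − 6Σd²/(n(n²−1))` when ties are absent. Percentile ranks are
`100·rank/n` with the top quartile labeled Q1.

## The synthetic corpus

The generator emulates the statistical structure of methods sections: each
document draws criterion sentences per-criterion with configured
prevalence, resource sentences with Poisson counts and per-mention
identifiability flags, plus distractors, then shuffles sentence order.
Templates are parameterized variants of canonical criterion/resource
phrasings (species, vendors, catalog numbers, and RRIDs drawn from small
pools) rather than free text, so detector evaluation against ground truth
is exact. Resource templates deliberately avoid criterion vocabulary (no
"male C57BL/6 mice") so planted prevalences can be recovered without
cross-contamination between channels, and names are sampled without
replacement within a document so entity de-duplication preserves planted
counts. The distractor pool contains hard negatives for the exclusion
lexicons.

Default prevalences and identifiability probabilities are anchored to
recent corpus-wide reporting rates in the open-access biomedical
literature: sex 37.0%, randomization 30.1%, blinding 8.6%, power analysis
9.9%; identifiability of antibodies 43.3%, organisms 22.0%, cell lines
39.3%, software 86.7%; IACUC prevalence 0.25 (vertebrate-animal papers are
roughly a quarter of the open-access corpus). Corpus-wide rates for IRB
(0.30), consent (0.25), authentication (0.10) and contamination (0.12)
statements are not reported at that granularity and were fixed once at
values plausible for a mixed clinical/preclinical corpus. Mean mentions
per paper default to 2 antibodies, 1 organism, 2 cell lines, 2 software
tools, 0.3 plasmids and 0.3 oligos.

**What passing tests show — and don't.** On this corpus the pattern engine
attains precision = recall = 1.0 by construction: templates were drawn from
detectable phrasings, which is exactly what makes the corpus a correctness
oracle for the plumbing (offsets, attachment, de-duplication, scoring,
aggregation, recovery of planted rates). It says nothing about recall on
the unbounded phrasing variety of real methods sections, where a lexicon
engine will miss paraphrases a trained classifier might catch; published
screening systems report agreement rates of 80-95% per entity type on real
text. The trainable IOB2 tagger (per-token logistic regression over
lexical window features, deterministic per seed) preserves the
learned-model interface for users with real annotated data.

## Numerical choices and degenerate inputs

- Score rate and league percentages round half-up (87.4666…% → 87.5%).
- Rates with zero denominators raise a "no-denominator" signal rather than
  returning 0, so absent data is distinguishable from zero adherence.
- Correlations require n ≥ 2, finite values, and nonzero (rank) variance;
  ties take average ranks everywhere.
- Documents whose methods section cannot be found (e.g. methods only in a
  supplementary PDF) are retained, flagged, score 0, and count as
  unscorable.
- Duplicate (journal, year) rows in an impact-factor table are an error
  naming the offending rows; ISSN is preferred over journal name as the
  join key.

## Problem sizes

The acceptance checks use one perfect-prevalence document for the score
endpoint and a 500-document corpus (seed-fixed) for parameter recovery,
with rates compared at 3 binomial standard errors; the tagger check trains
on 160/40 held-out sentence splits from a 200-document corpus. These sizes
give stable statistics while keeping the full suite to a few seconds.

## Known limitations

- Lexicon recall on real text is bounded by the shipped pattern lists;
  registries (software, cell lines, vendors) follow an 80/20 coverage
  pattern and are user-editable JSON.
- Catalog-number extraction is heuristic; vendor catalog numbering is
  itself unstable, which is precisely why RRIDs outrank catalog metadata.
- No PDF/OCR input, no bulk PMC retrieval, and no live RRID resolution.
- Corpus-scale published rates (million-article trends, journal league
  tables) require the full open-access corpus and are out of scope; the
  operations that would compute them are implemented and exercised on
  synthetic fixtures.
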