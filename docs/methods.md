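# Methods

## Scope and model

`synlib` models the desk-scale mathematics and simulation of a synthetic
scFv phage-display library built on one fixed scaffold: repertoire
composition profiling, CDR cassette design with TRIM codon mixtures,
in-silico assembly with a synthesis error model and β-lactamase in-frame
selection, and the QC/screening arithmetic used to judge the constructed
library. Wet-lab steps (phage rescue, panning enrichment dynamics, affinity
fitting) are out of scope; only their recorded counts and readings enter the
analytics.

## Scaffold and CDR bookkeeping

The scaffold is a VH–(Gly₄Ser)₃–VL template with IGHV3-23/IGKV1-39-style
frameworks. The diversified windows are Kabat H30–35 (6 aa), H50–58 (9 aa),
H95–102 (variable, default 3–18 aa), L28–34 (7 aa), L50–53 (4 aa) and
L89–96 (8 aa). CDR-H3 lengths shorten by dropping positions back from H100
and lengthen through insertion codes H100A…H100J; codes beyond Z are
disallowed (a length-18 loop needs only H100J).

Because the library lives on a single template, CDR extraction does not use
general antibody-numbering software: every framework offset is known once
the CDR-H3 length is inferred from the total sequence length, and each
flanking framework segment is verified exactly (anchor matching). This is
exact on error-free clones — `extract_cdrs ∘ assemble_scfv` is the identity —
and any flank mismatch is reported against the adjacent CDR. General
repertoire inputs that do not live on the scaffold should supply
pre-extracted CDR columns instead. Internally all indices are 0-based
half-open; Kabat labels appear only in reports.

The bundled template (`data/vh3_vk1_surrogate.yaml`) is a **synthetic
surrogate**: the amino-acid frameworks follow the well-known germline
sequences, and the nucleotide encodings are produced by the package's own
dual-host codon optimizer. The same applies to the β-lactamase signal/bla
fusion partners (TEM-1-like surrogates). Only their internal consistency and
reading frame matter to the model; all template invariants (segment-wise
`translate(nt) == aa`, (G₄S)₃ linker, disjoint diversified windows) are
asserted at load.

## Profiling

Composition profiles tabulate the fraction of each of the 20 amino acids at
each CDR position; CDR-H3 is stratified per length with no cross-length
alignment. Positions with zero observations in a stratum carry all-zero rows
plus an explicit unobserved flag rather than NaN. The CDR-H3 length window is
chosen as the shortest contiguous window whose cumulative probability reaches
the target coverage (default 0.8), ties broken toward the smaller minimum
length.

Designed-vs-observed comparison uses per-position total variation distance,
TVD(p) = ½ Σ_r |d(p,r) − o(p,r)|, a bounded, symmetric [0, 1] metric; the
mean TVD is the headline similarity figure, with 0.05 as the default
"similar" threshold. A formal statistical test of composition difference is
deliberately not provided.

## Cassette design and diversity

Designs are per-position frequency tables over an allowed support. The
default exclusion set is {Cys} — standard practice in synthetic CDR design,
and consistent with 19-residues-per-position short-H3 cassettes whose design
diversities are 19³ = 6.86 × 10³, 19⁴ = 1.30 × 10⁵ and 19⁵ = 2.48 × 10⁶ at
three significant figures. An optional frequency floor (≤ 0.05) drops rare
residues before renormalization.

Design diversity is computed in exact big-integer arithmetic as the product
of support sizes; reports render both the exact integer and the
3-significant-figure scientific form. A whole-library figure combines
cassettes as Σ over H3 lengths of the six-cassette product; since only
per-cassette values are physically measured (sub-library sizes), the
combined figure is labelled a model quantity. Longer-H3 cassette diversities
below 19^L indicate positional restrictions a design may impose; the uniform
default makes none.

TRIM mixtures assign one sense codon per supported residue at exactly the
design frequency, so the expected amino-acid composition reproduces the
design to numerical identity (checked to 1e-9) and no stop codon or
frameshift can be synthesized — the structural advantage over degenerate
codons. Degenerate patterns (NNK: 32 codons, one stop at 1/32; NNN: 3/64
stops) are enumerated from the IUPAC expansion with equiprobable codons for
comparison. The default TRIM codon table is the dual-host optimizer's
choice: per residue, the sense codon maximizing the geometric mean of
E. coli and human relative usage, ties broken alphabetically — a
deterministic rule chosen for reproducibility over expression realism.

Sampling coverage uses E[distinct] = D·(1 − (1 − 1/D)^N), evaluated with
`log1p`/`expm1` for D ≫ N and a second-order collision expansion
N − N(N−1)/(2D) once D exceeds 10¹⁷ (beyond float range).

## Assembly, errors, selection

Overlap-extension assembly of cassettes into the scaffold is modelled as
exact concatenation (flank identity is what the PCR exploits; no polymerase
error model). Synthesis errors are independent per-base deletions,
insertions and substitutions (rates capped at 5%), applied with a seeded
generator and recorded as lesions against the error-free insert.

In-frame selection fuses signal·insert·bla into one ORF and keeps a clone
iff the ORF length is a multiple of 3 and every codon is a sense codon under
the active stop policy. The default policy `standard` treats all three stops
as lethal; `amber_suppressed` reads TAG as Gln, because phage work commonly
uses supE strains (E. coli TG1) while the selection host's suppressor status
is generally unstated. A compensated frameshift (net indel ≡ 0 mod 3 with no
new stop) correctly survives, matching the biology of frame restoration
before bla. Selection soundness/completeness is tested against an
independent Biopython translation oracle on 10⁴ simulated clones.

## QC classification

A read is *readable* iff the template's seven constant nucleotide runs
(FR-H4/linker/FR-L1 merge into one) can all be located in order by exact
search — a defined surrogate for Sanger readability, which is not otherwise
recoverable. Gap lengths between runs are the CDR cassettes: a gap length
≢ 0 mod 3 is a frameshift attributed to the CDR containing the first frame
break (compensated multi-lesion clones are attributed to the first lesion's
region); an in-frame stop codon is an internal stop; otherwise the read is
in-frame. Headline rates round half-up to integer percent; exact fractions
are always retained.

## Screening analytics

ELISA positivity subtracts OD650 from OD450 and calls a well positive at
≥ 3× background by default (the threshold rule is conventional assay
practice; all bundled screen fixtures carry explicit positive flags, so
summaries never depend on it). Hit rate is positives/screened rounded
half-up to integer percent. Unique binders are keyed on the concatenated
amino-acid string of the six extracted CDRs — paratope identity, so
framework-silent nucleotide changes collapse — configurable to full-aa or
full-nt keys since the deduplication level of reported campaigns is often
unstated. Reporter inhibition is 100 − 100·(RLU_ab/RLU_control); negative
values are reported as-is (enhancement), and K_D / EC₅₀ curve fitting is a
non-goal.

## Synthetic data

The generators emulate inputs that are not publicly available:

- **Mock repertoires** draw each position's residue frequencies once from a
  symmetric Dirichlet (default concentration 1.0 — strongly position-skewed,
  like real CDRs; the concentration → ∞ limit is uniform), then sample
  sequences i.i.d. CDR-H3 lengths follow a discretized normal (mean 11.5,
  SD 2.8) over 3–18 aa, the typical human Kabat CDR-H3 profile that an
  ~80%-coverage window spans. Generating frequencies are returned for
  parameter-recovery tests (mean TVD < 0.01 at n = 10⁵).
- **QC read sets** mix clean clones, reads truncated upstream of the VL-side
  anchors (unreadable), and reads with exactly one 1-nt deletion inside
  CDR-H3 (frameshift). The standard preset is 300 reads / 42 unreadable /
  6 frameshifts, giving 258 readable and a 2% headline rate.
- **Selection pilots** fuse clones with a given number of single-nt indels
  in the CDR-H3 cassette; the standard preset is 100 clones / 9 frameshifted
  (91% in-frame before selection, 100% among survivors).
- **Screen tables** carry explicit positive flags; positive wells get
  sequences drawn with replacement from a fixed number of distinct clones
  (each appearing at least once, so deduplication is exact), negatives get
  background-level OD (uniform on [0, background], positives on
  [3×, 10×] background — arbitrary, since flags are explicit). The five
  presets are TIM-3 (1632 screened / 772 positive / 204 unique), TGF-β
  (96/91/29), B7H3 (192/134/23), a CCR5 peptide (1056/237/45) and a
  bacterial protein BA (192/166/26).

What passing these tests shows is that the pipeline's arithmetic,
classification and bookkeeping are correct under the stated generative
assumptions; it does not validate the error model against real synthesis
chemistry, model Sanger quality, phage display valency, or panning
enrichment between rounds.

## Numerical choices and problem sizes

Frequency/probability normalization is asserted to 1e-9 (1e-12 for
degenerate-codon enumerations). Diversity arithmetic is exact. Percent
headline figures round half-up. All stochastic operations take explicit
seeds and use one documented NumPy generator each. The default test and
reproduction runs use 10³ clones for round-trip identity, 10⁴ clones for
selection soundness/completeness, and 10⁵ draws for parameter recovery —
sizes at which the binomial tolerances above are already tight.

## Known limitations

- The anchor-based extractor and QC classifier require exact framework
  matches; a substitution inside a framework segment renders a read
  unreadable rather than partially interpretable.
- The combined library-diversity figure assumes independent cassette
  recombination (a model quantity, not a measured one).
- Codon usage tables are approximate compilations; only within-family
  rankings influence results.
- The ELISA positivity threshold is a convention, not a fitted rule.
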