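# synlib

Design, in-silico construction and quality control of **synthetic human scFv
phage-display antibody libraries**.

Synthetic antibody libraries diversify the six complementarity-determining
regions (CDRs) of a fixed, high-stability scaffold — here a VH–(Gly₄Ser)₃–VL
single-chain format built on IGHV3-23/IGKV1-39-style frameworks — with
amino-acid compositions tailored to mimic the natural human repertoire.
`synlib` is for library designers and protein engineers who need to:

- **profile** a repertoire: per-position amino-acid percentages of each CDR
  window (Kabat H30–35, H50–58, H95–102, L28–34, L50–53, L89–96) and the
  CDR-H3 length distribution, with shortest-window coverage selection;
- **design** cassettes: residue frequency tables per position, realized as
  TRIM (trinucleotide mutagenesis) codon mixtures — one sense codon per
  supported residue, dosed at the design frequency — compared against
  degenerate NNK/NNS schemes, with exact-integer design diversity
  `D = Π_p |support(p)|` and the expected-unique-sampling curve
  `E = D·(1 − (1 − 1/D)^N)`;
- **simulate** construction: sample clones from a design, inject per-base
  synthesis errors, fuse inserts between a β-lactamase signal sequence and
  the bla N-terminus, and apply carbenicillin **in-frame selection** (a clone
  survives iff the whole fusion reads through stop-free and in frame;
  amber-suppressed hosts are modelled by reading TAG as Gln);
- **QC and screen**: classify sequencing reads (readable / frameshift by CDR
  region / internal stop / in-frame), and summarize phage-ELISA panning
  campaigns (background-subtracted OD450 − OD650 positivity, hit rate =
  positives/screened, unique binders keyed on the concatenated CDR amino
  acids, reporter inhibition % = 100 − 100·RLU_ab/RLU_ctrl).

All randomized steps take explicit seeds; the synthetic-data module generates
every input the pipeline needs (mock repertoires with Dirichlet positional
skew, QC read sets, selection pilots, screen tables) together with
machine-readable ground truth.

## Worked example

```python
from synlib import (
    default_scaffold, uniform_library_design, design_diversity, scientific_3sig,
    sample_library, bla_fuse, inframe_select, orf_intact, hit_rate,
)

template = default_scaffold()                    # bundled surrogate scaffold
library = uniform_library_design(template)       # 19 residues/position (no Cys)

report = design_diversity(library)
for L in (3, 4, 5):
    print(f"H3({L}) design diversity: {scientific_3sig(report.per_cassette[f'H3({L})'])}")

clones = [bla_fuse(c) for c in sample_library(library, template, 100, seed=7)]
survivors = inframe_select(clones)
print(f"in-frame after selection: {len(survivors)}/{len(clones)}")
print(f"hit rate 772/1632 -> {hit_rate(772, 1632).percent}%")
```

prints

```
H3(3) design diversity: 6.86 x 10^3
H3(4) design diversity: 1.30 x 10^5
H3(5) design diversity: 2.48 x 10^6
in-frame after selection: 100/100
hit rate 772/1632 -> 47%
```

The three diversity lines are 19^L for a 19-residue-per-position CDR-H3
cassette of lengths 3–5; with error-free assembly every clone survives
in-frame selection; and a campaign screening 1632 clones with 772 ELISA
positives has a 47% hit rate.

A CLI mirrors the library:
`synlib scaffold validate`, `synlib profile`, `synlib design`,
`synlib simulate`, `synlib select`, `synlib qc`, `synlib screen-report`,
`synlib fixtures make <preset>`.

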