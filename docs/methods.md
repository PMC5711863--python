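# Methods

## Assay model

The package models a spotted-oligo diagnostic chip for ten *Liposcelis*
species. The biological chain is: single-insect DNA → asymmetric PCR of
the ITS2 region with a 20:1 excess of the Cy5-labeled reverse primer
(enriching the labeled antisense strand) → hybridization of the labeled
product to species-specific probes at 66 °C → scan at 635 nm → per-spot
foreground/background quantification. Everything before quantification is
outside the package; the computational chain starts at sequences (for
design and pattern prediction) and quantified spot tables (for calling).

Hybridization is modeled by sequence identity, not thermodynamics: at the
assay's stringency a probe behaves as an exact-match detector, so a probe
"hybridizes" with an amplicon iff its core matches a window of either
strand within `max_mismatches` (default 0, exposed for sensitivity
studies). No duplex-yield or kinetic modeling is attempted.

## Probe panel and file formats

The packaged tables transcribe the published panel: ten species probes
(22–26 nt, with 1-based inclusive coordinates on the target ITS2 sense
strand), four QC probes (anchor, positive, negative, blank), the
25-population species roster, and the primer set with the 20:1
labeled-reverse:forward ratio and 66 °C hybridization temperature stored
as panel metadata. Probes are stored as hybridizing cores; the 5′
amino + poly-T15 linker and the anchor's Cy5 are structured metadata so
sequence algorithms never see decoration. The parser accepts ASCII
hyphen, en- or em-dash in coordinate ranges and raises (naming the probe)
on any violated invariant: span ≠ length, non-ACGT cores, duplicate
codes, role-cardinality errors. `validate_panel` re-audits a constructed
panel non-fatally, one report row per check.

## Probe design

Specificity is ungapped Hamming distance: probes hybridize as
equal-length duplexes, so gapped alignment would model an interaction the
chemistry does not have. Edit distance (via edlib) is available as an
optional mode for users who want indel-tolerant screening. A candidate
window must

1. occur exactly (0 mismatches) in the required fraction of conspecific
   sequences (default: all of them),
2. keep ≥ `min_cross_species_mismatches` (default 3) to every same-length
   window, on either strand, of every non-target sequence,
3. pass a GC filter (default 0.30–0.70) and, optionally, a Tm window.

Both strands are always searched because the labeled hybridizing strand
is the reverse-primer extension while probes are printed in sense
orientation. IUPAC-degenerate bases are treated as compatible with every
base they can represent — conservative for specificity, since an
ambiguous base is assumed able to cross-hybridize. Candidates are ranked
by cross-species distance, then Tm; the candidate list is uncapped by
default so that every qualifying window (including a planted tag that is
not the most distant window) is reported.

The enumeration is vectorized (all reference windows against all subject
windows per length, as strided byte arrays) but is exactly equivalent to
the brute-force double loop; the tests enforce this equivalence on small
panels.

The default cross-species margin of 3 mismatches is a package decision:
no published margin exists for this panel, and 3 is the smallest value
that separates hybridization from noise robustly at probe lengths of
22–26 nt.

Melting temperatures use a two-state nearest-neighbor model with the
unified stacking parameter set, terminal initiation terms, the entropic
salt correction ΔS += 0.368·(N−1)·ln[Na⁺], and total strand concentration
entering as C_T/4 (defaults: 50 mM Na⁺, 0.25 µM oligo). The parameter
table is a fixed config block; tests cross-check the implementation
against an independent reference implementation to ±0.5 °C.

## Chip geometry

A chip has 12 identical lattices (6 rows × 2 columns); each lattice is an
8 × 10 spot grid with 0.4 mm column pitch and 0.8 mm row pitch. Anchor
spots fill row 1 and columns 1–2 (24 spots); the 56 interior spots hold 4
replicates of each of the 13 non-anchor probes (52 spots) placed
row-major in panel order. The 4 surplus spots default to blank — the
printed description fixes 24 anchors and 4 replicates per probe, which
under-determines 4 spots, and a blank is the only assignment that cannot
bias calling. Any other arrangement can be supplied as a GAL file, which
overrides the default layout entirely.

GAL and GPR files use an ATF-style header (`ATF 1.0`, record counts,
quoted `Key=Value` records) over a tab-delimited body, with 1-based
(Block, Row, Column) coordinates. Floats are written in shortest
round-trip representation and parsed with round-trip precision, so
write→read is lossless. The background column is `B635` by default with
`B635 Mean` accepted, since scanner software differs. Spot flags < 0
exclude a spot from all downstream statistics.

## Calling

The signal is s = F635 − B635, never clamped: negative signals are real
scanner noise and clamping would bias the control means that anchor the
rule. Control means (blank b, negative n) are means of background-
corrected signals over valid replicate spots; a lattice with zero valid
spots for either control is uninterpretable and raises. A site is
positive iff d = s − b satisfies d > 10·n and d > 500, both strict (the
rule says "higher than"). The 500-unit floor applies to d, the
blank-subtracted value, which is the quantity the rule's sentence is
about.

Probe aggregation defaults to applying the site rule to the mean of the
replicate signals (`mean_then_threshold`); `all_sites` mode instead
requires every valid replicate to pass individually. Probes with fewer
than `min_valid_replicates` (default 2) unflagged spots are
indeterminate: treated as negative but surfaced, and if an indeterminate
probe could have overturned a unique-positive verdict the call is demoted
to ambiguous rather than identified.

QC interprets three controls:

* anchors are judged on raw foreground (their Cy5 is attached at
  synthesis, so brightness reflects only probe–slide coupling) against
  `anchor_threshold` (defaults to the 500 absolute threshold);
  dark anchors → `ANCHOR_COUPLING_FAIL`;
* the negative control positive → `CONTAMINATION_OR_NONSPECIFIC`;
* the positive control negative → `AMPLIFICATION_OR_HYB_FAIL`.

The positive and negative controls are self-judged against the blank and
the absolute threshold only (the 10·n clause is dropped for them): the
10× veto presupposes a trustworthy negative control, which is precisely
what QC is testing — with the full rule a contaminated chip would veto
its own detection, since d for the negative control can never exceed ten
times itself. Species probes always use the full rule. Any QC failure
voids the lattice (`invalid`); otherwise exactly one positive species
probe → `identified`, several → `ambiguous`, none → `no_call`.

## Simulator

`simulate_sequences` emulates an ITS2 panel: per species a random
~450 nt backbone with a planted unique tag (default 24 nt) at recorded
coordinates, pairwise tag Hamming distance ≥ 5 on both strands, tag GC
constrained to 0.35–0.65 (a planted tag is by contract a valid probe, so
it must sit inside any sensible designer's GC band), and 1% within-
species SNPs that never touch the tag. It refuses configurations that
cannot honor the guarantees (zero tag distance, distance exceeding tag
length, sequences too short).

`simulate_scan` draws corrected signals log-normally (parameterized by
natural-scale mean/sd; defaults 10 000 ± 1 000 for hybridized spots,
40 000 for anchors) above an additive Gaussian background
(100 ± 30), with blank ≈ 20 and negative ≈ 30 control levels. Failure
modes per lattice: `anchor_fail` darkens anchors, `contamination` lifts
the negative control to the positive level, `hyb_fail` kills all
hybridization-driven signal; `cross_hyb` leaks a fraction of the positive
signal into a named probe. A lattice with no true species still lights
the positive control (the control template is spiked into every mix) and
yields `no_call`. Seeds are mandatory; identical seeds give byte-
identical files.

What the simulator does **not** emulate: real ITS2 sequences are not
uniform random (compositional bias, shared conserved blocks across
congeners make real specificity scarcer than simulated specificity);
cross-hybridization is phenomenological, not thermodynamic; spot
morphology, gridding errors and spatial background trends are absent.
Passing tests therefore demonstrate that the decision logic and formats
are correct, not that the wet-lab assay achieves these error rates.

## Problem sizes and numerics

The test suite and acceptance script run the brute-force design oracle on
panels of ≤ 3 species × ≤ 200 nt, planted-tag recovery on 8–10 species
panels of 300–450 nt, end-to-end recovery on 200 simulated lattices
(10 species × 20 replicates), and the calling-rule boundary on integer
grids plus 10⁴ random spots — sizes chosen so the full suite completes in
well under a minute apart from the design scans, while every check still
exercises the complete code path. Determinism: all randomness flows
through explicit integer seeds; reports are byte-identical across runs.

## Known limitations

* Probe coordinates are interpreted on whatever reference the user
  supplies; whether the published positions count from the ITS2 proper or
  a longer amplicon is not stated, so the coordinate check reports
  mismatches rather than enforcing them.
* The mismatch threshold at which 66 °C hybridization actually fails is
  unknown; pattern prediction exposes it as a free parameter rather than
  claiming a value.
* No secondary-structure, primer-dimer or probe-placement optimization.
* Single-chip analysis only: no multi-chip normalization or batch
  effects.
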