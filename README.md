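# psocidchip

Toolkit for diagnostic DNA-microarray identification of stored-product
psocids (booklice, genus *Liposcelis*) from ITS2 rDNA.

Stored-product psocids are ~1 mm grain pests that are intercepted at ports
thousands of times a year but are nearly impossible to identify
morphologically at any life stage. A spotted oligonucleotide chip solves
this: the ITS2 spacer of the rDNA cistron is conserved within species and
variable between, so a short (22–26 nt) probe matching a region unique to
one species' ITS2 lights up only when that species' labeled amplicon is
hybridized to it. One chip carries 12 identical probe lattices and
identifies 12 samples in a single 66 °C hybridization.

This package implements everything computational around that assay, for
people building or evaluating such chips (plant-quarantine labs, stored
product entomologists, diagnostics developers):

* **panel** — the ten-species probe panel, quality-control probes, species
  roster and PCR primers as validated, round-trippable TSV tables;
* **probe_design** — species-specific probe discovery from labeled ITS2
  FASTA panels, and specificity verification of an existing panel;
* **hybridization** — prediction of the expected chip pattern for an
  amplicon;
* **chip_io** — chip geometry (12 lattices of 8 × 10 spots) and the
  GAL/GPR scanner file dialects;
* **calling** — the decision procedure from quantified spot signals to a
  species call with QC diagnostics;
* **simulator** — seeded synthetic sequence panels and noisy scans with
  injectable failure modes, so the whole pipeline is testable end to end.

## The decision rule

Each spot is quantified at 635 nm as a foreground mean F635 and local
background B635; the working signal is s = F635 − B635. Per lattice, with
blank-control mean b and negative-control mean n (each over four replicate
spots), a detecting site with signal s is **positive** iff

    d = s − b,   d > 10 · n   and   d > 500.

A probe is positive when the mean of its four replicate signals passes
this rule. A lattice is valid only if the Cy5-anchored spots are bright
(probe–slide coupling), the positive-control probe is positive
(amplification + hybridization worked) and the negative-control probe is
negative (no contamination/non-specific binding). On a valid lattice,
exactly one positive species probe identifies the sample; several are
ambiguous; none is no-call.

Probe design treats specificity as ungapped Hamming distance: a candidate
window must occur exactly in every conspecific sequence and keep ≥ 3
mismatches to every same-length window, on either strand, of every other
species' sequence, within GC (and optionally melting-temperature) filters.

## Worked example

Identify a synthetic "unknown" sample (the packaged walkthrough):

```
$ psocid-chip demo --out demo_out --seed 3
expected pattern (sequence-level): positive probes = Lpa
chip call: status=identified species=Liposcelis paeta positive_probes=Lpa
demo OK: the unknown sample is identified as Liposcelis paeta
```

The demo plants the real Lpa probe window (25 nt, positions 98–122 of the
*L. paeta* ITS2) into a random amplicon backbone, predicts the expected
pattern (only Lpa should hybridize), simulates a noisy scan of a lattice
hybridized with that sample, and runs the caller: the chip passes QC, the
only positive species probe is Lpa, and the sample is called
*Liposcelis paeta*.

Simulate a full 12-sample chip and call it:

```
$ psocid-chip simulate --mode scan --out sim --seed 5
wrote scan with 960 spots (12 lattices)
$ psocid-chip call --gpr sim/scan.gpr --gal sim/layout.gal --out sim/calls
lattice 1   sample-01-Liposcelis_brunnea      identified  Liposcelis brunnea      -
lattice 2   sample-02-Liposcelis_entomophila  identified  Liposcelis entomophila  -
...
lattice 12  sample-12-Liposcelis_entomophila  identified  Liposcelis entomophila  -
```

Each line reports the lattice, its sample, the call status, the species
(when identified) and any QC failure codes (`-` means the lattice passed
all three controls).

Design probes for a synthetic panel:

```
$ psocid-chip simulate --mode sequences --out seqs --seed 1 --n-species 4
wrote 13 sequences for 4 species
$ psocid-chip design --fasta seqs/panel.fasta --out design
Simulospecies sp01: 940 candidates
Simulospecies sp02: 1916 candidates
Simulospecies sp03: 1682 candidates
Simulospecies sp04: 917 candidates
```

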