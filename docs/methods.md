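# Methods

This note documents the models, conventions and numerical choices behind
`iia-scout`, what the synthetic-data generator does and does not emulate, and
the limits of what the shipped tests demonstrate.

## Coordinates, translation, I/O

All genomic coordinates are 1-based inclusive on the forward strand (GFF3
convention); the conversion to Python's 0-based half-open slices happens only
inside `seqio`.  FASTA is read with Biopython, GFF3 with gffutils (gene
features; the `ID` attribute names the gene).  Translation uses the
bacterial/archaeal genetic code (table 11) by default and is deliberately
literal: stop codons render `*` with no truncation (the caller decides what a
stop means), codons containing `N` render `X` (and disqualify mass
computation downstream), and GTG/TTG-initiated ORFs keep their literal first
residue rather than being rewritten to Met — initiator-fMet processing is not
modelled, which matters only if one computes the mass of a non-ATG-initiated
candidate.

## Micro-ORF scanning

`scan_small_orfs` enumerates, in all three frames of a strand-oriented
region, ORFs that begin with a start codon in {ATG, GTG, TTG}, end at the
first in-frame stop (the stop codon is included in the reported interval),
and whose peptide length falls in [25, 100] — a window that covers the
34–78 aa range observed for subunit IIa across bacteria and archaea.  ORFs
running off the window edge are flagged `open_ended` and excluded by default:
a candidate without a stop inside the window cannot be length-validated.  Of
overlapping in-range ORFs sharing a stop, only the longest is kept (the
biologically conventional choice of the most upstream start); the length
filter is applied *before* this selection so that an over-long ORF sharing a
stop cannot shadow a valid shorter one.  The upstream window defaults to
750 nt directly 5′ of the anchor gene's start, truncated at the genome edge
and at the nearest annotated same-strand gene; same-strand search only, since
the operon arrangement places the IIa gene on the same transcript as
subunit II.

## Transmembrane calling and the candidacy filter

Hydropathy uses the Kyte–Doolittle scale with a 19-residue sliding window, a
call threshold of 1.6 on the window mean, and a 15-residue minimum segment —
standard single-helix heuristics for membrane proteins of this size.
Maximal runs of above-threshold windows become segments spanning the union
of their windows.  Two design details deserve note:

- Distinct runs remain distinct segments.  Two hydrophobic cores separated
  by a short hydrophilic linker produce two runs whose union spans can
  overlap by a couple of residues; the boundary is then split at the overlap
  midpoint, so segments never overlap and two cores are never silently fused
  into one helix.  (A fully merged union-span rule would report one segment
  for, e.g., E₅L₁₉E₈L₁₉E₅, which is the wrong answer for helix counting.)
- Non-standard residues (`X`) score hydropathy 0 with a warning.

The subunit IIa candidacy filter is the conjunction used throughout the
pipeline: *exactly one* predicted TM segment and a length within [25, 100] aa.
The verdict always carries a reason string for the survey log.

Hydropathy windows are not an HMM: absolute helix boundaries are approximate
and helix counts for large polytopic proteins (e.g. 12-13-helix oxidase
subunit I) are not expected to be exact.  The filter is used only on small
proteins, where one-vs-none and one-vs-two are robust decisions.

## Motif and alignment conventions

The conserved motif is P X₁₋₃ G [T/A]; matching is non-overlapping,
leftmost-shortest (the spacer is as short as possible), and the position
reported is that of the Pro.  The invariant Trp is reported as simple
presence/absence of W.  Pairwise validation alignments are global
Needleman–Wunsch under BLOSUM62 with affine gaps (open −10, extend −0.5; a
length-L gap costs open + (L−1)·extend, end gaps included).  Percent
identity and percent similarity use the full alignment length (gap columns
included) as denominator — published identity figures rarely state their
denominator, so ours is declared and tested rather than tuned; "similar"
means membership in one of the ClustalW strong conservation groups
{STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW}.

## Frameshift detection

`detect_frameshift` considers every single-base deletion (and, optionally,
insertion) and scores it by the gain in length of the longest ORF covering
the edited site, requiring a gain of at least 3 × 20 codons by default.
Conventions that make this well-defined:

- "Longest ORF covering the site" considers all three frames, all start
  codons in the configured set, and window-edge-truncated ORFs (windows cut
  through genes).
- The edit shifts downstream coordinates by one, so the pre-edit reference
  is the better of the two original positions the edited site maps to; a
  mere coordinate shift of an existing ORF never counts as gain.
- An indel inside a homopolymer run is indistinguishable from the same indel
  elsewhere in the run; more generally, every deletion inside the stretch
  that is stop-free under the frame shift restores the *identical* fused ORF
  and ties exactly on the score.  All such equivalent calls are merged into
  a single call spanning the ambiguous stretch (`run_start`–`run_end`).
  This is the honest localization uncertainty of frame arithmetic: genomic
  context narrows the run, sequencing resolves it.

Scoring is by ORF-length gain only; homology-guided correction is out of
scope.  Consequences worth knowing: an indel so close to a window edge that
the restored frame meets no stop cannot be validated (the "after" ORF is
open-ended on both sides of the comparison), and in very short ORFs
incidental GTG/TTG-initiated ORFs in shifted frames can mask the local gain
— restricting `starts` to ATG is the right knob there.

## Mass spectrometry

Residue masses are computed from elemental compositions against an IUPAC
element table shipped as package data (`data/elements.json`,
`data/residues.json`); nothing is hard-coded per call site.  Constants:
proton 1.007276 Da, Na⁺ 22.989218 Da (atomic Na minus one electron), NH₃
17.026549 Da, acetyl 42.010565 Da (monoisotopic; average-mode deltas are
derived from the same element table).  Only singly charged species are
modelled (MALDI context).  Peak assignment enumerates charge carrier
([M+H]⁺, [M+Na]⁺) × up to one NH₃ loss × up to one acetyl adduct per
hypothesis (multiplicity configurable), accepts matches within a ppm gate
(default 150 ppm, generous enough for externally calibrated intact-protein
MALDI), and reports the smallest-|ppm| hypothesis per peak while retaining
the full within-tolerance list.  Average-mode assignment exists because
linear-mode masses of intact proteins are average masses.

Tryptic digestion cleaves C-terminal to K/R except before P, with configurable
missed cleavages (PMF matching defaults to one); PMF matches observed masses
as monoisotopic [M+H]⁺ at 50 ppm (typical reflectron accuracy), defines
coverage as the union of matched peptide intervals, and can flag whether any
matched peptide overlaps a designated N-terminal interval — the question one
asks when an annotation has been extended.

y/b fragment series are monoisotopic singly protonated ions, n = 1..len−1.
Ladder readout sorts peaks, matches successive differences to the 20 residue
masses within a tolerance (default 0.5 Da, the scale of manually assigned
TOF/TOF work), and reports maximal contiguous runs of at least two matched
differences.  When a run's lowest peak itself matches residue + H₂O + proton
it is anchored as y₁ and positions are absolute from the C terminus.  At
0.5 Da, Ile/Leu (identical mass) and Lys/Gln (Δ 0.036 Da) are
indistinguishable; readouts carry ambiguity sets rather than guesses, and
the reported rms error is over matched differences (it can never exceed the
tolerance by construction).

## Survey logic

Per genome: characterize the anchor (subunit II) — TM count and theoretical
mass (average mode, as mass tables for proteins conventionally are) — then
(1) if an annotated same-strand gene within the upstream window passes the
candidacy filter, status `annotated`; (2) otherwise scan the upstream window
for unannotated ORFs, and a passing candidate (longest, if several) gives
`detected_unannotated`; (3) otherwise `absent`.  Every decision is logged.
The packaged `data/survey_reference.tsv` is a verbatim transcription of the
published 36-organism survey (spellings preserved), used for summary-count
checks: 36 regions = 21 annotated + 6 detected-unannotated + 9 absent, the
absent cases being exactly the oxidases whose subunit II has two TM helices.
Surveying real genomes is an offline workflow over locally supplied
FASTA/GFF manifests; nothing is fetched from the network.  An intervening
gene between IIa and II (known in one organism) is not skipped by default —
the window simply truncates at the nearest annotated same-strand gene.

## Synthetic data: what it emulates, what it does not

`simulate_operon_genome` plants, on the forward strand: background filler,
an upstream IIa ORF (default 41 aa: Met, hydrophilic head with the
P X₂ G T motif at Pro 5, a 19-residue {L,I,V,F} core, hydrophilic tail with
the conserved Trp), an intergenic gap (default 300 nt total), and an anchor
gene (default 150 aa, one — optionally two — 19-residue cores in otherwise
hydrophilic sequence with ~15% scattered hydrophobic singles), optionally
with a single-base insertion at a chosen offset in the anchor CDS.  Design
choices, all in the service of unambiguous ground truth:

- Filler is {C,G} with interspersed TAA/TAG triplets: no start codon (and
  hence no spurious ORF) can occur in or across the filler, yet every
  reading frame is regularly closed, so frameshift scanning cannot build
  ORFs that bridge the intergenic region.
- Hydrophobic cores from {L,I,V,F} and flanks from hydrophilic residues keep
  every hydropathy window far from the 1.6 threshold; tests never hinge on
  borderline windows.  The ~15% hydrophobic singles in anchor flanks make
  frame-shifted readings hit stop codons promptly (codon-table structure:
  central-base T belongs to hydrophobic codons), which keeps the frameshift
  ambiguity stretch short — and is also closer to real protein composition
  than a purely hydrophilic domain.
- A generation-time post-check re-derives the candidate set (the planted ORF
  must be the unique filter-passing candidate) and, when an indel is
  planted, re-runs frameshift detection (the top-ranked run must contain the
  planted position); failing draws are deterministically re-drawn from the
  seed.  The generator therefore *defines* study conditions under which the
  planted truth is recoverable from the sequence alone.

`simulate_spectra` plants [M+H]⁺, [M+H]⁺−NH₃, [M+H]⁺+acetyl and [M+Na]⁺
species (abundances 1.0/0.30/0.25/0.40) under multiplicative calibration
error (default ±80 ppm, within the 50–150 ppm regime of externally
calibrated instruments), plus noise peaks constrained to lie ≥500 ppm from
every enumerable hypothesis so that "no noise assigned" is a property of the
construction, not luck.  MS/MS y-series jitter (default amplitude 0.3 Da) is
modelled as a per-spectrum offset (2/3 of the amplitude) plus per-peak
residual (1/3): MALDI mass error is dominated by smooth miscalibration, and
this split means successive y-ion differences carry only the residual, so
ladder readout at 0.5 Da tolerance is guaranteed up to ambiguity classes.

What the generator does **not** emulate: realistic codon usage or GC
content, overlapping genes, isotopic envelopes, charge states > 1, peptide
modifications in PMF, or intensity physics.  Passing tests therefore show
the pipeline's logic is correct under clean, planted conditions; they do not
certify recall on real genomes (where hydropathy-borderline helices exist)
or real spectra (where envelopes and adduct zoos are richer).

All generator outputs are deterministic functions of (spec, seed) — a single
seeded NumPy generator per invocation, seed recorded in the truth JSON —
and byte-identical across reruns.

## Problem sizes in the standard runs

The shipped test suite and the acceptance script run at desk scale, chosen
to exercise every code path with comfortable margins: 1,000 random peptides
for the mass oracle cross-check, random regions up to 2 kb for the ORF-scan
oracle, 300 random peptides for ladder round-trips, 20 synthetic genomes
plus 20 spectra (and 8 frameshift genomes) for end-to-end recovery.

## Known limitations

- The TM caller is a hydropathy heuristic; boundaries are approximate and
  topology (in/out orientation, signal peptides) is not addressed.
- Frameshift localization is inherently interval-valued (see above); the
  reported run is the ambiguity interval, not a base-exact call.
- Alignment percentages depend on the declared denominator convention;
  comparisons to figures computed under unknown conventions are indicative
  only.
- Intact-mass assignment trusts the provided peak list; no deconvolution,
  charge inference or recalibration is performed.
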