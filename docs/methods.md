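# Methods

This note documents the rules the package implements, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the procedure was genuinely open.

## Somatic subtraction

Variant calls are made independently on tumor and normal; somatic status
is determined purely by subtraction of caller outputs. A call is part of
the normal output when its VAF is ≥ 5% and of the tumor output when ≥ 10%,
in both cases with at least 10 total reads and 3 variant-supporting reads
(`SubtractionConfig`, all four thresholds configurable). Matching is by
exact `(chrom, pos, ref, alt)` key after normalization; no fuzzy indel
matching is attempted, because the subtraction operates on caller output,
not on reads. Duplicate keys within one sample collapse to the record with
the highest depth before subtraction. Normal evidence *below* the 5%
output threshold does not veto a tumor call — it was never "called" in the
normal — but is propagated as a `normal_vaf` annotation so a reviewer can
weigh possible germline contamination or clonal hematopoiesis.

Coordinates are 1-based and closed; chromosome names are stripped of any
`chr` prefix; the reference build (GRCh37) is metadata only. Because no
reference sequence is accessed, indel "left alignment" is parsimony
trimming (shared suffix, then shared prefix) rather than reference-based
left-shifting; two representations that differ by placement within a
homopolymer would not be matched. When a reported VAF and the allele
depths disagree by more than 0.01, the reported value wins (caller output
is authoritative) and a warning is raised.

## Germline filtering

Three layers, all knowledge-base driven:

- reference range: gene ∈ cancer-predisposition/pharmacogenomics list, or
  `(gene, hgvs_c)` on an explicit patient-care allow-list (this is how
  star alleles such as UGT1A1 \*28 are routed, since they are not
  conventional coding changes);
- reportable range: COSMIC identifier ∈ catalog, or gene ∈ ACMG
  secondary-findings list;
- frequency: population minor allele frequency < 1% (configurable).

The retained set is (reference ∪ reportable) ∩ frequency-pass. The
combination is not dictated by the layers themselves; union-then-frequency
was chosen because each retention layer is an independent route into the
report, while the frequency filter is a population-genetics veto that
applies to both. A missing population frequency retains the variant: a
novel variant cannot be excluded as common. Layers are pure per-call
predicates, so evaluation order cannot matter; this is property-tested.

## Variant characterization and mutational load

Categories are non-exclusive: `disruptive` iff consequence ∈ {nonsense,
frameshift, splice_site}; `somatic` iff the key is in the subtraction
output; `compound_het` iff ≥ 2 distinct het calls share a gene
(phase-unknown co-occurrence — no trio or read-backed phasing in scope);
`homozygous` iff the caller says so or VAF ≥ 0.90 at depth ≥ 30. The
numeric homozygosity rule is conventional exome practice, not an upstream
requirement, and is configurable; whether "homozygous" means tumor
zygosity or reduction-to-homozygosity relative to germline is ambiguous
in the source procedure, so the reduction test lives separately in the
VOUS-return rule.

Mutational load counts tumor-specific variants with ≥ 30X coverage and
(quality ≥ 20 or VAF ≥ 25%). Cohort statistics report mean, SD, median,
and range, overall and per disease group. SD uses the sample (n−1)
convention and is flagged degenerate (reported as 0) for n = 1. The
published cohort's load statistics are not reproducible without
patient-level data; the statistics machinery is validated against an
independent numpy computation on synthetic counts instead.

## CNV gates and LOH

CNV calling is gated on coverage: strictly more than 95% of targeted
nucleotides at ≥ 10X in the normal and at least 90% at 30X in the tumor.
The boundary semantics follow the wording of the requirements: "greater
than 95%" is strict, "at least 90%" inclusive; the loss cutoff ("set to
−0.2") is inclusive. Loss: log2 ≤ −0.2. Gain: log2 ≥ +0.2 — the gain
cutoff has no upstream-specified value; +0.2 symmetric is the default and
gains are supporting evidence only.

LOH uses sites classified in the normal (het iff VAF 45–55%, hom iff
90–100%). A het site supports LOH when its tumor VAF shifts ≥ 0.25 from
0.5; a segment is LOH when ≥ 10 supporting sites fall inside it. Neither
number is externally fixed: at tumor purity ρ = 0.8 a true copy-neutral
LOH site sits at 0.5 ± ρ/2 = 0.5 ± 0.4, so a 0.25 shift detects it with
margin while binomial noise at 100X (sd ≈ 0.05 at VAF 0.5) stays far
inside; 10 sites makes a run of coincidental shifts vanishingly unlikely.
Both are exposed in config. Copy-neutral LOH = LOH flag ∧ neutral state.

Segment boundaries follow the log2 track, which is flat across
copy-neutral LOH; interval-accurate LOH boundaries therefore come from
`find_loh_runs`, which takes maximal runs of consecutive shifted het sites
(≥ 10 sites) and spans first to last site. `simple_segmenter` — merge
adjacent bins while a new bin is within 0.1 of the running segment mean —
is a deliberately minimal stand-in for external HMM segmentation, present
so synthetic end-to-end tests can run without that dependency; it is not
intended for production segmentation.

## Expression outliers and fusions

Each sample's FPKMs are divided by the median FPKM over a housekeeping
list (~8000 genes in production; a 30-gene bundled subset in tests), which
cancels global scale — flags are invariant to multiplying a sample by any
constant. The reference model stores per-gene median and raw median
absolute deviation of normalized expression across a panel of normal
transcriptomes (124 in the emulated design); genes absent from a profile
count as 0. A gene is flagged when |normalized − location| / max(MAD, ε)
≥ z with z = 3 by default and ε = 0.01 normalized units guarding
zero-MAD genes. No numeric definition of "significantly overexpressed"
exists upstream; the robust z on housekeeping-normalized values was chosen
for the heavy-tailed FPKM distribution and the cutoff is a parameter. The
RNA QC gates (≥ 50M uniquely mapped reads, < 5% DNA contamination) are
metadata checks on user-supplied numbers, not computed from reads.

Fusion annotation matches the exact 5'/3' pair first, then single-partner
matches (a novel fusion sharing one partner with a cataloged fusion is
expected to have the same effect); `match_type` distinguishes the two, and
5'/3' order is preserved in output.

## Tiering and reporting

Targetable iff (approved-or-experimental drug against the target or its
downstream pathway, OR preclinical efficacy evidence) AND age-appropriate
dosing information — three explicit booleans with a reasons breakdown.
Evidence lives in the drug-target catalog as (target, optional specific
alteration, drug, approval status, pediatric dosing, evidence class,
tumor types), because the underlying literature judgments cannot be
re-derived by the engine; the catalog rows for the bundled exemplars
encode the published board decisions.

Report tiers (ordered rules, lowest match wins): 1 — known driver
(hotspot or cataloged fusion), targetable, with same-tumor clinical
evidence; 2 — targetable, or known driver in an established cancer gene;
3 — other mutation in a cancer gene; 4 — catch-all VOUS. Actionability
sub-tiers: clinical/same-tumor → 1, clinical/different → 2,
preclinical/same → 3, preclinical/different → 4; tier 5 is only ever an
explicit board-override flag, never auto-assigned. Both tier systems are
pure functions of (finding, context, knowledge base) and are reported
independently; the mapping between them for borderline cases is not
specified upstream, so neither is derived from the other.

A germline VOUS is returned iff (1) predicted destructive, (2) in a
well-validated cancer gene, and (3) a second somatic hit exists in the
same gene or the variant is reduced to homozygosity (tumor VAF ≥ 0.9) at
the site.

Reports render with a fixed section order (somatic tiers 1→4, fusions,
CNV, expression, germline categories); JSON uses sorted keys and no
timestamps, so rendering is byte-identical across runs. With
secondary-findings opt-out, ACMG findings move to a TSV audit log and
never appear in the document.

## Cohort analytics

The bundled fixture tables transcribe the program's published findings
row-for-row, including same-patient and therapy-received footnotes. All
headline numbers are distinct-patient counts (patients recur across tier
sections); the diagnosis → solid/hematologic mapping ships as an explicit
lookup table. Denominators (101/65/36/90/57/33/60) come from the cohort
composition. The "38 patients with diagnostic/prognostic/pharmacogenomic
information" tally is not derivable from the printed tables alone and is
deliberately not computed.

## Synthetic data

The generator produces caller-level (not read-level) data, deterministic
per seed. Paired calls: positions drawn without replacement from a fixed
synthetic exome map (2 chromosomes × 500 targets), germline variants het
(VAF ≈ 0.5) or hom (VAF 1.0) in both samples, somatic variants only in
tumor at VAF ~ U(0.15, 0.5) × purity (0.8). Depths are Poisson(100) with
a floor of 30, emulating loci that pass coverage review; a planted call's
observed variant-read count is floored at its planted fraction because a
caller only emits calls above its output threshold. B-allele tracks place
one het site per target (normal VAF ~ N(0.5, 0.02) truncated to
[0.45, 0.55]); inside planted LOH intervals the tumor fraction centers on
0.5 ± ρ/2 with binomial sampling at 100X; log2 bins get Gaussian noise
(sd 0.05) and planted losses shift their bins. Expression panels share
per-gene log-normal baselines; panel profiles add inter-sample log-noise
(sd 0.25; housekeeping genes at one fifth of that), and the case profile
is the baseline with planted fold-changes applied — and no extra noise
term, because in a planted-truth design any unplanted deviation of the
case would be signal missing from the truth set, making "false positive"
ill-defined. The panel defaults to 124 profiles, the size of the
normal-transcriptome panel this emulates.

What the generator does *not* emulate: mapping artifacts, strand bias,
FFPE damage, subclonal structure, tissue-of-origin expression differences
between case and panel, and fusion discovery. Passing the recovery tests
therefore demonstrates that the pipeline stages implement their rules
correctly against planted truth — not that the thresholds would achieve
the same sensitivity on real tumors, where review by a molecular
pathologist remains part of the procedure.

Validation problem sizes (chosen to keep the full suite fast on one
core): 100 tumor/normal pairs of 250 variants for subtraction oracle
equivalence; 20 × 1000 calls for the filter cascade; 50 seeds for LOH
(Jaccard ≥ 0.9 per seed against a 40%-of-chromosome planted interval) and
for losses planted at log2 −0.3, the hardest value above the −0.2 cutoff;
50 seeds for expression recovery of a 20-fold outlier among ~1030 genes.

## Numerical and degenerate-input conventions

- Zero-MAD genes use ε = 0.01 normalized units; zero-scale never yields
  infinite z.
- A CNV segment with no informative het sites is `uninformative`, never
  LOH.
- Duplicate variant keys collapse to highest depth; ties keep the first
  seen (stable).
- Statistics on a single sample report SD 0 with a degenerate flag;
  empty inputs raise.
- Missing depth fields make a call ineligible for subtraction (with a
  warning) rather than silently dropping it from the parse.

## Known limitations

- No reference-sequence access: indel normalization is parsimony trimming
  only.
- No HMM segmentation, purity/ploidy estimation, or allele-specific copy
  number; the tumor fraction is a fixed parameter.
- Pathogenicity labels, hotspot status, fusion effects, and drug evidence
  are catalog inputs, not predictions; the bundled catalogs are small
  defaults for testing, not curated clinical content.
- The four-tier report system and five-tier actionability system are
  assigned independently; no rule converts one into the other.
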