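# Methods

## Model and assumptions

The detector assumes one statistical property of coding DNA: codon
structure makes the nucleotide composition of exons depend on the position
within the codon, which puts excess spectral power at ω = 2π/3 radians per
base. Introns are assumed to lack this periodicity. Everything else —
splice-site motifs, reading frame, strand — is ignored: the analysis is
single-strand, frame-agnostic, and reports intervals only.

The chain is: EIIP mapping → zero-phase band-pass at 2π/3 → Coiflet-5
level-2 DWT → detail-band energy profile → denoise → per-sequence max
normalization → threshold calling. The EIIP mapping is used because it is a
physical per-base quantity producing a single numeric track; the table is
overridable in the configuration.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| band-pass centre | 2π/3 | rad/sample | codon frequency |
| band-pass edges | centre ± 0.04π | rad/sample | narrow enough to reject the 1/f-ish background and neighbouring tones (power ratio at 2π/4 is <0.1% of the pass-band), wide enough that edge transients on a 300-sample tone stay under 10% |
| filter order | 4 (IIR), applied forward–backward | — | flat unit response at the centre after squaring |
| wavelet / levels | coif5 / 2 | — | compactly supported orthogonal wavelet with many vanishing moments; two levels put the 2π/3 band in the detail sub-bands at unit rate |
| boundary mode | symmetric | — | minimises edge artifacts on short exons; `periodization` available and exactly orthogonal |
| energy source | detail bands | — | the band-passed codon component lives there; `approx`/`all` configurable |
| profile smoothing | 9 | nt | light pre-smoothing of the raw squared coefficients |
| denoiser | moving average, window 51 | nt | a window well below the minimum exon scale of interest (~150 nt) that still suppresses position-to-position variance; NLMS line enhancer (µ = 0.05, order 16) and universal-threshold wavelet shrinkage are pluggable alternatives |
| call threshold | 0.35 | fraction of per-sequence max | best-performing operating point on the benchmark-gene threshold sweep |
| min region / merge gap | 50 / 20 | nt | drop sub-exon-scale blips, bridge brief dips; no published rule exists, these are this package's own post-processing defaults |

## Numerical choices

- **Band-pass semantics.** "Bandwidth" names the half-width: pass-band
  edges sit at centre ± bandwidth. The filter is applied with
  `sosfiltfilt`, so the effective response is |H|², exactly 1 at the
  centre frequency; signals must exceed the filtfilt padding length
  (15 samples at the default order) or they are rejected with a clear
  error (the CLI skips such records and continues).
- **Coefficient→position alignment.** Spreading each wavelet coefficient's
  squared magnitude uniformly over the 2^j positions it summarises needs a
  per-band shift between coefficient index and sequence position. No single
  closed form covers both the wavelet- and scaling-derived bands, so the
  shift is calibrated at import time by an impulse probe: decompose a
  centred unit impulse, take each band's energy centroid, and round the
  offset (for coif5/symmetric: 9, 36 and 54 samples for d1, d2 and a2).
  The probe is cached per (wavelet, mode, levels).
- **Orthogonality vs boundary handling.** Perfect reconstruction holds in
  every boundary mode and is asserted to 1e-8 relative error. Parseval
  (coefficient energy = signal energy) holds exactly only for the periodic
  extension, where the transform is orthogonal; the energy-conservation
  tests therefore run in `periodization` mode on lengths divisible by 4,
  while the pipeline default remains `symmetric`.
- **Thresholding ties.** Calls use ≥ (inclusive), so results are
  deterministic and the union of called positions at merge-gap 0 /
  min-length 1 is exactly the superlevel set.
- **Undefined ratios.** Any metric with a zero denominator is reported as
  an explicit undefined marker (`None` / `NA` in reports), never coerced
  to 0 or 1. All-zero confusion counts and all-zero profiles raise
  degenerate-input errors.
- **Segment-level conventions.** A truth exon counts as detected when
  predictions cover ≥ 50% of its length (configurable). The negative
  universe is a count of noncoding units, by default the gaps between and
  flanking the truth exons (n_exons + 1). A known arithmetic inconsistency
  in the published benchmark table (negative precision 80% where the
  formula gives 83.33%, which its own false-omission column supports) is
  resolved in favour of the formula.
- **ROC.** One (FPR, TPR) point per threshold; the curve is anchored at
  (0,0) and (1,1) and integrated by trapezoid. With thresholds at every
  distinct profile value this equals the Mann–Whitney statistic (asserted
  to 1e-9 against brute-force pair enumeration and scikit-learn).
- **N bases.** Allowed at ingest; mapped to the mean of the four EIIP
  values with a logged warning by default, or rejected at the first N in
  strict mode.

## Synthetic data: what it does and does not emulate

`generate_gene` lays out intron, then alternating exon/intron segments.
Introns are i.i.d. draws from a background composition parameterised by GC
fraction (default 0.5). Exon positions use three codon-position
distributions obtained by linearly interpolating, with weight
`codon_bias`, between the background and a fixed deterministic target
(position 1 → G, position 2 → A, position 3 → C); any fixed profile with
distinct position distributions produces period-3 power, and this one is
frozen in code for reproducibility. Exon lengths are rounded down to
multiples of 3 so the codon frame is intact. Defaults (5 exons of 150–300
nt among 300–600 nt introns, codon_bias 0.8) put the instance at the scale
of the multi-exon benchmark genes this class of detector is usually
demonstrated on.

Deliberately **not** modelled: splice-site motifs, start/stop codons,
long-range (1/f) correlated background, codon-usage tables of any real
organism, and alternative isoforms. Passing the recovery tests therefore
shows the pipeline detects codon-position compositional bias at realistic
exon/intron scales — not that it matches any particular accuracy figure on
real genomes, where the period-3 signal is weaker and the background is
correlated.

The independent check, `period3_strength`, is a sliding-window DFT of the
four base-indicator tracks at the 2π/3 bin (window a multiple of 3 so the
bin is exact). For a deterministic repeat its value approaches the
closed-form maximum window/3; for i.i.d. background it stays near 1.

## Test and simulation scales

The recovery suite runs the default pipeline over 20 seeded replicates
(~4 kb each) and pools segment counts: sensitivity and specificity are
1.00 and mean nucleotide AUC ≥ 0.998 at codon_bias 0.8. Transform
contracts use 100 random signals of 128–1200 samples; the
AUC/Mann–Whitney equivalence uses instances up to 1000 positions. The
whole suite completes in a few seconds on one CPU.

## Known limitations

- Per-sequence max normalization makes thresholds relative: a gene whose
  strongest exon dwarfs the others can push weak exons below threshold.
- The segment-level TN definition depends on an explicit noncoding-unit
  count; comparisons across tools must use the same convention.
- The NLMS line enhancer is a causal loop in Python — fine at gene scale,
  slow on megabase inputs; the moving-average default is vectorised.
- CLI exit codes: package errors map to 1 (config), 2 (data), 3
  (internal); argument errors raised by the CLI framework itself keep its
  conventional exit code 2.
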