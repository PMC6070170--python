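# Methods

## Problem and scope

`mirscout` implements the classical homology route to conserved plant miRNA
discovery: known mature miRNAs are matched against transcriptome sequences,
a candidate precursor window is cut around every match, the window is folded
into a secondary structure, and the fold is judged against the structural and
thermodynamic criteria that separate genuine pre-miRNA stem-loops from other
RNA.  Accepted precursors that co-locate on one transcript unit are reported
as a polycistronic cluster and assigned to annotated regions of the
reference (the motivating case is a ribosomal RNA precursor with
ETS–18S–ITS1–5.8S–ITS2–28S spans).  Two companion components cover the
validation arithmetic that typically accompanies such screens:
complementarity-based target-site scoring and relative-expression math
(Livak 2^-ΔΔCt and band densitometry).

## Homology scan

Mature queries (17–25 nt) are matched by an exhaustive full-length Hamming
scan of every transcript window on both strands, keeping windows within
`max_mismatches` (default 2).  For queries of this length the scan is a
strict superset of what a word-seeded heuristic search can return, and it is
deterministic, so an independent all-windows enumeration can verify it
exactly (the test suite does).  E-value-style statistics play no role in the
decision rule and are not computed.  Known precursors are matched by an
ungapped seed-and-extend scan: every exact shared 28-mer is extended to the
full precursor length and kept at ≥ 90 % identity.  The precursor scan being
ungapped is a known limitation: it is a screen, not an aligner.

Windows of `flank` = 150 nt on each side of a mature hit are extracted
(clipped at transcript edges); minus-strand hits are reverse-complemented so
folding always sees the mature sense strand.

## Folding model

The bundled model is an additive per-pair energy model (weighted nested
base-pair maximization): GC/CG −3.0, AU/UA −2.0, GU/UG −1.0 kcal/mol,
hairpin loops ≥ 3 nt, no pseudoknots, N unpairable.  It is *not* a
nearest-neighbor thermodynamic model, and it does not reproduce the folding
energies of thermodynamic engines; it was chosen because it is
dependency-free, exactly verifiable by brute-force enumeration at small
lengths, and deterministic.  All filter logic is agnostic to the energy
source, and an external engine can be swapped in per sequence through a
plain text contract (sequence on stdin; dot-bracket and energy out), or any
callable producing a validated structure.  Temperature and engine settings
are therefore configuration, not part of the method.

Traceback ties are fully specified so output is bit-stable: each interval
prefers pairing its two endpoints when that is optimal, otherwise it splits
at the leftmost optimal point.

## Candidate filter

A candidate must satisfy, in evaluation order: precursor length within
[60, 400] nt; mature length within [17, 25] nt; a single stem-loop (exactly
one transition from an "(" run to a ")" run, with at least one pair); a
defined mature:star duplex with **fewer than 6** unpaired mature positions
(the mismatch bound is exclusive) and ≥ 16 base pairs; the mature wholly on
the 5p or 3p arm; MFEI ≤ −0.49; MFE ≤ −15 kcal/mol; every duplex bulge ≤ 3 nt
and per-internal-loop asymmetry ≤ 2 nt; G+C between 24 % and 71 %.  All
bounds are configurable (`FilterCriteria`); the MFEI default is the
least-negative value observed among the catalogued accepted precursors —
much of the literature uses −0.85, which callers can set.

Definitions: AMFE = 100·MFE/LP (energy per 100 nt); MFEI = AMFE/GC%.  A
"mismatch" is a mature position with no pairing partner; G:U wobble counts
as paired, consistent with plant miRNA practice.  The star span is derived
purely from the pairing table; no 2-nt-overhang processing convention is
imposed.  Reported values round half-away-from-zero to 2 decimals; the
bundled reference catalogue mixes rounding and truncation, so consistency
checks allow ±0.01 and arithmetically inconsistent rows are flagged rather
than forced.

### Window trimming

Extraction windows are ~300 nt, but precursor statistics (LP, GC%, MFEI)
are meaningful only on the hairpin itself — the catalogued precursor lengths
(59–164 nt) are far shorter than the 300-nt extraction window they came
from.  The pipeline therefore folds the window, cuts it to the span of the
outermost base pair enclosing the mature site plus 8-nt tails (widened
symmetrically to the 60-nt minimum, clipped at window edges), refolds the
trimmed precursor and evaluates that.  If no pair encloses the mature, the
padded mature span is evaluated as-is and fails on structural grounds.

### Deduplication

One locus, one call: overlapping extraction windows on a transcript (the
same hairpin reached through the mature on the plus strand and the star on
the minus strand, or through homologous queries) collapse to the best call —
accepted over rejected, then most negative MFEI, then leftmost.

## Clusters and regions

Within one reference, accepted precursors whose successive spans are at most
`max_gap` apart chain into a cluster; the default gap is unlimited (one
cluster per transcript unit), matching the polycistronic pre-rRNA use case;
set a finite gap for genomic scanning.  Singletons are not clusters.  Spans
are assigned to the annotated region containing their midpoint; a span
straddling a boundary keeps the midpoint label and is flagged.

## Target scoring

Sites are scored ungapped against the reverse complement of the miRNA with
the standard plant penalty scheme: mismatch 1.0, G:U wobble 0.5, doubled at
positions 2–13 from the miRNA 5' end; a strict mismatch at positions 9–11
predicts translational rather than cleavage-guided repression.  The
reporting cutoff defaults to an expectation of 5.0 — the cutoff of the
original web-service runs behind published catalogues is not recorded, so
5.0 is a documented assumption.  Gapped (bulged) sites are excluded; a gap
penalty slot is reserved in the schema for a future gapped mode.  This
module reproduces the *kind* of computation a target-prediction server
performs, not any specific server's output.

## Expression arithmetic

2^-ΔΔCt with technical replicates averaged on the Ct scale before the
formula; no amplification-efficiency (Pfaffl-style) correction.  Band
densitometry normalizes the target/reference density ratio by the
calibrator's ratio; a zero target density is a valid "undetected"
observation.  The calibrator tissue is an explicit input and is never
inferred, because published designs routinely switch calibrators between
panels.

## Synthetic data

The generators emulate the statistical structure the analysis assumes:

* **Planted precursors** are `[mature][loop][star]` hairpins (mirrored for
  3p), star = reverse complement of the mature with 0–3 mismatch mutations
  (the scan tolerates 0–2 scan-level mismatches; the duplex up to 5), loops
  cycle A/C bases, and flanks/embedding pads are runs of N.  N pads are
  deliberate: under an additive per-pair model any real-base flank can tie
  with a stem pair of the same type and steal it in the traceback, whereas N
  is unpairable, making planted structures exactly recoverable.  Mismatch
  mutations replace the star base with the least reactive non-pairing base
  (A, or C opposite U) at positions preferentially opposite weak (A/U)
  mature bases, never within 2 nt of either stem end.
* **Decoys** are constructed per designated criterion — an AU-extreme
  hairpin (GC below floor), an unfoldable A/C-only site (energy ≈ 0), a GC
  clamp enclosing two stem-loops, a star with 8 mismatches, and a transcript
  shorter than the minimum precursor.  Only the designated criterion is
  guaranteed to fail; others may incidentally fail too.
* **Background transcripts** draw uniform bases, lengths 300–2000 nt
  (GC-skew available for stress tests).
* **The polycistron scenario** plants five precursors — three in "18S", two
  in "28S" of an ETS–18S–ITS1–5.8S–ITS2–28S layout (6.7 kb reference) —
  using the five catalogued cluster mature sequences (miR2914, miR2916,
  miR2910, miR1310, miR2911); if a catalogue mature cannot be realized as a
  clean hairpin under the bundled model, a synthetic stand-in mature of the
  same length is drawn (the truth table records the sequence actually used).

Every generator is a pure function of (spec, seed): one named, seeded
pseudo-random stream per call.  Generation ends with a self-check through
the real filter; when the bundled fold model finds an unintended alternative
structure for a random draw (roughly 5–10 % of draws with mutated stars),
the mature is redrawn from the same stream, bounded and deterministic.

What passing the synthetic benchmarks does **not** show: recovery rates on
real transcriptome assemblies, where expression noise, paralogs, repeats and
assembly artifacts dominate; realistic thermodynamic energies (the bundled
model's energies are systematically more negative per pair than
nearest-neighbor values); or behaviour on gapped/bulged precursor variants.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open throughout; BED-style region input.
* T is silently normalized to U; IUPAC codes other than N are rejected
  because the filters are base-exact; N never matches and never pairs.
* Energies are compared with a 1e-9 tolerance in traceback; default weights
  are integer-valued so ties are exact.
* GC = 0 leaves MFEI undefined: the MFEI criterion then fails (it cannot be
  evaluated), and `compute_mfei` raises a domain error when called directly.
* Empty transcriptomes, zero hits and zero accepted candidates are ordinary
  successful runs with zero counts.

## Benchmark problem sizes

The bundled benchmarks run the full pipeline on 65 synthetic transcripts
(50 background, 10 planted, 5 decoys) and on one 6.7-kb polycistronic
reference; the folding oracle enumerates all structures up to 12 nt; the
scan oracle covers 100 random query/transcript pairs.  These sizes exercise
every code path while keeping the whole suite fast enough to run on every
change.

## Known limitations

* The precursor-mode scan is ungapped; indel-divergent known precursors are
  missed.
* The bundled energy model cannot reproduce thermodynamic MFE values; for
  realistic energies plug in an external engine and recalibrate the MFE and
  MFEI thresholds against it.
* Protein-coding exclusion (screening candidate windows against protein
  databases), GO/KEGG enrichment of targets and cross-species alignment of
  cluster precursors are outside this package's scope: they depend on
  external databases and services, and published counts derived from them
  (e.g. genome-scale candidate tallies or a 284-gene target catalogue) are
  not reproducible from synthetic data and are not claimed by the test
  suite.
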