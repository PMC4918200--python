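# Methods

This note documents the models, parameter choices and numerical
decisions behind the `retrozyme` package, and what the synthetic
benchmark does and does not demonstrate about real genomes.

## The hammerhead descriptor

The hammerhead ribozyme is a three-helix junction around a conserved
catalytic core; its three natural circular permutations (types I, II,
III) differ only in which helix is open to the flanking sequence. We
model the motif as a cycle

    [helix I] – core_A – [helix II + loop2] – core_B – [helix III + loop3]
              – cleavage_context ↓ cut – cut_adjacent – back to [helix I]

with DNA-side defaults `core_A = CTGANGA`, `core_B = GAAA`,
`cleavage_context = NTH` (cut 3' of the H) and an invariant `C`
immediately 3' of the cut. Counting every position of these four
segments gives the motif's 15 constrained catalytic-core positions,
which the descriptor reports (`n_core_positions`). The exact core
residues, like every other descriptor parameter, live in configuration:
users matching a different core transcription can adjust the strings,
and the constrained-position count follows.

Default geometric ranges — helix I 3–7 bp, helix II 3–6 bp, helix III
2–5 bp, hairpin loops 3–20 nt — span the motif sizes of typical plant
hammerheads (linearized motifs of roughly 40–90 nt, always ≤150 nt).
Helices pair Watson–Crick with at most one G·U wobble each; helix
stability is scored GC=3, AT=2, GT=1 summed over pairs. Type II is
implemented but disabled by default, since only types I and III occur in
plants.

Degenerate (genomic `N`) positions never match any descriptor position,
including descriptor `N` — ambiguous sequence is conservatively
unsearchable rather than permissive.

### Scanning

The scanner seeds on exact occurrences of the least-degenerate core
word (`CTGA` under defaults) and attempts junction assembly around each
seed for every enabled topology, on the plus strand of each record and
of its reverse complement. Motifs with any substitution in the seed
word are invisible to the structural scan *by design*; decayed relatives
are recovered separately by `find_degenerate_copies` (edlib
infix search at ≥90% identity over ≥90 nt with ≤2 gap columns),
mirroring the usual structure-search-then-homology-search census
procedure.

Every candidate is screened for the helix I–helix II tertiary contact
("bona fide" filter): the longest contiguous antiparallel Watson–Crick
run between loop 1 and loop 2, with a ≥2-bp threshold. Wobbles are
excluded from this run by default because the kissing interactions of
known plant hammerheads are Watson–Crick. Two stand-ins are needed:
type I motifs have no loop 1, so the terminal 6 nt of the distal
helix-I arm are used; type II motifs have no loop 2, so loops 1 and 3
are compared (reported for completeness — it is not the canonical
contact). The contiguous-run heuristic is a reproducible proxy for what
is, in practice, expert curation of loop–loop geometry; it should not be
assumed to reproduce any particular curator's judgment.

Overlapping candidates are resolved greedily, preferring bona fide
status first and helix score second, with orientation-independent
tie-breaks (layout tuple, motif sequence) so that scanning a reverse
complement yields exactly mirrored output. Bona fide status outranks
raw score deliberately: chance pairing of flanking bases can extend an
open helix arm and outscore the genuine layout while pushing the
type I loop-window off the motif, and the scan's purpose is finding
active ribozymes, not maximal stems.

## Element annotation

**Pairing.** Bona fide hits on the same contig, strand and topology are
chained when consecutive *cleavage-to-cleavage* distances fall in
[400, 1100] nt — the spacing is measured between self-cleavage sites
because that distance is exactly the monomer size. Runs of k ≥ 2 hits
give k−1 monomer units; each link is then validated by repeat homology
and runs are split at failing links, which protects elements from being
chained to an unrelated nearby hammerhead.

**LTR delimitation.** The two repeats are anchored offset-aligned at
their cleavage sites and extended outward with a banded global
alignment (match +1, mismatch −1, gap −2, band ±10). The scored model
matters: edit-distance alignment gap-shuffles unrelated sequence up to
~55% identity, while under the scored model random flanks stay near
25%, so the rolling 20-column identity ≥ 0.6 trim actually stops where
homology ends. The end is then pulled back to the last run of five
consecutive matching columns; without this anchor, windows straddling
the repeat edge admit up to ~8 chance columns and downstream TSD search
latches onto spurious duplications. The block is reported when it is
≥200 columns at ≥70% identity; otherwise the pair is rejected
(absence is a value — it is how stray hammerhead pairs are filtered).
Extension is capped at min(cleavage spacing, 700 nt).

**TSD.** The annotator searches for an exact duplication whose left
copy ends at the element start and right copy begins at the element
end, sliding both boundaries independently by ≤12 nt and preferring
longer duplications (6 > 5 > 4 bp), then smaller boundary shifts.
Longer-first tolerates repeat-trimming errors of a few nt; the
generator in turn guarantees (by flank resampling at build time) that
each planted TSD is the unique best duplication in that search
neighbourhood, so the recovered boundaries are exact on the benchmark.
4-bp TSDs are annotated for the WWRR consensus (W∈{A,T}, R∈{A,G}).

**Boxes.** The 3' box (~25 nt spanning the 5'LTR → PBS junction) and
5' box (PPT → 3'LTR junction) are matched as IUPAC consensus strings
with ≤6 mismatches in a ±40-nt window around the expected junction
offset, on the element's own sense. The default strings are
configuration placeholders built around the canonical plant Ty3-gypsy
PBS (`TGGTATCAGAGC`, the tRNA-Met complement) and a purine PPT; the
synthetic generator embeds whatever is configured, so correctness of
the pipeline is decoupled from the fidelity of any particular consensus
transcription. A standalone PPT detector also reports the longest
purine run ≥8 nt (≤1 pyrimidine) within 40 nt upstream of the 3' LTR.

**Classification** is a partition: full_retrozyme (validated LTR pair,
monomer within [500, 1200] nt — wider than the biological 600–1000 to
tolerate boundary noise), multimeric_retrozyme(n) for runs of ≥3 hits,
solo_LTR for a lone bona fide hammerhead embedded in a 250–450 nt
context carrying the LTR halves of both boxes at proportionally scaled
mismatch tolerance, and orphan_HHR otherwise. Every bona fide hit
receives exactly one class.

**Monomer extraction** is a pure slice between cleavage positions
(plus-strand between-base indices; minus-strand monomers are
reverse-complemented), returned in the RNA alphabet. For multimers the
monomer is the first repeat unit in element sense. Length equals the
coordinate difference exactly, by construction.

## Folding

The monomer self-complementarity statistic — the fraction of
nucleotides engaged in base pairs — is computed from a maximum-weight
nested structure (weighted Nussinov DP; GC=3, AU=2, GU=1; hairpin
loops ≥3; no pseudoknots) rather than a thermodynamic model. At this
granularity the statistic is robust to the scoring model, and the DP
admits exact brute-force oracle testing (exhaustive enumeration agrees
with the DP optimum on every seeded sequence ≤25 nt). Co-optimal ties
are broken by a fixed traceback: at each interval, the smallest
5'-partner that achieves the optimum pairs the 3' base, else the 3'
base is left unpaired. The kernel is JIT-compiled when numba is
available, with an identical pure-Python fallback.

Two caveats are worth recording. First, with wobble pairs the pairing
statistic is *not* invariant under reverse complement (a G·U pair maps
to A·C, which does not pair); the invariance property holds, and is
tested, for the Watson–Crick-only weight set. Second, base-pair
maximization systematically pairs more nucleotides than a free-energy
model — random 750-nt RNA already reaches ~0.76 fraction paired under
these weights, and planted monomers ~0.75–0.80 — so absolute
fraction-paired values are comparable within this scorer, not directly
against minimum-free-energy predictions. An external MFE engine can be
used for cross-checks, but nothing in the package requires one.

`hhr_blocked` reports the share of hammerhead-motif nucleotides whose
pairing partner lies outside the motif span — the "blocked"
conformation in which the folded monomer sequesters its own ribozyme.

## Consensus rendering

Per column, with gaps excluded from the denominator: a single base at
total conservation renders uppercase; a purine or pyrimidine class at
total conservation renders `R`/`Y`; a single base at ≥70% renders
lowercase; a class at ≥70% renders `r`/`y`; anything else is a dot.
Class checks precede the lowercase tier at the total-conservation level,
so an all-purine column split 7/3 renders `R`, not `g`. Gap exclusion
is a robustness choice for ragged alignment ends. The bundled
center-star aligner (+1/−1/−2) exists to build fixtures from
near-identical synthetic sequences; it is not a general MSA tool.

## The synthetic benchmark

`SyntheticSpec` defaults define the study conditions: a 5-Mb i.i.d.
background at 40% GC carrying 20 full retrozymes, 5 solo LTRs, 2
multimers (3–4 hammerheads) and 10 decoys, with 330-bp LTRs, 300–600 bp
internal regions (monomers 600–1000 nt), 1% LTR divergence, 4-bp WWRR
TSDs, type III hammerheads, random strands, seed 7. Divergence
mutations avoid the hammerhead footprint — the ribozyme is under
purifying selection in real elements, and an element whose second
ribozyme is dead is no longer the planted class. The decoy catalogue is
designed to probe each filter independently: core-mutated hammerheads
(descriptor soundness), shuffled monomers (sequence-composition
specificity), stray hammerhead pairs (LTR-homology validation), LTR
pairs without hammerheads (anchor requirement).

`make_hhr` validates each sampled motif against the scanner and
resamples ambiguous draws, so the recorded layout and cleavage offset
are guaranteed to be the unique best parse; ground truth is therefore
exact by construction, not by curation. Planted inserts keep ≥1250 nt
of background between them so that flank-dependent annotation steps
(TSD search, solo-LTR context) never interact across elements.

What passing the benchmark shows: the scanner is sound and complete for
motifs inside descriptor ranges, strand-symmetric, and robust to the
planted decoys; the annotator recovers planted anatomy exactly under
≤2% LTR divergence. What it does not show: performance on real repeat
landscapes (nested insertions, segmental duplications, diverged element
families), on assemblies with gaps/ambiguity runs, or under descriptor
mismatch to a genome's actual hammerhead variants — the i.i.d.
background contains none of these. Real-genome censuses additionally
depend on assembly version and manual curation, which is why published
counts are treated as indicative cross-checks only.

## Numerical and convention choices

* Coordinates are 0-based half-open on the plus strand throughout;
  writers convert (GFF3 1-based inclusive; BED6 unchanged). Cleavage
  positions are between-base indices; a minus-strand motif stores the
  plus-strand position of its biological cut, which makes monomer
  extraction a strand-agnostic slice.
* Determinism: identical inputs and configuration produce byte-identical
  outputs everywhere; all generator randomness flows from one seed
  through `numpy.random.default_rng`.
* Degenerate-copy search reports matches merged per strand and excludes
  the seed's own locus (an explicit interval if supplied, else the
  first exact occurrence).
* Box consensus strings, descriptor geometry, spacing bounds, monomer
  bounds and all thresholds are exposed in YAML configuration
  (`retrozyme.config`); the values named in this note are the defaults.

## Problem sizes

The test suite and the acceptance script size their computations for a
single CPU: 200 planted motifs per topology for the detection-rate
check, all non-N core positions over 15–20 motifs for specificity, 50
seeded genomes for strand symmetry, 100 sequences ≤25 nt for the
folding oracle, and one 5-Mb benchmark genome end-to-end. The whole
suite runs in a few minutes; the acceptance script in well under five.

## Known limitations

* The loop–loop heuristic, the type I distal-arm window and the type II
  loop1–loop3 stand-in are proxies for curated tertiary-geometry
  inspection.
* Solo-LTR detection presumes the configured box halves; heavily
  diverged solo LTRs classify as orphan_HHR.
* The TSD search can prefer a spurious longer duplication when the
  delimited boundary drifts outside the generator-guaranteed window;
  on the benchmark this does not occur, on real data it would add a
  few-nt boundary noise.
* Folding is linear-sequence only (no circular folding, pseudoknots or
  ensemble statistics), matching how monomer structures are usually
  drawn.
* U3/R/U5 sub-annotation of LTRs, identification of autonomous partner
  elements, and insertion-age estimation are out of scope.
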