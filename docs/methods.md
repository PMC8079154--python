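# Methods

This note documents the models and conventions behind each screen, the
defaults and why they were chosen, what the synthetic generators emulate,
and the known limits of what passing tests demonstrate.

## HGT indices

For one gene with hit table *H* and taxonomy groups *g* ∈ {prokaryote,
eukaryote, algae, lophotrochozoa}, let `S_g = max{bit score of h ∈ H :
taxon(h) ∈ g}`, with `S_g = 0` when the group has no hit (the usual
alien-index convention; it makes a gene with only donor-side hits strongly
positive rather than undefined). Then

    h  = S_prokaryote − S_eukaryote
    hA = S_algae      − S_lophotrochozoa

Both are plain bit-score differences — no length normalisation, no
self-hit correction — computed from the raw hit table (no LCA-style
pre-filtering). A gene is a candidate when its index reaches the
configured threshold (default 100 bits, the conventional magnitude). The
sign convention is donor-minus-host with candidacy at ≥ +100; because the
opposite reading of the h threshold circulates in figure legends, a
config switch (`hgt_index.sign = "host-donor"`) negates both indices so
either convention is reproducible. Note that algae and lophotrochozoans
are both eukaryotes, so `S_eukaryote ≥ max(S_algae, S_lophotrochozoa)` by
construction.

Properties tested: antisymmetry under donor/host exchange, translation
invariance when both groups have hits (and its documented failure when
one is pinned at 0), monotone shrinkage of the candidate set in the
threshold.

## LCA assignment

Hits of one gene are filtered by Min Score (bit ≥ 50), Max Expected
(E ≤ 1e-4), and Top Percent: keep hits within 20% of the best surviving
bit score (bit ≥ 0.8 × best). Distinct subject taxa then vote — multiple
hits to the same taxon count once, so one over-represented subject genome
cannot dominate. The gene is assigned to the deepest node whose subtree
contains ≥ `lca_percent`/100 (default 90%) of the voting taxa; equally
deep qualifying nodes are resolved to their LCA, which makes the result
independent of hit order. Fewer retained hits than `min_support`
(default 1) gives the UNASSIGNED sentinel.

Min Support Percent (default 0.1%) is applied across a whole run, the way
MEGAN applies it: a gene assigned to a taxon whose subtree accounts for
less than that share of all assigned genes is *pushed up* to the nearest
ancestor with sufficient cumulative support, rather than discarded. The
root always qualifies, so the rule relocates evidence instead of deleting
it. Min Complexity is a sequence-level filter; this pipeline never reads
sequences, so an optional per-query low-complexity mask is accepted as
input and logged as skipped when absent.

The implementation only examines ancestors of hit taxa (support is zero
elsewhere); the test suite checks it against an exhaustive scan over
every tree node on 200 random (tree, hit-set) instances.

## Alignment and read screens

A genome-level hit is *credible* iff it covers more than 60% of the query
— `(qend − qstart + 1)/qlen > 0.60` — and its normalised score exceeds 2,
where the normalised score is the raw alignment score (substitution
matrix plus gap penalties) divided by the aligned length in bp. Both
inequalities are strict; dialects that lack a raw-score column fail fast.
The tblastn-style screen is E-value only: credible iff `E < 1e-4`
(strict).

Read-hit counts are normalised as TPM: `rate_q = count_q/(len_q/1000)`,
`tpm_q = rate_q / Σ rates × 1e6` over the query universe (the union of
the target and control sets within one library), so TPMs sum to 1e6
whenever any read maps. Because published per-query means on this scale
need not satisfy that sum constraint, an alternative denominator — total
library reads per million — is available (`read_screen.tpm_denominator =
"library_total"`); it is the scale on which per-query counts are
comparable across libraries and the one the read generator targets. The
two query sets are compared with Welch's two-sided *t* on TPM values;
target-set queries above `flag_tpm` (default 100, strict >) are flagged
as annotations only. A flagged query is *explained* when more than half
(configurable) of its reads also hit at least one host gene — the
signature of a conserved host paralog rather than a true algal locus.

## Assembly decontamination

Two removal rules, deliberately conservative so a genuine horizontally
transferred gene on a nuclear scaffold is never discarded:

- **bacterial contaminant**: ≥ 2 bacterial genes (by LCA) and zero
  lophotrochozoan genes. A single host gene always rescues a scaffold.
- **organelle**: best blastn-style bit score against an organelle
  reference > 1000 *and* read depth ≥ 10× the nuclear mean depth. The
  nuclear mean is computed two-pass, excluding bit-score-flagged
  scaffolds, so organelle depths (often 17–170× nuclear) cannot inflate
  the baseline. The 10× default sits far below observed organelle folds
  and far above nuclear depth noise. A bit-score pass without the depth
  pass yields *ambiguous*: reported, retained.

The kleptoplast tissue-depth check is a corroboration flag, not a gate: a
scaffold's depth ratio between a kleptoplast-rich and a kleptoplast-poor
library, after dividing each library's depths by its median (library
sizes differ), should fall in the closed interval [2, 4].

## Orthogroup statistics

Family expansion: per orthogroup, `z = (count_focal − mean)/sd` over all
species columns with the sample SD (n−1); rows with zero SD get z = 0 and
are never expanded; expanded iff z > 2 (strict). The focal species is
included in mean/SD by default (the heatmap-row convention); note this
caps the attainable z at `(n−1)/√n`, so meaningful calls need a
reasonable species panel (the default synthetic panel has 18).
`expansion.include_focal = False` switches to the leave-one-out variant.

Enrichment: Fisher's exact test on (up-in-group, up-elsewhere,
not-up-in-group, not-up-elsewhere). The two-sided p is the
point-probability method (sum over tables whose probability does not
exceed the observed one), the common statistical-package convention; a
one-sided "greater" alternative is available, and the headline results
hold under both. The background defaults to all genes in the membership
map and can be overridden (e.g. all 77,230 gene models vs an
expression-tested subset); the reported enrichments are insensitive to
that choice at the 1e-4 level. Implementation: `scipy.stats.fisher_exact`;
the test suite verifies it against full-margin enumeration with exact
integer arithmetic for tables up to N = 200.

## Physiology

Oxygen rates are OLS slopes of concentration (mg O₂ l⁻¹) against time,
reported per minute. The caller selects the dark and light fitting
windows explicitly — oxygen traces lag a few minutes after illumination
changes, and no automatic trimming is attempted. Gross photosynthesis is
`oG = oL + oD` with `oD` stored as a positive consumption magnitude
(`oD = max(0, −dark_slope)`); a positive dark slope is biologically
unexpected and is clamped with a warning. Welch's *t* uses the standard
statistic with Welch–Satterthwaite degrees of freedom and a two-sided p;
zero-variance degenerate inputs give t = 0, p = 1 for equal means and a
p → 0 sentinel with a warning otherwise.

## Synthetic data: what it emulates, and what it does not

Bit scores are synthesised from a raw-score model through the
Karlin–Altschul conversion `bits = (λ·S − ln K)/ln 2` with λ = 0.267,
K = 0.041 (classic protein-search constants; synthesis only). A gene of
L residues scores about `L × 2.0 × 0.9` bits against its true-origin
group, and `margin` bits lower (default 400) against the opposing group,
plus Gaussian noise (SD 25 bits). The defaults keep the 100-bit candidate
threshold many noise-SDs away from both the planted-HGT and host
populations, which is why the recovery tests demand perfect separation;
the separation degrades monotonically as noise grows, and that trend —
not the perfect recovery — is what transfers to real data, where margins
are far smaller and database composition matters.

The genome generator plants HGT genes *among* host genes on nuclear
scaffolds (decontamination must not remove them), builds contaminant
scaffolds carrying only bacterial genes, and organelle scaffolds with no
gene models. Depths follow the observed structure: nuclear ≈ 31× (SD 3),
organelle 17–166× nuclear with a 2.2–3.8× rich/poor tissue ratio (kept
inside the closed [2, 4] acceptance band), contaminants on their own
lower scale. Read counts are negative-binomial — strongly overdispersed,
matching control sets whose SD is of the order of the mean — with the
control set ~100× the algal set (targets 25 vs 2601 on the per-library
TPM scale) over 614 algal and 905 control queries. Orthogroup counts are
Poisson(3) per species over 200 orthogroups × 18 species, with planted
focal expansions (focal count 60–250) that guarantee z > 2 at this panel
shape.

Sequences, when written, are random nucleotides; no screen reads sequence
content. Nothing in the generators models alignment mechanics, database
incompleteness, chimeric assembly, or cross-contamination between taxa —
so a passing recovery suite demonstrates the *logic* of the screens under
their stated assumptions, not their field performance.

## Numerical and design choices

- Coordinates: GFF3 is 1-based inclusive externally, 0-based half-open
  internally; conversion happens only at the I/O boundary.
- Hit-table dialects are explicit (`blast6`, `blast6+qlen`, `mmseq2` =
  the 12 standard columns + qlen + raw), never sniffed: tabular variants
  differ silently in column order. An optional trailing `staxid` column
  or an external subject→taxon map supplies taxa.
- Floats are written with `repr` so every table round-trips bit-exactly.
- All boundary conventions are strict or closed exactly as stated above
  (coverage >, norm score >, E <, bit score >, TPM flag >, z >, tissue
  ratio closed [2, 4]) and are pinned by dedicated unit tests.
- Every generator takes an explicit seed and is fully deterministic under
  it; the acceptance script derives all sub-seeds from its `--seed`.
- Problem sizes in the recovery suites (≈2,100 genes × 10 seeds, 200
  orthogroups × 18 species) were chosen as the smallest scale at which
  each statistic is comfortably identified.

## Known limitations

- The LCA implementation targets the MEGAN parameter set used for genome
  screening; it does not implement MEGAN's long-read or weighted modes.
- The organelle rule assumes depth data exist; without any depth table it
  degrades to bit-score-only calls with a logged warning.
- Fisher's odds ratio is the sample odds ratio (∞ when a margin cell is
  empty), not the conditional MLE.
- The expansion Z-score is a descriptive screen, not a birth–death model;
  gene-family inference tools with explicit phylogenies answer a
  different, sharper question and their calls can be carried as an input
  annotation instead.
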