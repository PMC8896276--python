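# Methods

## The estimand

PM5 (within-codon concordance) is treated as a binary diagnostic test. For a
missense variant *v* with a dichotomous functional truth label
(DEL/TOL), the test result is the PM5 prediction obtained by looking up
colocated deleterious variants in a lookup source. The quantity of interest is
the positive likelihood ratio

pLR = sensitivity / false-positive rate = [TP/(TP+FN)] / [FP/(FP+TN)],

the factor by which observing the PM5 criterion multiplies a variant's prior
odds of pathogenicity. The printed-orientation negative likelihood ratio
[TN/(TN+FP)] / [FN/(FN+TP)] is also computed; note this is the reciprocal of
the conventional nLR (values > 1 favour benignity). Because false-negative
rates are high under stringent rules, the nLR is uninformative by design and
carries no evidence weight here.

## Rules, bands, lookup

Colocated references are counted per **distinct amino-acid substitution** at
the same (gene, codon), never per nucleotide change: two SNVs encoding the
same residue change contribute one reference, and the substitution under
examination is always excluded (leave-one-out). The identical substitution
reached by a different nucleotide change is same-residue (PS1-type) evidence,
not within-codon concordance, which is why leave-one-out operates at
substitution level. This also makes the engine safe when lookup and truth
share a source.

Rules a–e combine a minimum colocated-DEL count (1 or 2) with an
"equally-or-more damaging" in-silico comparison met against ≥0, ≥1 or ≥2
references. Ties count as met. A missing score on either side makes a
comparison undecidable; undecidable counts as *not met*, which biases
predictions toward TOL (conservative). References with missing scores still
count toward the colocated-DEL minimum for rules a/b.

Bands x / y / baseline are the mutually exclusive version: x = exactly one
colocated DEL with the comparison met; y = ≥2 with ≥1 met; baseline =
everything else. Band cells are evaluated band-vs-baseline, so the x and y
rows of one tool share their FN/TN cells.

Supported lookup/truth combinations: clinical lookup vs functional truth (the
primary design), functional/functional, clinical/clinical. Functional lookup
against clinical truth has no interpretation in this design and is rejected.

## Eligibility and dichotomization

A record enters analysis if it is missense (ref ≠ alt, alt not a stop), not at
the initiator codon (any change at codon 1 is excluded regardless of
residues), not at a para-splice-site position (the 2 exonic bases flanking an
intron–exon junction; terminal exon edges abut UTR and are not flagged by
default, `flag_terminal` overrides), and carries a dichotomous assay class —
intermediate or absent assay output is excluded. Clinical classes map to
DEL for P/LP and TOL for B/LB gated on a ≥1-star review status; VUS,
conflicting, unrated and unlabelled records are missing. An optional
sensitivity toggle (`drop_spliceogenic`) additionally removes records whose
RNA readout is flagged intermediate or depleted, mirroring the midexonic
spliceogenic sensitivity analysis.

Exclusion reasons are reported in fixed precedence (non-missense >
initiation > para-splice-site > intermediate assay > spliceogenic) purely for
stable reporting; the filters are independent predicates, so the eligible set
does not depend on order, and counts always reconcile:
n_input = n_eligible + Σ exclusions.

Nucleotide duplicates of one substitution are collapsed before filtering. If
the collapsed records disagree on functional class, the merged record is set
INTERMEDIATE (hence excluded) and a warning is emitted rather than silently
keeping either class — the disagreement is data, not a tie to break.

## In-silico comparators

BLOSUM45/62/80 are the published matrices (via Biopython); lower score = more
damaging substitution. The Grantham distance is computed from the 1974
composition/polarity/volume properties, D = ρ·[α·Δc² + β·Δp² + γ·Δv²]^½ with
α = 1.833, β = 0.1018, γ = 0.000399 and ρ normalizing the mean over the 190
residue pairs to 100 (ρ ≈ 50.790); higher = more damaging. Distances are
rounded half-up to integers; the full rounded matrix is frozen as package data
and the test suite sweeps formula-vs-table equality. Historically typeset
copies of the matrix differ from direct formula evaluation by one unit in a
minority of cells (rounding conventions of the era); this package treats the
formula as the single source of truth. The anchors that matter downstream
(Leu–Ile = 5, Trp–Cys = 215 = maximum, zero diagonal, symmetry) hold.

REVEL, Meta-SNP and CADD (Phred-scaled) are higher-is-damaging inputs;
Align-GVGD is compared on ordered class rank C0 < C15 < … < C65 (comparison on
class labels, not raw GV/GD, is the default; the registry is overridable in
the run config, which is also how a new tool is added).

## Likelihood-ratio estimation

Every 2×2 receives the Haldane–Anscombe correction (+0.5 per cell)
unconditionally — not only when a zero cell occurs — so all cells, including
well-populated ones, are estimated under the same slightly conservative
scheme, and double correction is an error. The 95% CI uses the standard
log-method for a ratio of two binomial proportions:
exp(ln pLR ± z·√(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN))) on corrected cells,
with z = 1.959964 (the exact 97.5th normal quantile; the two-decimal 1.96
shifts a few extreme upper bounds by one final digit relative to the published
values). Display rounding is half-up to 1 decimal; internal values keep full
precision. Evidence points are 8·ln(pLR)/ln(350), binned at 1/2/4/8 points
into supporting/moderate/strong/very strong.

Per-gene scopes are evaluated separately and combined by cell-wise summation
of the confusion matrices; no other pooling is performed.

## Synthetic cohorts

The generator draws, per codon: a class (deleterious-only / mixed /
tolerated-only), a variant count, a reference residue, and distinct alternate
residues. Mixed codons with ≥2 variants are guaranteed to carry both classes.
Each variant gets a latent damage signal (1 for DEL, 0 for TOL); generated
tool scores and the functional score are damage + Gaussian noise with
standard deviation `tool_noise_sd`, so one dial controls how informative the
in-silico comparison is. Clinical labels are sparse and DEL-biased
(`p_clinical_label_given_del` ≫ `p_clinical_label_given_tol`), wrong with
probability `clinical_error_rate`, and carry 1–3 stars. Para-splice-site and
spliceogenic-RNA flags are sampled independently. One `numpy` Generator seeded
from the config drives everything; a fixed config is bit-reproducible.

Defaults mirror the scale and mix of the combined study cohort: 1229 codons,
class mix (0.019, 0.279, 0.702), 3–9 variants per codon (~7.5k variants),
DEL-given/TOL-given label probabilities 0.19 / 0.0074, error rate 0.02, noise
SD 0.5, para-splice probability 0.05, spliceogenic probability 0.017.

`shuffle_null` permutes the functional labels across variants (marginals
preserved), severing any association between codon structure or clinical
labels and truth: under this null the definition-a pLR is ≈ 1, which the
acceptance suite checks as a mean over 20 seeds at 2000 codons within
[0.8, 1.25]. Property tests at these sizes run in seconds; they were chosen as
the smallest scales at which binomial noise is comfortably inside the asserted
bounds.

What the generator does *not* emulate: real per-tool score distributions,
gene-specific codon architecture, linkage between splice-site position and
assay readout, and ascertainment structure of real clinical databases beyond
simple DEL-biased sparsity. Passing synthetic tests therefore demonstrates
correctness of the machinery and qualitative behaviour (calibration under the
null, monotone gain with stringency, conservatism under label sparsity), not
real-data effect sizes. One measured divergence from a naive expectation is
itself informative: thinning deleterious labels raises the FN rate *and*
lowers the FP rate in step, leaving the pLR roughly stable — sparse clinical
classification makes PM5 rarer, not weaker.

## Published-cell replay

The published result tables print the full TP/FN/FP/TN for all 126 analysis
cells (binary rules × 8 tools × 3 gene scopes, plus banded x/y rows). These
integers are shipped as a plain-text fixture and replayed through the LR
engine; all 126 printed pLRs and CI bounds reproduce to 1 decimal. One
typesetting anomaly in the source is preserved as printed: the combined
banded Grantham y row duplicates the CADD y row and is not the sum of its
per-gene cells, but it is internally consistent with its own printed pLR.
Regenerating the confusion matrices themselves from raw MAVE + ClinVar data
requires external downloads and is out of scope; the engine-level properties
(brute-force equivalence, nesting, band partition, null calibration) stand in
for it.

## Known limitations

- The pLR treats the truthset as ground truth; assay misclassification is not
  modelled.
- No exact conditional CIs; the log-method is asymptotic (the unconditional
  +0.5 correction mitigates but does not remove small-cell issues).
- Cross-gene (paralog) lookup and PS1-style same-substitution logic are out of
  scope.
- The generator's damage signal is binary; hypomorphic/intermediate-penetrance
  structure is represented only as an exclusion class.
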