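# Methods

## Scope

`hipscreen` models the computational side of a functional screen for
proinsulin-derived hybrid insulin peptides (HIPs): neoepitopes formed when
two proteolytic fragments of proinsulin fuse inside beta-cell secretory
granules and are presented on MHC class II (HLA-DQ8/DR4) to islet-
infiltrating CD4+ T cells. The pipeline covers library design, pool layout,
a generative model of the pooled luciferase screen, staged hit
deconvolution, potency estimation, fragment-origin mapping, and CFSE
cohort statistics. Wet-lab steps (cloning, flow cytometry, sequencing
chemistry) are out of scope; their outputs enter as plain-text tables.

## Library construction

Mature human proinsulin (86 aa: B-chain 1-30, RR linker 31-32, C-peptide
33-63, KR linker 64-65, A-chain 66-86; 1-based inclusive coordinates) is
cut into all 75 overlapping 12-mers. Every ordered pair of distinct
12-mers is fused into a 24-mer (75 x 74 = 5,550 fusions), and every
12-residue sliding window that crosses the fusion junction is a candidate
epitope (11 per fusion; 61,050 before deduplication). Windows contained
within a single parent 12-mer are native proinsulin peptides and are
excluded.

Candidates are ranked by a pluggable binding predictor using the
percentile-rank convention (lower = stronger). The faithful path is a
table-backed predictor fed from an external MHC class II prediction
server export; the file must declare `# rank: ascending` or the loader
refuses it. A deterministic surrogate position-weight scorer (9-mer core,
best register, acidic bonus at the P9 anchor in the style of the HLA-DQ8
motif) ships so the pipeline runs offline; it is documented as a
non-validated stand-in, not a predictor. Selection keeps the
floor(q*N) strongest candidates (default q = 0.21) with deterministic
tie-breaking (sequence, then provenance), and duplicates are merged last,
preserving every parental provenance. A config switch allows
deduplicate-before-select for sensitivity analysis.

The full-scale screen scenario (`hipscreen.scenario`) uses the 4,488
strongest distinct candidates under the surrogate scorer so that the
screen dimensions (4,488 members, 136 pools of 33, 34 super-pools of 4,
109 avatars; 489,192 avatar x peptide combinations) are exact; member
identities in this scenario are synthetic because the original external
predictor is not reimplemented.

## Pooling and representation QC

Members are shuffled by a seeded RNG and chunked into pools of 33; pools
are grouped in id order into super-pools of 4; trailing pool/super-pool
may be short. Sequencing counts are converted to transcripts per million,
`tpm_i = (c_i/l_i) / sum_j(c_j/l_j) * 1e6`, and the representation report
counts members strictly above a threshold (default 26 TPM). The synthetic
count generator draws member proportions from a symmetric Dirichlet
(default concentration 2.5 per member, a well-made library) and reads
from a multinomial; at these defaults >= 97.5% of a 4,488-member library
sits above 26 TPM.

## Generative model of the screen

A well's readout is `rlu = (background + signal) * eps`, with
`eps ~ LogNormal(0, sigma^2)`: luciferase readouts are positive with
roughly constant coefficient of variation. The activation signal follows
a Hill curve of the agonist concentration,
`signal = signal_max * c^h / (c^h + EC50^h)`. In a pooled well each
member is diluted to `dose / pool_size` (configurable off), and when
several agonists share a well the strongest dominates (the reporter
saturates; a saturating-sum option exists). Antigen-negative wells
(GST-only bacteria, no antigen) carry zero signal. Colonies are sampled
from pools by a Dirichlet-multinomial (symmetric concentration `skew`;
infinity = uniform), or exhaustively (one colony per member).

Defaults, chosen once as plausible assay magnitudes: background 2,000
RLU; signal_max 50,000 RLU (so saturated responses sit >1e4 RLU above
background, the scale of a strong screen response); sigma 0.15 for
bacterial screen wells and 0.10 for synthetic-peptide titrations (cleaner
antigen); Hill slope 1; dropout 0; screen antigen load 2 mM equivalents
(bacteria deliver antigen far above any planted EC50, so super-pool
dilution by 132 still saturates weak agonists). All randomness flows from
explicit integer seeds; each simulated plate derives its seed from the
master seed and the query, so whole screens are bit-reproducible.

The planted headline truth mirrors the screen outcome being modelled:
9 reactive avatars among 109, 13 distinct reactive members with
potencies log-spaced 20 nM - 20 uM, and the observed avatar
multiplicities (one avatar recognising eight members, two recognising
three, one two, five one, with sharing between avatars).

What the generator does not model: bacterial growth and induction
kinetics, antigen-presentation cell biology, plate-position effects,
cross-reactivity to sequence-similar non-planted members, and predictor
error. Passing recovery tests therefore shows the decision rules and
bookkeeping are sound under the stated noise model, not that the wet
screen had this sensitivity.

## Hit calling and deconvolution

Responses are Delta-luciferase: well RLU minus the mean of the GST-only
control wells on the same plate (computed per plate, as each screening
batch carries its own baseline). An antigen is positive when its mean
replicate delta exceeds `k * SD(control wells)` (k = 2; SD floored at
1 RLU to guard the noiseless degenerate case) and, by default, is also
significant in a one-way ANOVA followed by Dunnett's many-to-one
comparison against the control at family-wise alpha = 0.05 (one-sided:
activation is directional).

For balanced designs the Dunnett adjusted p is computed by the standard
two-dimensional quadrature of the multivariate-t max statistic
(Gauss-Hermite over the shared control variate, Gauss-Legendre over the
chi-distributed pooled scale); unbalanced designs fall back to scipy.
The quadrature path is validated against scipy's implementation and
against a simulated global null (family-wise error ~ alpha).

Deconvolution proceeds super-pool -> pool -> colony. Stage 1 screens all
34 super-pools in triplicate per avatar. Stage 2 re-tests each positive
super-pool alongside its four component pools; a super-pool that fails
re-testing is dropped (weak unconfirmed responses go no further). Stage 3
screens colonies from positive pools in duplicate; positive colonies are
then re-screened on an independent plate and must confirm before their
member is reported. The confirmation step reflects that no hit in the
modelled workflow is reported from a single plate (every hit was
validated downstream with sequencing and synthetic peptide); without it,
chance colony positives at the per-family alpha accumulate across the
~13 colony families of a full screen and inflate the recovered set by
roughly one member every few screens. Identified members are deduplicated
per avatar and each carries its full evidence chain (super-pool, pool,
colony ids, stage deltas), which is checked against the manifest.

Paired islet-versus-spleen extract responses are compared with a paired
Student's t test on within-pair differences; constant nonzero differences
are flagged degenerate (no sampling variance) with the limiting p of 0.

## Dose-response potency

Curves follow the four-parameter logistic
`y = bottom + (top - bottom) / (1 + (EC50/x)^hill)`, fitted by nonlinear
least squares on log10 dose with data-driven initialisation (bottom =
min, top = max, EC50 = geometric mid-dose, hill = 1). Two error models:
additive (raw residuals) and proportional (log-residuals, the correct
likelihood for multiplicative noise; requires positive responses).
Zero-dose wells constrain the bottom asymptote directly. A fit is
censored — reported as "> max dose" — when the fitted EC50 exceeds the
highest tested dose or the response at the top dose reaches less than
80% of the fitted span; flat curves (span within ~2 residual SDs) are
flagged unreliable. The standard titration is a 12-point 3-fold dilution
series from 20 uM in triplicate, and a peptide's potency is the
geometric-mean EC50 over three independent titrations; at sigma 0.10
this recovers a 20 nM potency within 15% in 59/60 seeded replicates
(single titrations are information-limited to roughly +/-25%).

## Fragment-origin mapping

Each identified HIP is split at its junction (known from provenance, or
enumerated over all splits mappable to proinsulin), each side located in
the sequence (all occurrences reported), and assigned the region covering
the majority of its residues; ties favour C-peptide, then the earlier
region — a fixed rule for linker-spanning fragments. The origin summary
refuses ambiguous annotations (a side occurring in two different regions)
rather than guessing; provenance resolves these in practice. The packaged
13-member panel (`data/synthetic_hip_panel.tsv`) contains the two
published main-text sequences plus eleven synthetic fusions constructed
to match the reported aggregate origin distribution (all 13 N-terminal
fragments from C-peptide; C-terminal: 8 C-peptide, 3 B-chain, 1 A-chain,
1 linker-spanning); it is a labelled synthetic stand-in for the
unpublished full peptide table. Logo input is a right-aligned
position-frequency matrix (column 0 = C-terminus), exported as TSV for
external logo renderers.

## CFSE cohort statistics

The cell division index is CDI = (CFSE-dim CD4+ cells with antigen) /
(without antigen), both counted per 5,000 CFSE-bright cells; CDI >= 3.0
is a positive response (inclusive threshold). A zero denominator is
floored at 1 and flagged. Cohort responder fractions are compared with a
one-tailed Mann-Whitney rank test: exact enumeration of all group
assignments (ties handled exactly) up to combined n = 20, normal
approximation with tie correction beyond. The cohort generator plants a
per-group responder probability and effect size with Poisson counts
around a base rate (default 20 dim cells per 5,000 bright).

## Numerical and design notes

- Coordinates 1-based inclusive throughout; FASTA/TSV/CSV/JSON are the
  only interchange formats.
- Selection size is floor(q*N); ties at the cut break deterministically.
- Pool assignment is seeded-random (id-order chunking via `seed=None`).
- The 2xSD threshold uses strict ">", the TPM threshold strict ">",
  the CDI threshold inclusive ">=", each matching its stated rule.
- Problem sizes in the test suite (20-seed full screens in the
  acceptance script, 3 in the suite; 2,000-4,000-replicate null
  simulations; 200-curve recovery) were chosen to give stable Monte-Carlo
  estimates at interactive runtimes.
- Known limitations: the surrogate binding scorer is not a predictor and
  library member identities in the full-scale scenario are synthetic;
  the noise model is single-plate lognormal without spatial or batch
  structure; deconvolution assumes the manifest is error-free (no
  misplated members); censored EC50s are bounds, not estimates.
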