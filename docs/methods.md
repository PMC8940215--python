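# Methods

## Cleavage events and coordinates

The unit of evidence is a cleavage event: one observation, in one
biological replicate, of a neo-N-terminal peptide whose preceding
residue is aspartate (a D↓X site). Coordinates are 1-based; the cut
falls between P1 and P1′; every event carries the 8-residue P4-P4′
window, right-padded with `X` past the C terminus. Only the P4-P2 half
enters any statistic (P1 is D by construction, and prime-side residues
are confounded with MS detectability of the recovered peptide).

Events are derived from peptide evidence by requiring the residue
immediately preceding the peptide start to be D. Sites with P1 < 5 are
dropped — no full P4 window exists — and the same rule bounds the
background (below), so all 60 motif tests share one population of
aspartate contexts. Peptides without a stated start coordinate are
located by exact substring search and yield one event per match;
same-replicate events from different proteins with identical P4-P4′
octamers can be collapsed to a single event ("family duplicates", kept
toggleable with an audit log, because protein families are not
computable from accessions alone and the identical-octamer proxy is a
conservative superset).

## Subsite enrichment

For motif m at subsite s, per replicate i: k = cleaved sites whose s
residue matches m, n = all cleaved sites, K = aspartate contexts in the
replicate's cleaved substrates matching m, N = all their aspartate
contexts (positions >= 5). Totals sum over replicates, so a substrate
cleaved in r replicates contributes its sequence background r times —
replicate weighting makes the background track where the evidence
actually is. The test is the two-sided mid-p hypergeometric
(doubling the smaller one-sided mid-p, capped at 1); fold is
(k/n)/(K/N). Residues outside the 20-letter alphabet (X/U/B/Z) at a
subsite match no motif but still count toward N: they are genuine
aspartate contexts of unknown residue.

Mid-p assigns half the probability of the observed outcome to the tail:
it is not strictly level-α for any single test, but its rejection rate
averages α across parameter configurations, which is the property the
null-calibration tests verify.

## Multiple testing

Within each family (the 60 motifs; the 1,770 pairs; each annotation
category separately) false discovery is controlled by the two-stage
linear step-up procedure: stage 1 runs the linear step-up at level
α/(1+α) and estimates the number of true nulls m₀ as m minus the
stage-1 rejections; stage 2 reruns the step-up sharpened by m₀/m. The
reported q-values are calibrated so that q ≤ α reproduces the two-stage
decision at level α (they carry the (1+α) factor); when m₀ < m they can
drop below the raw p-values, which is the adaptive procedure's point.
Family-wise control, where used (pair candidate selection), is the
Bonferroni cutoff α/m.

## The protein-cleavage null model

The annotation-association question must not be answered by term
enrichment alone: flagged substrates may simply carry more cleavage
sites per protein (the package's Mann-Whitney comparison of
(protein, replicate) site counts makes that bias visible), in which
case *any* motif would appear associated. The Monte Carlo null
conditions on exactly the two observed quantities that create the bias:
each replicate's motif frequency k/n, and each flagged substrate's own
per-replicate site count S. Under the null the substrate's S site slots
are exchangeable with all n slots, giving the no-hit complement

    Pr(cleaved at motif) = 1 − Π_{i=0}^{S−1}(1 − k/(n−i)) = 1 − C(n−k,S)/C(n,S),

with factors clamped to [0, 1] when k/(n−i) exceeds 1 as S approaches
n. One simulation draws a Bernoulli(Pr) for every
(flagged substrate, replicate) with S >= 1 and sums them into a total
protein-cleavage count C; the observed C is scored against the
simulated distribution by the discrete mid-p method (two-sided by
doubling, one-sided available). When the observed count lies beyond the
simulated support, the reported p is the resolution bound 1/n_sims and
is flagged as an upper-bound estimate. Fold enrichment is observed C
over the simulated mean. Pairs use at-least-once semantics: a site
matching either member counts, and a substrate cleaved at both members
in one replicate is still one protein-cleavage.

Screens draw each target's simulations from a counter-based substream
(SeedSequence spawning), so a target's p-value is independent of which
other targets are screened and runs reproduce exactly under a fixed
seed. The default is 10⁵ simulations per target — p resolution 10⁻⁵,
adequate for q-values judged at 0.05 over 60-1,770 targets — with
larger counts available where the far tail itself is of interest.

## Candidate pair selection

Each pair is positioned on (fold enrichment, coverage), coverage being
its share of all observed flagged protein-cleavages. Pairs in which one
member is a configurable rare-P4 motif (default IXXD, CXXD, GXXD) and
the other has <= 1 observed protein-cleavage are marked ineligible
before selection: with a near-zero expected mean, the fold ratio is
arbitrarily inflated and such pairs are selection hazards, which is why
the filter precedes the walk rather than merely hiding points from a
plot. Selection sorts eligible, significant (p below the Bonferroni
cutoff over the pair family) points by descending fold and admits a
pair only when its coverage strictly exceeds every previously admitted
pair's. The result is exactly the strict Pareto frontier of
(fold, coverage); the significance gate is applied before the walk so
that non-significant points cannot block significant ones.
"Strictly exceeds" means coverage ties do not extend the candidate
list.

## Synthetic degradome generator

The generator emulates the structure the analysis consumes: a proteome
of i.i.d. sequences from Swiss-Prot-like residue frequencies (aspartate
~5.5%), a flagged substrate subset, and per-replicate event draws
without replacement from the candidate-site pool (aspartates at
position >= 5 with at least five downstream residues), with propensity
multiplied per matching motif by `subsite_weights` (global preference),
`scoc_motif_boost` (flagged substrates only) and
`scoc_sites_multiplier` (flagged substrates, motif-blind site-count
inflation). Sampling uses Gumbel top-k, which is exact weighted
sampling without replacement. Evidence rows emit the neo-N-terminal
peptide (P1′ onward to the first tryptic K/R at least five residues in,
capped at 30), exercising the extraction path end to end; a direct-site
shortcut (`events_from`) bypasses peptide mapping for speed.

Defaults and why:

- `n_replicates=3`, `events_per_replicate=1000` — the replicate
  structure of a small label-free study at the scale the calibration
  experiments use.
- `n_proteins=1000`, `protein_length=(450, 120)` — vertebrate-like
  protein lengths and, at 1,000 events per replicate, roughly one event
  per substrate per replicate, matching the site-per-substrate density
  of real degradome catalogues (a few hundred substrates per few
  hundred sites). Density matters: if the pool is so small that every
  protein is cleaved several times per replicate, each protein's fixed
  context composition is resampled in every replicate and the
  independent-Bernoulli null becomes visibly anti-conservative. At
  realistic density this effect is negligible (the null-calibration
  tests measure it directly).
- `scoc_fraction=0.1` — a moderately sized annotation class; large
  enough that association tests have meaningful expected counts.
- `aa_frequencies` — Swiss-Prot averages, so aspartate density and
  hence candidate-site density are realistic.

What the generator does **not** emulate: mass-spectral detectability
bias, protein abundance structure, missed or semi-specific cleavages
beyond the tryptic-like C terminus, and real protein families
(sequences are independent, so family collapse is exercised only by
coincidental octamer identity). Passing calibration and recovery tests
on this generator therefore shows the statistics behave as designed
under the model's own assumptions — not that real degradomes satisfy
those assumptions.

## Numerical choices

- Hypergeometric tails come from scipy's exact routines; no normal or
  continuity approximation anywhere (tail values down to 10⁻⁶ are
  meaningful in pair screens).
- Two-sided p-values double the smaller one-sided mid-p and cap at 1;
  at a support point of a symmetric two-point null this yields 0.5, at
  the symmetric center 1.0.
- Mann-Whitney switches from exact enumeration to the tie-corrected
  normal approximation above a combined n of 20 or in the presence of
  ties.
- Monte Carlo simulation is chunked (4·10⁶ draws per chunk) to keep
  memory flat at any n_sims.
- Selection tie-breaks: equal folds order by descending coverage, then
  pair label, and only strict coverage increases extend the candidate
  list.
- Degenerate inputs fail loudly: zero events, empty null histograms,
  empty groups, unresolvable accessions and invariant-violating counts
  all raise with the offending quantity named.

## Known limitations

- The background treats every aspartate in a cleaved substrate as
  equally accessible; topology and solvent accessibility are ignored.
- The Monte Carlo null conditions on per-replicate frequencies but
  assumes independence of a substrate's cleavage indicators across
  replicates; substrates with idiosyncratic context composition that
  recur in many replicates violate this mildly, in proportion to how
  concentrated the catalogue is on few substrates.
- Two-sided-ness of the screens is a convention (doubling), not a
  derivation; one-sided screening is available via `sided="upper"`.
- Family collapse uses identical-octamer identity as a proxy for
  homology; true paralogs with diverged cleavage contexts are not
  collapsed.
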