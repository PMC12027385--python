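# Methods

## Model and assumptions

`cenet` operates on the competing endogenous RNA (ceRNA) hypothesis:
every transcript that physically binds a miRNA (mRNA, lncRNA or
circRNA — collectively *ceRNAs*) competes for it, so miRNA
dysregulation reads out the state of its sponging network. The package
models one specific setting: miRNAs carried by extracellular vesicles
(EVs) released from stressed cells into a tissue, observed at one or
more disease stages.

Assumptions baked into the pipeline:

- **Direction concordance defines relevance.** A miRNA matters for the
  tissue network only if its DE direction agrees between the EV cargo
  and the tissue at that stage. Concordance is a set intersection of
  per-compartment calls; no overlap statistic is attached (raw
  intersections are the object of interest).
- **Stable vesicle release.** The EV compartment has a single,
  stage-independent DE table that is intersected with every tissue
  stage. If stage-resolved EV profiles exist they can be supplied as
  separate runs.
- **Polarity inversion.** Up-miRNAs imply sponges off, so they seed
  the DOWN network (down-regulated ceRNAs); down-miRNAs seed the UP
  network. A network edge survives filtering only when the target's
  tissue direction equals the network polarity.
- **Interactions are evidence, not inference.** miRNA→target edges
  come from a flat CLIP-supported interaction table (ENCORI-style
  export). The package never predicts targets; `clip_support` is
  carried through for optional thresholding (default: keep all, since
  the workflow it mirrors states no minimum).

## Parameters that matter

| Parameter | Default | Units / range | Rationale |
|---|---|---|---|
| `lfc` (DE inference) | 0.0 | log2 fold change | any reproducible change counts when upstream tables are pre-filtered; raise for raw DE tables |
| `padj` | 0.05 | probability | conventional DE significance |
| `fdr_max` | 0.05 | BH-adjusted p | enrichment significance threshold |
| `strength_min` | 0.01 | log10(obs/exp) | effect-size floor excluding terms barely above expectation |
| `min_hits` | 2 | genes | single-gene term hits are uninformative |
| `similarity_min` | 0.2 | Jaccard | grouping threshold for related terms |
| `clip_support_min` | 0 | CLIP experiments | keep-all default; raise to restrict to well-supported edges |

DE tables may carry an explicit `direction` column (takes precedence,
but a sign conflict with `log2fc` is a validation error, and
`up`/`down` must agree with the ordering of the normalized means) or
`log2fc`/`padj`, from which the direction is inferred with strict
inequalities — `log2fc` exactly at the threshold is not significant.
A missing `padj` is treated as pre-filtered input only when the padj
requirement is disabled (`padj >= 1`); otherwise the record is `ns`.
miRNA identifiers are atomic, case-preserving strings after whitespace
trimming: arm variants (-5p/-3p) are distinct entities and are never
collapsed. A miRNA reported with conflicting directions inside one
compartment is excluded from seed selection and logged. ceRNA targets
are matched to DE evidence by (identifier, RNA class); when the id
exists only under a different class than the interaction table claims,
the interaction table's class annotation wins and the mismatch is
logged. circRNAs are identified by host-gene symbol; there is no
back-splice coordinate model.

## Enrichment statistics

For a query of `n` genes inside a background universe of `N`, a term
with `K` background genes and `k` query hits is scored with the exact
hypergeometric upper tail `P(X ≥ k)` (via `scipy.stats.hypergeom.sf`,
log-space stable; validated in the tests against integer-combinatorics
enumeration over the complete grid `N ≤ 60` at 1e-12 relative error).
BH adjustment (`scipy.stats.false_discovery_control`) runs separately
within each annotation category over all tested terms of that
category, matching the practice of reporting ontology categories as
separate panels. The effect-size filter is the STRING-style *strength*
`log10((k/n)/(K/N))`; the composite "signal" blend of strength and FDR
used by some servers is not reproducible from published descriptions
and is deliberately not implemented. Term grouping is single-linkage
clustering on Jaccard similarity of the terms' query-member sets —
Jaccard was chosen over kappa-style agreement for definability; group
representatives are lowest-FDR terms and group ids follow
representative order, so output is deterministic. The default
background is the union of all genes in the supplied annotation files;
supply an explicit genome list to widen it.

## Synthetic data: what it emulates and what it does not

The generator plants known structure and returns it as `truth`:

- `frac_concordant_up`/`_down` of `n_mirna` miRNAs share their
  direction across compartments; all others are deliberately
  discordant. Tissue labels then flip with `noise_flip_prob`, which
  both removes planted members and creates spurious ones — the two
  error modes real label noise produces.
- Each planted seed receives `planted_edges_per_seed` reserved targets
  (cycled over mRNA/lncRNA/circRNA) whose tissue direction is set
  polarity-consistent; all other miRNA×ceRNA pairs appear
  independently with probability `edge_density` and uniform CLIP
  support on 1..10. `truth` also lists every edge an ideal polarity
  filter would keep (planted plus coincidentally consistent background
  edges), which is what the pipeline must recover exactly at zero
  noise.
- One annotation term covers `planted_term_coverage` of the ideal
  network's gene set, padded to `planted_term_size` with off-network
  genes; the remaining terms are uniform draws.

Defaults (60 miRNAs, 300 ceRNAs per class, 10%/8% concordant, density
0.005, 3 planted edges per seed, 50 terms, 25-gene planted term at 80%
coverage) describe a small but structurally complete study of this
kind; expression means are log-normal around class-specific baselines
and exist only so the direction/mean-ordering invariant holds. The
generator does **not** model count-level noise, miRNA families or seed
sequences, shared targets between seeds, or sponging kinetics —
passing recovery tests therefore demonstrates correctness of the
selection/filtering logic, not statistical power on real sequencing
data.

All sampling flows from one `numpy.random.Generator` keyed by
`rng_seed` in a fixed draw order, so equal configs give byte-identical
files. A calibration note: at `noise_flip_prob = 0.1` the mean
seed-set Jaccard against truth is ≈ 0.80 (500-replicate brute-force
estimate; SD of 100-replicate means ≈ 0.011); the regression test
bounds the 100-replicate mean at 0.76 (≈ mean − 3 SD), because the
per-direction seed sets are small enough that single flips move the
ratio appreciably.

## Numerical and design choices

- All tabular I/O is header-addressed TSV (UTF-8, `#` comments); no
  positional parsing. Duplicate interaction rows collapse to the
  maximum CLIP support, keeping first-seen order so deduplication is
  idempotent.
- `select_concordant` reads the compartment roles off the records, so
  the two record lists can be passed in either order; mixing
  compartments within one list or passing the same compartment twice
  is an error.
- Exports are fully sorted (edges by (miRNA, target), nodes
  lexicographic); reruns of the pipeline on identical inputs are
  byte-identical, which the tests assert at the file-bytes level.
- Degree-0 seed miRNAs never appear in exported node sets but are
  reported in the run report, split into seeds absent from the
  interaction table (`missing_seeds`) and seeds whose every edge the
  polarity filter removed (`filtered_out_seeds`); together with the
  connected seeds these partition the seed set.
- Empty seed sets and empty networks are warnings, not errors: a
  stage/direction with no concordant miRNAs is a legitimate finding.

## Problem sizes

The test suite and the acceptance script run entirely on the packaged
fixture (tens of rows) and on synthetic instances of at most a few
thousand interactions; statistical checks use 100–500 seeded
replicates and the exactness grid for the hypergeometric tail stops at
`N = 60`, sizes at which the exact enumeration oracle is itself
trustworthy. Nothing in the implementation is size-limited: the
filtering and enrichment steps are linear and `O(terms × genes)`
respectively, and genome-scale interaction tables are handled by the
same code paths.

## Known limitations

- The concordance step treats DE calls as binary labels; magnitude
  information (fold changes) is not used beyond direction inference.
- Networks reconstructed from public interaction snapshots inherit
  that snapshot's coverage bias (well-studied miRNAs have more CLIP
  support); `missing_seeds` makes the gap visible but cannot correct
  it.
- Enrichment results depend on the annotation files supplied; the
  package deliberately ships no annotation database and performs no
  live queries, so term lists from any given web server will differ
  with its database version.
- The EV stage-independence assumption is a modelling convenience;
  violations (stage-specific cargo) bias seed sets toward the stages
  the EV table actually reflects.
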