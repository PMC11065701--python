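# bcrnet

**B cell receptor (BCR) repertoire analysis of clonal immunosurveillance and
temporal persistence.**

Tumor-infiltrating B cell clones can be tracked across metastatic sites and
across therapy timepoints from heavy-chain BCR sequencing. `bcrnet` implements
the full analysis chain for such data, for immunogenomics analysts working
with AIRR-style rearrangement tables:

- **Clonotype assembly** — unique-sequence networks whose edges join
  sequences differing by a single non-indel substitution, unioned with
  single-linkage clustering of equal-length CDR3s at 95% amino-acid identity
  within the same IGHV gene. Clones are the connected components, per
  participant.
- **Depth-matched clonal sharing** — pairwise shared-VDJ counts and Jaccard
  coefficients J = |A∩B| / |A∪B| between samples, each estimated as the
  median over 10,000 subsamples at 90% of the shallowest sample's unique-VDJ
  depth.
- **Repertoire trees** — Ward-D2 dendrograms on D = 1 − J, cophenetic
  correlation between BCR/TCR trees and edge-weighted tumor phylogenies
  (Newick), with a one-sided 100-permutation label-shuffling test.
- **Clone classes** — stem / clade / private topology (all / some / one of a
  participant's samples), a Gaussian-mixture expansion threshold on pooled
  log₁₀ percent-UMI clone sizes, and the four classes A (private expanded),
  B (shared expanded), C (private unexpanded), D (shared unexpanded).
- **Diversity and maturation profiles** — subsampled Gini / Shannon / mean
  clone size, SHM categories (no / low / high / very high), isotype usage and
  the class-switch + >4 mutations antigen-experience rule.
- **Degree centrality — the headline method.** For every clone in ≥2 samples
  with ≥10 unique BCRs, alignments are end-trimmed to 95% column occupancy
  (min 80 nt), identical sequences are grouped into variants, and a minimum
  spanning tree is built on the pairwise Hamming matrix. A variant's *degree*
  (number of incident MST edges) measures how many descendant variants it
  spawned; thresholding the degree (>1, >2, >10) predicts which BCRs are
  immunosurveilling (seen in ≥2 sites) or temporally persistent (≥2
  timepoints).
- **Antigen screening** — fuzzy matching of CDR3s (equal length, ≤3 amino
  acid mismatches) against a reference table of antibodies with known
  anti-pathogen specificity, to exclude contamination by systemic responses.
- **Synthetic repertoires with planted truth** — a generator that emulates
  multi-site/multi-timepoint repertoires with point-mutation lineages,
  two-component clone sizes, depth-dependent class switching and planted
  cross-site *hub* variants, so every stage of the pipeline can be validated
  against known labels without access to any controlled human data.

## Worked example

```python
from bcrnet import SimConfig, simulate
from bcrnet.evaluate import assign_all, recovery_report

cfg = SimConfig()                       # 2 participants x 8 sites, 300 clones each
rep, truth = simulate(cfg, seed=1)
report = recovery_report(rep, truth, cfg, seed=1)

print(f"records: {len(rep)}  samples: {len(rep.samples)}  participants: {len(rep.participants)}")
print(f"clonotyping ARI vs planted lineages: {report.ari:.3f}")
print(f"expansion cutoff (log10 % UMIs): {report.cutoff:.2f} "
      f"(planted boundary {report.planted_boundary:.2f})")
print(report.classifier[["cutoff", "sensitivity", "specificity", "accuracy"]]
      .round(3).to_string(index=False))
```

prints

```
records: 3977  samples: 16  participants: 2
clonotyping ARI vs planted lineages: 0.988
expansion cutoff (log10 % UMIs): 0.45 (planted boundary 0.37)
 cutoff  sensitivity  specificity  accuracy
      1        1.000        0.450     0.479
      2        0.963        0.957     0.958
     10        0.331        1.000     0.966
```

Reading this: clone assembly recovers the planted lineages almost perfectly
(adjusted Rand index 0.988); the fitted expansion cutoff lands within
0.1 log₁₀ of the planted component boundary; and classifying a BCR variant as
immunosurveilling when its MST degree exceeds 2 identifies the planted
cross-site hubs with ~96% sensitivity, specificity and accuracy — degree >1
over-calls (every chain interior qualifies) and degree >10 under-calls,
reproducing the characteristic sensitivity/specificity trade-off across
cutoffs.

A thin CLI mirrors the library for shell use:

```sh
bcrnet simulate --seed 3 --out sim/
bcrnet sharing    --repertoire sim/repertoire.tsv --metadata sim/metadata.tsv --out shar
bcrnet trees      --input shar.matrix.csv --out tree
bcrnet centrality --repertoire sim/repertoire.tsv --metadata sim/metadata.tsv --out cent
```

## Notes

The analysis model and its assumptions, the generator's design and what it
does and does not emulate, and all numerical choices are documented in
[`docs/methods.md`](docs/methods.md). Real controlled-access cohort data are
not required anywhere; the packaged reference antibody table is synthetic
(random sequences with a realistic per-source composition) and a user-supplied
curated table can be dropped in via `bcrnet.antigen.load_reference_db`.
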