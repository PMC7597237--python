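# pathpid

Path-based partial information decomposition (PID) for discrete
multivariate systems.

Pairwise associations between discrete random variables are modeled as
discrete memoryless channels — row-stochastic transition tensors estimated
from a joint pmf.  Channels compose along paths by matrix multiplication,
which defines a *path-based mutual information*: the MI of the
path-propagated joint rather than the empirical endpoint joint.
Redundancy between a set of sources and a target is the minimum path-based
MI over all admissible paths that visit every source and end at the
target; unique information and synergy follow from the usual PID
additivity equations, and atoms live on Williams–Beer redundancy lattices
with Möbius inversion.

Features:

* `JointPMF` — validated joint pmfs with marginalization, entropy, mutual
  information, conditional MI, and interaction information (bits, log2).
* `Channel` — channel estimation from a joint pmf, Bayes reversal, pmf
  propagation, cascade composition, null-channel detection.
* `Path` / `path_mutual_information` — path tensors, path-propagated
  joints, data-processing-inequality reports, traverse invariance.
* `infer_graph` — prune edges that carry no information (identical-row
  channels) or whose association is fully explained by a cascade through a
  third variable (with witness paths).
* `decompose` — the two-source PID (redundancy / unique / synergy) plus
  the 2- and 3-source redundancy lattices, Möbius atoms, the Williams–Beer
  `imin` reference measure, and an axiom-verification report.
* `fixtures` — exact rational reconstructions of the standard reference
  distributions (two-bit copy, Xor, And/Or, PwUnq, dyadic/triadic, …) and
  seeded random-system generators.
* TSV/CSV/JSON pmf documents (fractions like `5/6` parsed exactly) and a
  `pathpid` command-line interface.

## CLI

```sh
# decomposition of a built-in distribution (atom table, 4 dp)
pathpid decompose --fixture xor --sources X,Y --target Z

# or from a pmf document; '+' joins variables into a group
pathpid decompose --input system.tsv --sources X,Y --target Z+W --json

# association-graph inference with pruning provenance
pathpid structure --fixture triadic

# path-based MI along one path (reversible)
pathpid pathmi --fixture two_bit_copy --path X,Y,Z

# export a fixture, verify the redundancy axioms
pathpid fixture --name pwunq --out pwunq.tsv
pathpid axioms --fixture reduced_or --sources X,Y --target Z
```

Exit codes: `0` success, `2` validation failure, `3` when a negative atom
beyond tolerance is detected (a diagnostic signal for unobserved common
causes or over-determined systems — the table is still printed).

A pmf document is a TSV/CSV with one column per variable plus a final
probability column, or a JSON object with `variables`, optional
`alphabets`, and `states` rows.  `--counts` accepts raw counts.

## Notes

* Two conventions are surfaced explicitly: an empty admissible-path set
  yields redundancy 0 (independent sources), and indirect-pruned edges
  remain traversable by redundancy paths unless `strict=True`
  (`--strict-pruning`), which is the mode that recovers zero unique
  information for the distal source of a Markov chain.
* Synergy is defined as the additivity remainder, so the decomposition sums
  exactly; the interaction-information identity `S − R = I(X;Y|Z) − I(X;Y)`
  is verified as a cross-check rather than assumed.
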