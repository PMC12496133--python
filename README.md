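# pathact

Consensus pathway activity inference from copy-number and RNA-seq data.

Tumor cohorts measure the same biology through different, sometimes
conflicting, omic layers: a gene can be amplified yet underexpressed, or
transcriptionally silent while its pathway partners are active. `pathact`
integrates per-gene copy-number alteration (CNA) focal scores and RNA-seq
expression through a prior-knowledge pathway network — typed entities
(proteins, complexes, families, abstract processes) joined by signed
transcript-level, protein-level and membership interactions — to infer a
single consensus activity state per pathway entity per patient, and then
mines the cohort for patient groups and clinically relevant proteins.

## The model

Each pathway entity carries a hidden ternary state (−1 repressed, 0 normal,
+1 activated). Observed proteins get a three-layer chain *dna → rna →
activity*; interactions add regulation factors whose deterministic core is a
signed **vote** (regulatory edges), **min** (complex components: AND) or
**max** (family members: OR) over parents, softened by a mismatch
probability ε; observations attach with noise η. Sum-product belief
propagation (exact on acyclic graphs) yields marginals, summarized as the
**inferred pathway level**

&nbsp;&nbsp;&nbsp;&nbsp;IPL = log₁₀ ( p(activated) / p(repressed) ),

whose sign defines the entity's pathway state. The workflow is:

1. **States** — CNA state = sign(focal score); RNA state = position of the
   tumor value relative to mean ± 2 SD of a per-gene Gaussian fit to normal
   tissue (the 2 SD two-sided tail ≈ 0.0455, matching the usual P < .05).
2. **Inference** — factor-graph IPLs per patient.
3. **Permutation null** — (CNA, RNA) pairs shuffled between genes within
   each patient (default 100 permutations); IPLs recomputed.
4. **Filter** — a real IPL within 3 median absolute deviations of its
   permuted distribution is set to NA.
5. **Largest component** — only the biggest connected set of surviving
   entities is kept; everything else becomes state 0.
6. **Profiles & groups** — per-patient one-sided Fisher overrepresentation
   of altered entities in gene sets (GMT), BH-adjusted, −log₁₀-capped;
   patients grouped by Ward clustering of these profiles.
7. **Submodules** — connected entity sets (≥5 members, ≥1 observed protein)
   nonzero in *every* patient of a group; **key proteins** keep one
   constant nonzero direction.
8. **Survival** — patients stratified by whether all key proteins have
   IPL > 0; two-group log-rank test.

A synthetic-cohort generator (`pathact.synthetic`) plants coherent
multi-omic alterations with known carriers, so the whole pipeline is
testable without any external download.

## Worked example

`examples/05_group_discover_survive.py` simulates 20 patients (half carry
an activated 7-protein ring module), runs the eight steps and prints:

```
grouping vs planted carriers: adjusted Rand index = 1.00
group sizes: {1: 10, 2: 10}

group 1 submodule: 14 entities, 7 proteins
  key proteins (same nonzero state in every group patient): ['P001', 'P002', 'P003', 'P004', 'P005', 'P006', 'P007']

survival stratified by key-protein activation: log-rank stat 4.436, P = 0.0352 (10 activated vs 10 other)
```

The adjusted Rand index of 1.0 means the enrichment profiles separate
carriers from non-carriers perfectly; the reported submodule is exactly the
planted ring (7 proteins + 7 complexes), every planted protein is recovered
as an activated key protein, and key-protein activation stratifies the
simulated survival benefit (log-rank P < .05). The other numbered examples
walk through one capability each: parsing (01), state calls (02), inference
with conflicting omics (03), and the permutation-null filter (04).

A thin CLI wraps the same library (`pathact run --config config.yaml`, plus
per-stage subcommands `states`, `infer`, `permute`, `filter`, `profile`,
`group`, `submodules`, `survival`, `simulate`).

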