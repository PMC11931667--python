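# ensmut

Ensemble-based profiling of missense mutations in human lysosomal
α-mannosidase (hLAMAN), the enzyme deficient in α-mannosidosis.  Most of
the 43 reported deleterious variants sit far from the catalytic Zn²⁺ site,
so their effect cannot be read off a static structure.  This package
implements the descriptor pipeline that interrogates a *conformational
ensemble* (molecular-dynamics snapshots) instead:

- **Stability**: the distribution of the stability change ΔΔG(X→Y) across
  snapshots — its mean measures the impact on the fold, its standard
  deviation acts as a local-dynamics descriptor, and multimodality flags
  distinct conformational states.  The scorer is pluggable (a built-in
  empirical surrogate, or imported per-frame tables from external
  force-field tools).
- **Dihedral mutual information**: histogram MI between all dihedral-angle
  time series, `MI = H(x) + H(y) − H(x,y)`, normalized by the smaller
  marginal entropy to [0, 1] and summed over dihedral pairs to give the
  total coupling of every residue with the 10-residue active-site set
  (H72, D74, W77, D196, R220, D319, H446, D447, Y660, R823).
- **Bond-to-bond propensity**: on an energy-weighted heavy-atom graph with
  incidence matrix `B` and weight diagonal `W`, the edge-to-edge transfer
  `M = W B L⁺ Bᵀ W` (with `L = Bᵀ W B` the weighted Laplacian) measures how
  a perturbation at the active-site bonds redistributes onto every other
  bond; a distance-corrected quantile score in [0, 1] ranks each bond
  against peers equally far from the source.
- **Suboptimal paths**: k shortest loopless paths on a residue network
  whose edges require a heavy-atom contact (≤ 6 Å) and feature correlation
  |C| ≥ 0.25, with weight −log |C|.
- **Interface energetics**: chain–chain binding energies over the ensemble
  with an exact per-residue decomposition.
- **Integration**: the four descriptors normalized to [0, 1] (stability
  against a 20.35 kcal/mol cap), radar/quadrant profiles, group medians,
  Mann–Whitney rank-sum tests, and nearest-median classification of
  unassigned variants.

The packaged data tables carry the published catalog: 43 deleterious
variants (23 folding-defective / 17 activity-defective / 3 unclassified),
9 benign variants, and the normalized per-variant descriptor table.
A synthetic-data module generates ensembles, coupled dihedral series and
toy complexes with closed-form ground truth, so every stage is testable
without trajectories.

## Worked example

Profile the packaged descriptor table and classify the three unassigned
variants:

```python
from ensmut import (
    load_descriptor_table, packaged_path,
    profiles_from_descriptor_rows, group_medians, classify_unknown,
)

profiles = profiles_from_descriptor_rows(
    load_descriptor_table(packaged_path("descriptors"))
)
summaries = group_medians(profiles, ("folding", "activity"))
for s in summaries:
    print(s.group, s.n, {k: round(v, 3) for k, v in s.medians.items()})
for p in profiles:
    if p.group == "unclassified":
        group, dist = classify_unknown(p, summaries)
        print(p.mutation, "->", group,
              {k: round(v, 3) for k, v in dist.items()})
```

prints

```
folding 23 {'total_dihedral_mi': 0.181, 'ddg_norm': 0.294, 'ddg_sd_norm': 0.087, 'b2b_propensity': 0.709}
activity 17 {'total_dihedral_mi': 0.358, 'ddg_norm': 0.208, 'ddg_sd_norm': 0.091, 'b2b_propensity': 0.569}
L518P -> folding {'folding': 0.124, 'activity': 0.19}
G801D -> activity {'folding': 0.428, 'activity': 0.39}
R916S -> folding {'folding': 0.131, 'activity': 0.333}
```

The medians show the two groups' signatures: folding-defective variants
couple weakly to the active site (MI median 0.181) but carry high
bond-to-bond propensity (0.709) and larger stability changes, while
activity-defective variants show the opposite pattern.  The classifier
reports the Euclidean distance of each unassigned variant's normalized
4-vector to both group medians; the assignment is a nearest-median rule
and is reported together with the full distance table rather than as a
bare label.

The same pipeline runs from the shell:

```sh
ensmut --out-dir out profile src/ensmut/data/descriptors_normalized.csv
ensmut --seed 3 --out-dir out simulate          # synthetic ensemble + catalog
ensmut --out-dir out rmsf out/synthetic_ensemble.pdb
```

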