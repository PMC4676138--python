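# librank

Multi-criteria profiling and consensus ranking of compound screening
libraries.

Experimental screening campaigns start from a compound collection, and many
candidate libraries are available from different vendors — so which one
should a project buy? `librank` answers that question computationally. It
takes candidate libraries as SDF/SMILES files, profiles each on criteria
that matter for screening, and combines the profiles into a single ranking:

1. **Curation** — salt stripping, removal of inorganics, mixtures,
   bad-valence structures and duplicates; one protonation state at pH 7.4
   and one canonical tautomer per compound.
2. **ADME/T profile** — percent of compounds violating Lipinski's rule of
   five (more than one of HBD > 5, MW > 500, CLogP > 5, HBA > 10) or
   Veber's rules (rotatable bonds ≤ 10 and (TPSA ≤ 140 Å² or H-bond
   count ≤ 12)), and percent predicted not to cross the blood-brain
   barrier by a linear-plus-spline logBB model:

   ```
   logBB = 1.2827 + 0.17977·AlogP98 − 0.0033777·DPSA1
           − 0.18676·Num_H_Acceptors + 0.1557·S_sssN
           − 0.022135·⟨4.6743 − S_ssCH2⟩ ,   ⟨x⟩ = max(0, x)
   ```

   with logBB ≥ 0 classed as permeable.
3. **Promiscuous binders** — percent of compounds matching a PAINS-style
   frequent-hitter SMARTS catalog (shipped default, fully replaceable).
4. **Internal diversity** — mean pairwise Tanimoto similarity in several
   2D fingerprint spaces (ECFP_2, MDL keys and a 2-point pharmacophore
   fingerprint by default; lower similarity = more diverse).
5. **Similarity to known actives** (optional) — counts of compounds within
   a Tanimoto threshold of reference active compounds, plus a
   variable-atom substructure search.
6. **Overlap with an in-house collection** (optional) — percent of
   candidate compounds within Tanimoto 0.7 (ECFP_4) of any in-house
   compound.

Rankings use a two-level **dense-rank consensus**: every criterion ranks
the libraries (best = 1, ties share a rank, next distinct value = previous
rank + 1), ranks are summed per block, sums are dense-ranked, and block
ranks sum into grand totals and final ranks. Only value orderings matter,
so the scheme is invariant to monotone rescaling of any criterion. The
package also includes a Genetic Function Approximation (GFA) module —
kNN outlier filter, train/test splitting, evolution of linear/spline term
sets under Friedman's lack-of-fit criterion, Y-scrambling validation —
that rebuilds models of exactly the form the logBB equation takes.

See `docs/methods.md` for the underlying models, assumptions, parameter
defaults and limitations.

## Worked example

Build two small libraries — one clean and diverse, one consisting of a
single analogue series plus known frequent-hitter chemotypes — and rank
them:

```python
from librank.chemio import (Library, analogue_series, generate_fixture_library,
                            records_from_smiles, write_library)

good, _ = generate_fixture_library({"clean": 20}, seed=7, name="vendor_a")
write_library(good, "vendor_a.smi")

ref, analogues = analogue_series(9)            # one chain-homolog series
hitters = ["Oc1ccccc1O", "O=C1C=CC(=O)C=C1",   # catechol, quinone
           "S=C1NC(=O)CS1", "BrCCCCc1ccccc1"]  # rhodanine, alkyl halide
bad = Library("vendor_b", records_from_smiles([ref] + analogues + hitters))
write_library(bad, "vendor_b.smi")
```

```
$ cat config.yml
libraries:
  - {name: vendor_a, path: vendor_a.smi}
  - {name: vendor_b, path: vendor_b.smi}
seed: 1

$ librank rank --config config.yml --out results
best library: vendor_a

$ cat results/consensus.csv
library,size,admet_rank,promiscuity_rank,diversity_rank,total_rank,final_rank
vendor_a,20,1,1,1,3,1
vendor_b,14,2,2,2,6,2
```

vendor_a wins every block: none of its compounds trigger alerts
(`results/alerts.csv` shows 0.0 % vs 21.4 % promiscuous binders), and its
mean internal ECFP_2 similarity is 0.229 against vendor_b's 0.512 — the
analogue series makes vendor_b far less diverse (`results/diversity.csv`).
The total rank 3 vs 6 gives vendor_a final rank 1. Size (20 vs 14) is
reported but never ranked. Other subcommands (`curate`, `admet`, `alerts`,
`diversity`, `similarity`, `compare`, `benchmark-descriptors`,
`build-qsar`, `run`) expose the individual stages; `librank --help` lists
them.

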